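"""Readers and writers for region tables, confounds and clinical scores.

Two input dialects are supported for regional morphometry:

* plain TSV — one row per subject, first column ``subject_id``, remaining
  columns named after atlas regions (any column order);
* the FreeSurfer ``aparc.stats`` / ``aseg.stats`` whitespace-delimited
  dialect — one file per subject (and hemisphere, for ``aparc``), with
  ``#``-prefixed header lines and a ``# ColHeaders`` line naming the data
  columns.  A documented alias table maps FreeSurfer structure names onto
  canonical atlas names.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .data import ClinicalTable, ConfoundTable, MorphometryTable

__all__ = [
    "TableFormatError",
    "read_region_table",
    "write_region_table",
    "read_freesurfer_stats",
    "freesurfer_alias",
    "read_confound_table",
    "write_confound_table",
    "read_clinical_table",
    "write_clinical_table",
]

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


# FreeSurfer aparc measure column per morphometric measure.
_APARC_MEASURE_COLUMN = {"CT": "ThickAvg", "SA": "SurfArea", "MC": "MeanCurv"}

# FreeSurfer aseg structure names -> canonical atlas names.
_ASEG_ALIASES = {
    "Left-Cerebellum-Cortex": "lh_cerebellum_cortex",
    "Right-Cerebellum-Cortex": "rh_cerebellum_cortex",
    "Left-Cerebellum-White-Matter": "lh_cerebellum_white_matter",
    "Right-Cerebellum-White-Matter": "rh_cerebellum_white_matter",
    "Left-Thalamus": "lh_thalamus",
    "Right-Thalamus": "rh_thalamus",
    "Left-Thalamus-Proper": "lh_thalamus",
    "Right-Thalamus-Proper": "rh_thalamus",
    "Left-Caudate": "lh_caudate",
    "Right-Caudate": "rh_caudate",
    "Left-Putamen": "lh_putamen",
    "Right-Putamen": "rh_putamen",
    "Left-Pallidum": "lh_pallidum",
    "Right-Pallidum": "rh_pallidum",
    "Left-Hippocampus": "lh_hippocampus",
    "Right-Hippocampus": "rh_hippocampus",
    "Left-Amygdala": "lh_amygdala",
    "Right-Amygdala": "rh_amygdala",
    "Left-Accumbens-area": "lh_accumbens",
    "Right-Accumbens-area": "rh_accumbens",
    "Brain-Stem": "brainstem",
}


def freesurfer_alias(struct_name: str, hemisphere: Optional[str] = None) -> str:
    """Canonical atlas name for a FreeSurfer structure name.

    ``aparc`` parcel names need the hemisphere (``lh``/``rh``); ``aseg``
    segmentation names are resolved through the alias table.
    """
    if struct_name in _ASEG_ALIASES:
        return _ASEG_ALIASES[struct_name]
    if hemisphere in ("lh", "rh"):
        return f"{hemisphere}_{struct_name}"
    return struct_name


def _parse_stats_file(path) -> Tuple[pd.DataFrame, Dict[str, float], Optional[str]]:
    """Parse the FreeSurfer stats dialect: comment header with a
    ``# ColHeaders`` line, ``# Measure`` summary lines, whitespace rows."""
    columns = None
    measures: Dict[str, float] = {}
    hemi = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("ColHeaders"):
                    columns = body.split()[1:]
                elif body.startswith("Measure"):
                    parts = [p.strip() for p in body[len("Measure"):].split(",")]
                    if len(parts) >= 4:
                        try:
                            measures[parts[1]] = float(parts[3])
                        except ValueError:
                            pass
                elif body.startswith("hemi"):
                    hemi = body.split()[-1]
                continue
            rows.append(line.split())
    if columns is None:
        raise TableFormatError(f"{path}: no '# ColHeaders' line found")
    bad = [r for r in rows if len(r) != len(columns)]
    if bad:
        raise TableFormatError(
            f"{path}: data row has {len(bad[0])} fields, expected {len(columns)}"
        )
    df = pd.DataFrame(rows, columns=columns)
    return df, measures, hemi


def read_freesurfer_stats(path, kind: str, measure: str = "CT"):
    """Read one subject's ``aparc.stats`` or ``aseg.stats`` file.

    Returns ``(values, measures)`` where ``values`` maps canonical region
    names to floats (for ``aparc``, the requested measure's column; for
    ``aseg``, ``Volume_mm3``) and ``measures`` holds the file's summary
    ``# Measure`` entries (for ``aseg`` this includes ``TotalGray``).
    """
    df, file_measures, hemi = _parse_stats_file(path)
    if kind == "aparc":
        col = _APARC_MEASURE_COLUMN.get(measure)
        if col is None:
            raise ValueError(f"no aparc column for measure {measure!r}")
        if "StructName" not in df.columns or col not in df.columns:
            raise TableFormatError(
                f"{path}: aparc dialect needs StructName and {col} columns"
            )
        if hemi is None:
            raise TableFormatError(f"{path}: aparc file lacks a '# hemi' line")
        try:
            vals = df[col].astype(float)
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric cell in {col}: {exc}") from exc
        values = {
            freesurfer_alias(s, hemi): v for s, v in zip(df["StructName"], vals)
        }
    elif kind == "aseg":
        if "StructName" not in df.columns or "Volume_mm3" not in df.columns:
            raise TableFormatError(
                f"{path}: aseg dialect needs StructName and Volume_mm3 columns"
            )
        try:
            vals = df["Volume_mm3"].astype(float)
        except ValueError as exc:
            raise TableFormatError(
                f"{path}: non-numeric cell in Volume_mm3: {exc}"
            ) from exc
        values = {
            freesurfer_alias(s): v for s, v in zip(df["StructName"], vals)
        }
    else:
        raise ValueError(f"unknown FreeSurfer stats kind {kind!r}")
    return values, file_measures


def read_region_table(
    path,
    dialect: str,
    atlas: RegionAtlas,
    group: str = "HC",
    measure: str = "CT",
    subject_id: Optional[str] = None,
) -> MorphometryTable:
    """Read a regional morphometry table aligned to canonical atlas order.

    ``dialect`` is one of ``tsv`` (multi-subject wide table),
    ``freesurfer_aparc`` or ``freesurfer_aseg`` (single-subject stats
    files; regions absent from the file — e.g. the other hemisphere — are
    returned as NaN and must be filled before assembly).  Unmapped region
    columns are reported via logging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.columns[0] != "subject_id":
            raise TableFormatError(
                f"{path}: first TSV column must be 'subject_id', "
                f"found {df.columns[0]!r}"
            )
        subject_ids = tuple(df["subject_id"])
        present = [c for c in df.columns[1:]]
        unmapped = [c for c in present if c not in atlas.names]
        if unmapped:
            logger.warning("%s: ignoring unmapped region columns %s", path, unmapped)
        missing = [n for n in atlas.names if n not in present]
        if missing:
            raise TableFormatError(
                f"{path}: missing region column(s) {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''} for subjects {subject_ids[:3]}"
            )
        try:
            values = df[list(atlas.names)].astype(float).to_numpy()
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric cell: {exc}") from exc
        return MorphometryTable(group, measure, values, subject_ids)
    if dialect in ("freesurfer_aparc", "freesurfer_aseg"):
        kind = dialect.split("_", 1)[1]
        values, _ = read_freesurfer_stats(path, kind, measure)
        unmapped = [n for n in values if n not in atlas.names]
        if unmapped:
            logger.warning("%s: unmapped structures %s", path, unmapped)
        row = np.full(atlas.n_regions, np.nan)
        for name, v in values.items():
            if name in atlas.names:
                row[atlas.index(name)] = v
        sid = subject_id if subject_id is not None else path.stem
        return MorphometryTable(group, measure, row[None, :], (sid,))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_region_table(table: MorphometryTable, atlas: RegionAtlas, path) -> None:
    """Write a TSV region table (full float precision, round-trip safe)."""
    df = pd.DataFrame(table.values, columns=list(atlas.names))
    df.insert(0, "subject_id", list(table.subject_ids))
    df.to_csv(path, sep="\t", index=False)


def read_confound_table(path) -> ConfoundTable:
    """CSV with columns subject_id, age, gender, total_gm_volume.

    Empty cells become NaN; subjects with missing confounds are excluded
    at assembly with a warning.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "age", "gender", "total_gm_volume"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: confound CSV needs columns {sorted(required)}"
        )
    return ConfoundTable(
        tuple(df["subject_id"].astype(str)),
        pd.to_numeric(df["age"], errors="raise").to_numpy(),
        pd.to_numeric(df["gender"], errors="raise").to_numpy(),
        pd.to_numeric(df["total_gm_volume"], errors="raise").to_numpy(),
    )


def write_confound_table(conf: ConfoundTable, path) -> None:
    conf.to_frame().to_csv(path, index=False)


def read_clinical_table(path) -> ClinicalTable:
    """CSV with subject_id and pre/post score columns; empty cells = missing."""
    df = pd.read_csv(path)
    df["subject_id"] = df["subject_id"].astype(str)
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.frame.to_csv(path, index=False)
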