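"""Core data containers and confound residualization.

A study compares three groups — healthy controls (``HC``), essential-tremor
patients before thalamotomy (``ET_pre``) and the same patients one year after
(``ET_post``) — on three regional cortical morphometric measures: cortical
thickness (``CT``, mm), surface area (``SA``, mm^2) and mean curvature
(``MC``, 1/mm).  For each measure, the 19 noncortical regional volumes
(mm^3) are appended to the 68 cortical values, giving one P = 87-dimensional
vector per subject.  Only cross-regional correlations are analysed, so the
heterogeneous units are immaterial.

Before any covariance analysis, age, gender and total gray matter volume are
linearly regressed out of every regional column, separately within each
group; all downstream analyses operate on the residuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

__all__ = [
    "GROUPS",
    "MEASURES",
    "SCORES",
    "MorphometryTable",
    "ConfoundTable",
    "ClinicalTable",
    "StudyDataset",
    "residualize",
    "assemble_study",
]

logger = logging.getLogger(__name__)

GROUPS = ("HC", "ET_pre", "ET_post")
MEASURES = ("CT", "SA", "MC")

#: Clinical scores used by the leave-out association procedure.
SCORES = ("TSTH_baseline", "TSTH_percent_improvement")

_RTOL = 1e-10  # double-precision OLS tolerance for invariant checks


@dataclass(frozen=True)
class MorphometryTable:
    """Subjects x regions value matrix for one (group, measure).

    ``values[s, r]`` is subject ``s``'s value for atlas region ``r`` in
    canonical order (cortical columns first, then noncortical volumes).
    """

    group: str
    measure: str
    values: np.ndarray
    subject_ids: tuple
    residualized: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x regions matrix")
        if values.shape[0] != len(self.subject_ids):
            raise ValueError("row count must equal number of subject ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            s, r = bad[0]
            raise ValueError(
                f"non-finite value for subject {self.subject_ids[s]!r}, "
                f"region column {r} (and possibly others)"
            )

    def subset(self, subject_ids: Sequence[str]) -> "MorphometryTable":
        """Row subset preserving this table's subject order."""
        keep = set(subject_ids)
        rows = [i for i, s in enumerate(self.subject_ids) if s in keep]
        return replace(
            self,
            values=self.values[rows],
            subject_ids=tuple(self.subject_ids[i] for i in rows),
        )

    def drop_subjects(self, subject_ids: Iterable[str]) -> "MorphometryTable":
        drop = set(subject_ids)
        rows = [i for i, s in enumerate(self.subject_ids) if s not in drop]
        return replace(
            self,
            values=self.values[rows],
            subject_ids=tuple(self.subject_ids[i] for i in rows),
        )


@dataclass(frozen=True)
class ConfoundTable:
    """Per-subject nuisance covariates: age (years), gender (0/1 code,
    reference female), total gray matter volume (mm^3)."""

    subject_ids: tuple
    age: np.ndarray
    gender: np.ndarray
    total_gm_volume: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        for name in ("age", "gender", "total_gm_volume"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(self.subject_ids),):
                raise ValueError(f"{name} must have one value per subject")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        if np.any(self.age <= 0):
            raise ValueError("ages must be positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def complete_subjects(self) -> tuple:
        """Subjects with no missing confound (others are dropped upstream)."""
        ok = (
            np.isfinite(self.age)
            & np.isfinite(self.gender)
            & np.isfinite(self.total_gm_volume)
        )
        return tuple(s for s, good in zip(self.subject_ids, ok) if good)

    def aligned_to(self, subject_ids: Sequence[str]) -> "ConfoundTable":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise ValueError(f"confounds missing for subjects {missing}")
        rows = [pos[s] for s in subject_ids]
        return ConfoundTable(
            tuple(subject_ids),
            self.age[rows],
            self.gender[rows],
            self.total_gm_volume[rows],
        )

    def design_matrix(self) -> np.ndarray:
        """Intercept + age + gender + total GM volume, one row per subject."""
        return np.column_stack(
            [np.ones(self.n_subjects), self.age, self.gender, self.total_gm_volume]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "age": self.age,
                "gender": self.gender,
                "total_gm_volume": self.total_gm_volume,
            }
        )


_SCORE_COLUMNS = (
    "TSTH_pre",
    "TSTH_post",
    "ADL_pre",
    "ADL_post",
    "HEAD_pre",
    "HEAD_post",
    "QUEST_pre",
    "QUEST_post",
)


@dataclass(frozen=True)
class ClinicalTable:
    """Pre/post clinical scores for the patient cohort.

    Scores: TSTH (tremor score on the treated hand), ADL (activities of
    daily living), HEAD (head tremor, 0-3) and QUEST (quality of life in
    essential tremor).  Missing values are NaN; subjects with a missing
    score are excluded from computations that use that score.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        if "subject_id" not in df.columns:
            raise ValueError("clinical table needs a subject_id column")
        for col in _SCORE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        if df["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in clinical table")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    @property
    def subject_ids(self) -> tuple:
        return tuple(self.frame["subject_id"])

    def score(self, name: str) -> pd.Series:
        """A score series indexed by subject id.

        ``TSTH_baseline`` is the pre-intervention TSTH; the percent
        improvement is (pre - post) / pre * 100, undefined (NaN) when
        pre <= 0.
        """
        df = self.frame.set_index("subject_id")
        if name == "TSTH_baseline":
            return df["TSTH_pre"]
        if name == "TSTH_percent_improvement":
            return self.percent_improvement("TSTH")
        if name in df.columns:
            return df[name]
        raise KeyError(f"unknown clinical score {name!r}")

    def percent_improvement(self, score: str = "TSTH") -> pd.Series:
        """(pre - post) / pre * 100 per subject; NaN where pre <= 0 or missing."""
        df = self.frame.set_index("subject_id")
        pre = df[f"{score}_pre"]
        post = df[f"{score}_post"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (pre - post) / pre * 100.0
        out[~(pre > 0)] = np.nan
        return out

    def change(self, score: str = "TSTH") -> pd.Series:
        """Post-minus-pre score change (points) per subject."""
        df = self.frame.set_index("subject_id")
        return df[f"{score}_post"] - df[f"{score}_pre"]


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of ``y`` on the design ``X``."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _check_design_rank(X: np.ndarray) -> None:
    # Scale columns before the rank test so mm^3 volumes do not mask
    # collinearity among the remaining covariates.
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    rank = np.linalg.matrix_rank(X / norms, tol=1e-8)
    if rank < X.shape[1]:
        corr = np.corrcoef((X[:, 1:] - X[:, 1:].mean(0)).T)
        names = ["age", "gender", "total_gm_volume"]
        worst = None
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                r = abs(corr[a, b])
                if np.isfinite(r) and (worst is None or r > worst[0]):
                    worst = (r, names[a], names[b])
        detail = ""
        if worst is not None and worst[0] > 0.999:
            detail = f" ({worst[1]} and {worst[2]} are collinear)"
        elif np.any(np.std(X[:, 1:], axis=0) == 0):
            const = [n for n, s in zip(names, np.std(X[:, 1:], axis=0)) if s == 0]
            detail = f" (constant confound column(s): {const})"
        raise ValueError(f"confound design matrix is rank-deficient{detail}")


def residualize(table: MorphometryTable, confounds: ConfoundTable) -> MorphometryTable:
    """Regress age, gender and total GM volume out of every region column.

    Ordinary least squares with an intercept, fitted within the table's group
    only.  Residual columns are zero-mean and orthogonal to each confound.
    Requires at least 5 subjects (rank-deficiency guard) and a full-rank
    design.  Idempotent: residualizing residuals returns them unchanged up
    to ~1e-10.
    """
    table.require_finite()
    if table.n_subjects < 5:
        raise ValueError(
            f"group {table.group!r} has {table.n_subjects} subjects; "
            "at least 5 are required for confound regression"
        )
    conf = confounds.aligned_to(table.subject_ids)
    X = conf.design_matrix()
    _check_design_rank(X)
    resid = _ols_residuals(table.values, X)
    return replace(table, values=resid, residualized=True)


@dataclass(frozen=True)
class StudyDataset:
    """Assembled study: residualized tables per (group, measure), confounds
    per group, clinical scores for the patient cohort, and the atlas."""

    atlas: RegionAtlas
    tables: Mapping
    confounds: Mapping
    clinical: Optional[ClinicalTable] = None

    def __post_init__(self):
        object.__setattr__(self, "tables", dict(self.tables))
        object.__setattr__(self, "confounds", dict(self.confounds))

    @property
    def groups(self) -> tuple:
        return tuple(sorted({g for g, _ in self.tables}, key=_group_key))

    @property
    def measures(self) -> tuple:
        return tuple(sorted({m for _, m in self.tables}, key=_measure_key))

    def table(self, group: str, measure: str) -> MorphometryTable:
        try:
            return self.tables[(group, measure)]
        except KeyError:
            raise KeyError(f"no table for group {group!r}, measure {measure!r}") from None

    def group_sizes(self) -> Dict[str, int]:
        sizes: Dict[str, int] = {}
        for (g, _), t in self.tables.items():
            sizes.setdefault(g, t.n_subjects)
        return sizes


def _group_key(g):
    return GROUPS.index(g) if g in GROUPS else len(GROUPS)


def _measure_key(m):
    return MEASURES.index(m) if m in MEASURES else len(MEASURES)


def assemble_study(
    tables: Iterable[MorphometryTable],
    confounds: Mapping,
    clinical: Optional[ClinicalTable],
    atlas: RegionAtlas,
    residualize_tables: bool = True,
) -> StudyDataset:
    """Validate, residualize and bundle per-(group, measure) tables.

    Subjects with a missing confound are dropped with a warning.  The paired
    design is enforced: ``ET_pre`` and ``ET_post`` must hold the same
    subjects.  Each table must have exactly one column per atlas region.
    """
    by_key: Dict[tuple, MorphometryTable] = {}
    for t in tables:
        key = (t.group, t.measure)
        if key in by_key:
            raise ValueError(f"duplicate table for {key}")
        if t.n_regions != atlas.n_regions:
            raise ValueError(
                f"table {key} has {t.n_regions} columns, atlas has "
                f"{atlas.n_regions} regions"
            )
        by_key[key] = t

    groups = {g for g, _ in by_key}
    measures_by_group = {
        g: {m for gg, m in by_key if gg == g} for g in groups
    }
    all_measures = set().union(*measures_by_group.values()) if by_key else set()
    for g, ms in measures_by_group.items():
        missing = all_measures - ms
        if missing:
            raise ValueError(f"group {g!r} is missing measure(s) {sorted(missing)}")

    out_tables: Dict[tuple, MorphometryTable] = {}
    out_conf: Dict[str, ConfoundTable] = {}
    for g in groups:
        if g not in confounds:
            raise ValueError(f"no confound table for group {g!r}")
        conf = confounds[g]
        complete = set(conf.complete_subjects())
        for m in measures_by_group[g]:
            t = by_key[(g, m)]
            dropped = [s for s in t.subject_ids if s not in complete]
            if dropped:
                warnings.warn(
                    f"group {g!r}: dropping subjects with missing confounds: "
                    f"{dropped}",
                    stacklevel=2,
                )
                t = t.drop_subjects(dropped)
            t.require_finite()
            if residualize_tables and not t.residualized:
                t = residualize(t, conf)
            out_tables[(g, m)] = t
        kept_ids = out_tables[(g, next(iter(measures_by_group[g])))].subject_ids
        out_conf[g] = conf.aligned_to(kept_ids)

    if "ET_pre" in groups and "ET_post" in groups:
        m0 = next(iter(all_measures))
        pre_ids = set(out_tables[("ET_pre", m0)].subject_ids)
        post_ids = set(out_tables[("ET_post", m0)].subject_ids)
        if pre_ids != post_ids:
            odd = sorted(pre_ids.symmetric_difference(post_ids))
            raise ValueError(
                f"ET_pre / ET_post subject mismatch (paired design): {odd}"
            )

    study = StudyDataset(atlas, out_tables, out_conf, clinical)
    logger.info("assembled study: group sizes %s", study.group_sizes())
    return study
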