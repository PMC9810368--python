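"""Region atlas for parcellated morphometry.

The default atlas is the Desikan-Killiany cortical parcellation (34 regions
per hemisphere, 68 total) plus 19 noncortical regions (cerebellar cortex and
white matter, subcortical nuclei, and the brainstem), for P = 87 regions in
all.  The canonical order is fixed: left cortical (alphabetical), right
cortical (alphabetical), then the noncortical block.  Analyses index regions
by this order throughout, so it must be stable across runs.

The noncortical list mirrors the FreeSurfer ``aseg`` segmentation
conventions; a different region set can be supplied as a TSV with columns
``name``, ``hemisphere`` and ``class``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["RegionAtlas", "load_atlas", "AtlasFormatError", "DEFAULT_ATLAS"]

HEMISPHERES = ("left", "right", "midline")
REGION_CLASSES = ("cortical", "noncortical")

# Desikan-Killiany cortical parcel names, alphabetical within hemisphere.
_DK_CORTICAL_34 = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

# 19 noncortical regions: bilateral cerebellum (cortex + white matter),
# bilateral thalamus/caudate/putamen/pallidum/hippocampus/amygdala/accumbens,
# and the brainstem.  This is a documented convention, configurable via TSV.
_NONCORTICAL_19 = (
    ("lh_cerebellum_cortex", "left"),
    ("rh_cerebellum_cortex", "right"),
    ("lh_cerebellum_white_matter", "left"),
    ("rh_cerebellum_white_matter", "right"),
    ("lh_thalamus", "left"),
    ("rh_thalamus", "right"),
    ("lh_caudate", "left"),
    ("rh_caudate", "right"),
    ("lh_putamen", "left"),
    ("rh_putamen", "right"),
    ("lh_pallidum", "left"),
    ("rh_pallidum", "right"),
    ("lh_hippocampus", "left"),
    ("rh_hippocampus", "right"),
    ("lh_amygdala", "left"),
    ("rh_amygdala", "right"),
    ("lh_accumbens", "left"),
    ("rh_accumbens", "right"),
    ("brainstem", "midline"),
)


class AtlasFormatError(ValueError):
    """Raised when an atlas specification violates the format contract."""


@dataclass(frozen=True)
class RegionAtlas:
    """Immutable ordered region set.

    Parameters
    ----------
    names
        Unique region names in canonical order.
    hemispheres
        One of ``left`` / ``right`` / ``midline`` per region.
    region_classes
        One of ``cortical`` / ``noncortical`` per region.
    """

    names: tuple
    hemispheres: tuple
    region_classes: tuple
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not (len(self.names) == len(self.hemispheres) == len(self.region_classes)):
            raise AtlasFormatError("names, hemispheres and classes must align")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise AtlasFormatError(f"duplicate region names: {dupes}")
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise AtlasFormatError(f"unknown hemisphere token: {h!r}")
        for c in self.region_classes:
            if c not in REGION_CLASSES:
                raise AtlasFormatError(f"unknown region class token: {c!r}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def n_regions(self) -> int:
        return len(self.names)

    @property
    def cortical_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.region_classes) if c == "cortical"], dtype=int
        )

    @property
    def noncortical_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.region_classes) if c == "noncortical"],
            dtype=int,
        )

    @property
    def n_cortical(self) -> int:
        return len(self.cortical_indices)

    @property
    def n_noncortical(self) -> int:
        return len(self.noncortical_indices)

    def index(self, name: str) -> int:
        """Canonical 0-based index of a region name."""
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"region {name!r} not in atlas") from None

    def edge(self, name_i: str, name_j: str) -> tuple:
        """Unordered region pair as a sorted (i, j) index tuple with i < j."""
        i, j = self.index(name_i), self.index(name_j)
        if i == j:
            raise ValueError("an edge joins two distinct regions")
        return (i, j) if i < j else (j, i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "hemisphere": self.hemispheres,
                "class": self.region_classes,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _default_atlas() -> RegionAtlas:
    names, hemis, classes = [], [], []
    for hemi, prefix in (("left", "lh_"), ("right", "rh_")):
        for region in _DK_CORTICAL_34:
            names.append(prefix + region)
            hemis.append(hemi)
            classes.append("cortical")
    for name, hemi in _NONCORTICAL_19:
        names.append(name)
        hemis.append(hemi)
        classes.append("noncortical")
    return RegionAtlas(tuple(names), tuple(hemis), tuple(classes))


DEFAULT_ATLAS = _default_atlas()


def load_atlas(spec_path: Optional[str] = None) -> RegionAtlas:
    """Load a region atlas.

    With no argument, returns the built-in default (68 cortical + 19
    noncortical regions, P = 87).  Otherwise reads a TSV with columns
    ``name``, ``hemisphere``, ``class``; row order defines canonical order.
    """
    if spec_path is None:
        return DEFAULT_ATLAS
    path = Path(spec_path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "hemisphere", "class"}
    if not required.issubset(df.columns):
        raise AtlasFormatError(
            f"atlas TSV needs columns {sorted(required)}, found {list(df.columns)}"
        )
    if df["name"].isna().any():
        raise AtlasFormatError("atlas TSV contains empty region names")
    return RegionAtlas(
        tuple(df["name"]), tuple(df["hemisphere"]), tuple(df["class"])
    )
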