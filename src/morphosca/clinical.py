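"""Leave-out association between SC group differences and clinical scores.

Structural covariance is a group-level quantity, so it cannot be correlated
with per-subject clinical scores directly.  Instead, for every significant
edge the group difference is recomputed after excluding r = 1..10 patients
ranked by a clinical score:

* ``SC1(r)`` — difference after removing the r patients at the *low* end of
  the score (least impaired by baseline TSTH, or worst recoverers by
  percent TSTH improvement);
* ``SC2(r)`` — difference after removing the r patients at the *high* end
  (most impaired / best recoverers).

The summary metrics are the mean ``mu_SC`` and the OLS slope ``beta_SC`` of
the curve y(r) = |SC2(r)| - |SC1(r)|.  An edge is classified as clinically
associated when both are strictly positive.

For the HC vs ET_pre contrast, exclusions apply to the ET_pre patients only
(HC subjects are untouched) and the ranking score is baseline TSTH.  For
the ET_post vs ET_pre contrast, the sampling unit is the patient: an
excluded patient is removed from both the pre and the post table, ranked by
percent TSTH improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from .data import ClinicalTable, MorphometryTable

__all__ = [
    "CONTRASTS",
    "ClinicalLinkResult",
    "order_by_score",
    "leaveout_curves",
    "link_metrics",
    "classify_association",
    "evaluate_link",
]

logger = logging.getLogger(__name__)

#: contrast name -> (minuend group, subtrahend group, ranking score)
CONTRASTS = {
    "HC_vs_ETpre": ("HC", "ET_pre", "TSTH_baseline"),
    "ETpost_vs_ETpre": ("ET_post", "ET_pre", "TSTH_percent_improvement"),
}


def order_by_score(
    clinical: ClinicalTable,
    score_name: str,
    subject_ids: Optional[Sequence[str]] = None,
) -> Tuple[list, list]:
    """Subjects in ascending score order, plus those excluded for missingness.

    Ties are broken by the stable input subject order (seed-independent).
    Subjects whose score is missing are excluded first and reported.
    """
    scores = clinical.score(score_name)
    ids = list(subject_ids) if subject_ids is not None else list(clinical.subject_ids)
    unknown = [s for s in ids if s not in scores.index]
    if unknown:
        raise KeyError(f"subjects without clinical rows: {unknown}")
    excluded = [s for s in ids if not np.isfinite(scores[s])]
    if excluded:
        logger.warning(
            "excluding %d subject(s) with missing %s: %s",
            len(excluded), score_name, excluded,
        )
    ranked = [s for s in ids if s not in set(excluded)]
    # stable: ties keep input subject order, independent of any seed
    order = {s: i for i, s in enumerate(ids)}
    ranked.sort(key=lambda s: (scores[s], order[s]))
    return ranked, excluded


def _edge_corr(values: np.ndarray, i: int, j: int) -> float:
    x, y = values[:, i], values[:, j]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance region in reduced sample")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def leaveout_curves(
    tables: Mapping,
    clinical: ClinicalTable,
    edge: Tuple[int, int],
    contrast: str,
    r_max: int = 10,
    include_zero: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """SC1(r) and SC2(r) group-difference curves for one edge, r = 1..r_max.

    ``tables`` maps group name to its residualized :class:`MorphometryTable`.
    Residuals are not recomputed on the reduced subsets, so curve changes
    are attributable to subject exclusion alone.  With ``include_zero`` the
    curves start at r = 0 (the full-sample difference, useful for testing);
    the procedure proper uses r = 1..r_max.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    group_a, group_b, score_name = CONTRASTS[contrast]
    ta: MorphometryTable = tables[group_a]
    tb: MorphometryTable = tables[group_b]
    i, j = edge
    if i == j:
        raise ValueError("an edge joins two distinct regions")

    paired = contrast == "ETpost_vs_ETpre"
    ranked_pool = tb.subject_ids  # exclusions always rank the patient group
    ranked, _ = order_by_score(clinical, score_name, ranked_pool)
    n_ranked = len(ranked)
    if n_ranked - r_max < 5:
        raise ValueError(
            f"r_max={r_max} leaves fewer than 5 of {n_ranked} ranked subjects"
        )

    r_lo = 0 if include_zero else 1
    rs = range(r_lo, r_max + 1)
    sc1 = np.empty(len(rs))
    sc2 = np.empty(len(rs))
    for k, r in enumerate(rs):
        low = ranked[:r]  # least impaired / worst recoverers
        high = ranked[n_ranked - r:] if r > 0 else []  # most impaired / best recoverers
        for out, removed in ((sc1, low), (sc2, high)):
            tb_r = tb.drop_subjects(removed)
            ta_r = ta.drop_subjects(removed) if paired else ta
            out[k] = _edge_corr(ta_r.values, i, j) - _edge_corr(tb_r.values, i, j)
    return sc1, sc2


def link_metrics(
    sc1_curve: np.ndarray, sc2_curve: np.ndarray
) -> Tuple[float, float]:
    """Summary metrics of the leave-out difference curve.

    ``mu_SC`` is the mean of y(r) = |SC2(r)| - |SC1(r)| over r = 1..r_max;
    ``beta_SC`` is the slope of the OLS fit y = beta_SC * r + c.
    """
    sc1 = np.asarray(sc1_curve, dtype=float)
    sc2 = np.asarray(sc2_curve, dtype=float)
    if sc1.shape != sc2.shape or sc1.ndim != 1 or sc1.size < 2:
        raise ValueError("curves must be equal-length 1-D arrays of length >= 2")
    y = np.abs(sc2) - np.abs(sc1)
    r = np.arange(1, y.size + 1, dtype=float)
    mu = float(y.mean())
    beta = float(np.polyfit(r, y, 1)[0])
    return mu, beta


def classify_association(mu_sc: float, beta_sc: float) -> bool:
    """Edge shows a clinical association iff both metrics are strictly
    positive."""
    if not (np.isfinite(mu_sc) and np.isfinite(beta_sc)):
        raise ValueError("metrics must be finite")
    return bool(mu_sc > 0 and beta_sc > 0)


@dataclass(frozen=True)
class ClinicalLinkResult:
    """Leave-out clinical-association result for one edge."""

    edge: Tuple[int, int]
    contrast: str
    score_name: str
    sc1_curve: np.ndarray
    sc2_curve: np.ndarray
    mu_sc: float
    beta_sc: float
    associated: bool

    @property
    def diff_curve(self) -> np.ndarray:
        return np.abs(self.sc2_curve) - np.abs(self.sc1_curve)


def evaluate_link(
    tables: Mapping,
    clinical: ClinicalTable,
    edge: Tuple[int, int],
    contrast: str,
    r_max: int = 10,
) -> ClinicalLinkResult:
    """Run the full leave-out procedure for one edge and classify it."""
    sc1, sc2 = leaveout_curves(tables, clinical, edge, contrast, r_max)
    mu, beta = link_metrics(sc1, sc2)
    _, _, score_name = CONTRASTS[contrast]
    return ClinicalLinkResult(
        edge=tuple(edge),
        contrast=contrast,
        score_name=score_name,
        sc1_curve=sc1,
        sc2_curve=sc2,
        mu_sc=mu,
        beta_sc=beta,
        associated=classify_association(mu, beta),
    )
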