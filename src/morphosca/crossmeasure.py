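"""Per-region covariance across morphometric measures.

For each cortical region, the cross-measure covariance C is the Pearson
correlation, across the subjects of one group, between two measures'
residualized values in that region (e.g. is a region that is thicker in a
subject also larger in surface area?).  Only the 68 cortical regions enter
(noncortical regions carry a single volume measure), and no noise-edge
thresholding applies: the family is the 68 regional assessments per
(measure pair, contrast).

Group contrasts reuse the edge-wise machinery: subject-reshuffling
permutation nulls, add-one two-sided p-values, Benjamini-Hochberg FDR
across the 68 regions, and a global Wilcoxon rank-sum comparison of the
region-wise C distributions.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .data import MorphometryTable
from .edgewise import PermutationConfig, fdr_bh, rank_sum_z

__all__ = [
    "MEASURE_PAIRS",
    "cross_cov",
    "crossmeasure_contrast_test",
    "rank_sum_global_regions",
]

MEASURE_PAIRS = (("CT", "SA"), ("CT", "MC"), ("SA", "MC"))


def _check_same_subjects(tableX: MorphometryTable, tableY: MorphometryTable) -> None:
    if tableX.subject_ids != tableY.subject_ids:
        raise ValueError("the two measures must cover the same subjects in order")
    if tableX.group != tableY.group:
        raise ValueError("the two measures must come from the same group")


def _columnwise_corr(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching columns of X and Y across rows."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = X.std(axis=0)
    sy = Y.std(axis=0)
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("zero-variance region column")
    return (Xc * Yc).mean(axis=0) / (sx * sy)


def cross_cov(
    tableX: MorphometryTable, tableY: MorphometryTable, atlas: RegionAtlas
) -> np.ndarray:
    """Per-cortical-region correlation between two measures across subjects.

    Returns one value per cortical region, in canonical atlas order.
    """
    _check_same_subjects(tableX, tableY)
    cort = atlas.cortical_indices
    return _columnwise_corr(tableX.values[:, cort], tableY.values[:, cort])


def _batch_columnwise_corr(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column correlations for stacks shaped (k, n, m)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = X.std(axis=1)
    sy = Y.std(axis=1)
    sx = np.where(sx == 0, np.nan, sx)
    sy = np.where(sy == 0, np.nan, sy)
    return (Xc * Yc).mean(axis=1) / (sx * sy)


def crossmeasure_contrast_test(
    groupA_tables: Tuple[MorphometryTable, MorphometryTable],
    groupB_tables: Tuple[MorphometryTable, MorphometryTable],
    atlas: RegionAtlas,
    cfg: PermutationConfig,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-wise permutation test of the cross-measure difference A - B.

    Each permutation reassigns pooled subjects (keeping each subject's two
    measure vectors together) into groups of the original sizes and
    recomputes the per-region cross-measure correlation difference.
    """
    XA, YA = groupA_tables
    XB, YB = groupB_tables
    _check_same_subjects(XA, YA)
    _check_same_subjects(XB, YB)
    nA, nB = XA.n_subjects, XB.n_subjects
    if nA < 3 or nB < 3:
        raise ValueError("each group needs at least 3 subjects")

    cort = atlas.cortical_indices
    cA = _columnwise_corr(XA.values[:, cort], YA.values[:, cort])
    cB = _columnwise_corr(XB.values[:, cort], YB.values[:, cort])
    obs = cA - cB

    pooledX = np.vstack([XA.values[:, cort], XB.values[:, cort]])
    pooledY = np.vstack([YA.values[:, cort], YB.values[:, cort]])
    n = nA + nB
    rng = np.random.default_rng(cfg.seed)
    exceed = np.zeros(obs.size, dtype=np.int64)
    abs_obs = np.abs(obs)

    done = 0
    while done < cfg.n_perm:
        k = min(cfg.chunk, cfg.n_perm - done)
        order = np.argsort(rng.random((k, n)), axis=1)
        pX = pooledX[order]
        pY = pooledY[order]
        nullA = _batch_columnwise_corr(pX[:, :nA, :], pY[:, :nA, :])
        nullB = _batch_columnwise_corr(pX[:, nA:, :], pY[:, nA:, :])
        null = nullA - nullB
        # ties count as exceedances, as in permutation_test_edges
        if cfg.two_sided:
            exceed += (np.abs(null) >= abs_obs[None, :] - 1e-12).sum(axis=0)
        else:
            exceed += (null >= abs_obs[None, :] - 1e-12).sum(axis=0)
        done += k

    pvals = (1.0 + exceed) / (1.0 + cfg.n_perm)
    qvals, signif = fdr_bh(pvals, alpha=alpha)

    names = [atlas.names[i] for i in cort]
    return pd.DataFrame(
        {
            "region": cort,
            "region_name": names,
            "c_a": cA,
            "c_b": cB,
            "delta_c": obs,
            "p_perm": pvals,
            "q_fdr": qvals,
            "significant": signif,
        }
    )


def rank_sum_global_regions(
    c_a: Sequence[float], c_b: Sequence[float]
) -> Tuple[float, float]:
    """Wilcoxon rank-sum comparison of two region-wise C distributions.

    Same convention as the edge-wise global test: z < 0 when the first
    group's values are stochastically smaller.
    """
    a = np.asarray(c_a, dtype=float)
    b = np.asarray(c_b, dtype=float)
    if a.size != b.size:
        raise ValueError("region vectors must have equal length")
    return rank_sum_z(a, b)
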