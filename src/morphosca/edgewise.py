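"""Edge-wise structural covariance analysis.

Structural covariance (SC) of a morphometric measure is the Pearson
correlation, across the subjects of one group, between the residualized
regional values of a pair of regions ("edge").  For P regions there are
P(P-1)/2 candidate edges (3,741 for the default P = 87 atlas).

The analysis proceeds in four steps:

1. per-group SC matrices (:func:`compute_sc`);
2. noise-edge exclusion: an edge is discarded when its coefficient of
   determination R^2 stays below 0.2 (|R| < sqrt(0.2) ~ 0.4472) in every
   group (:func:`exclude_noise_edges`);
3. edge-wise group contrasts of the retained edges, assessed against a
   permutation null obtained by reshuffling subjects across groups, with
   Benjamini-Hochberg FDR correction (:func:`permutation_test_edges`);
4. a global Wilcoxon rank-sum comparison of the two groups' retained SC
   value distributions (:func:`rank_sum_global`).

Edges are linearly indexed over the upper triangle, i < j, row-major,
0-based; the convention is fixed and shared by all result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import MorphometryTable

__all__ = [
    "SCMatrix",
    "EdgeMask",
    "PermutationConfig",
    "n_edges",
    "edge_pairs",
    "edge_index",
    "kept_percentage",
    "compute_sc",
    "exclude_noise_edges",
    "edge_contrast",
    "permutation_test_edges",
    "exhaustive_permutation_test",
    "fdr_bh",
    "rank_sum_global",
    "rank_sum_z",
]

#: Default R^2 threshold below which (in all groups) an edge is noise.
NOISE_R2_THRESHOLD = 0.2


def n_edges(P: int) -> int:
    """Number of unordered region pairs, P(P-1)/2."""
    return P * (P - 1) // 2


def edge_pairs(P: int) -> Tuple[np.ndarray, np.ndarray]:
    """Region index pair (i, j), i < j, for each linear edge index
    (upper triangle, row-major)."""
    return np.triu_indices(P, k=1)


def edge_index(P: int, i: int, j: int) -> int:
    """Linear edge index of the unordered pair (i, j)."""
    if i == j:
        raise ValueError("an edge joins two distinct regions")
    if i > j:
        i, j = j, i
    if not (0 <= i < j < P):
        raise ValueError(f"region indices ({i}, {j}) out of range for P={P}")
    # row-major upper triangle offset
    return i * (2 * P - i - 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class SCMatrix:
    """Symmetric P x P structural covariance (Pearson R) matrix for one
    (group, measure), with unit diagonal."""

    group: str
    measure: str
    R: np.ndarray
    n_subjects: int

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")

    @property
    def P(self) -> int:
        return self.R.shape[0]

    def edge_values(self) -> np.ndarray:
        """Upper-triangle SC values in linear edge order."""
        iu, ju = edge_pairs(self.P)
        return self.R[iu, ju]


@dataclass(frozen=True)
class EdgeMask:
    """Boolean retain-flags over the P(P-1)/2 linear edge indices."""

    mask: np.ndarray
    P: int

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.shape != (n_edges(self.P),):
            raise ValueError(
                f"mask length {mask.shape} does not match P={self.P} "
                f"({n_edges(self.P)} edges)"
            )

    @property
    def n_total(self) -> int:
        return self.mask.size

    @property
    def n_kept(self) -> int:
        return int(self.mask.sum())

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_kept

    @property
    def percent_kept(self) -> float:
        return kept_percentage(self.n_total, self.n_excluded)


def kept_percentage(n_total: int, n_excluded: int) -> float:
    """Percentage of edges kept after exclusion, rounded to 2 decimals."""
    return round((n_total - n_excluded) / n_total * 100.0, 2)


def compute_sc(table: MorphometryTable) -> SCMatrix:
    """Pearson correlation of every region pair across subjects.

    Requires at least 3 subjects and no zero-variance column.
    """
    table.require_finite()
    X = table.values
    if X.shape[0] < 3:
        raise ValueError(
            f"SC needs at least 3 subjects, got {X.shape[0]} "
            f"({table.group}/{table.measure})"
        )
    sd = X.std(axis=0)
    if np.any(sd == 0):
        cols = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance region column(s) {cols.tolist()}")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return SCMatrix(table.group, table.measure, R, X.shape[0])


def exclude_noise_edges(
    sc_list: Sequence[SCMatrix], r2_threshold: float = NOISE_R2_THRESHOLD
) -> EdgeMask:
    """Retain an edge iff its R^2 reaches the threshold in at least one group.

    Noise edges are those whose coefficient of determination stays below
    ``r2_threshold`` (default 0.2, i.e. |R| < 0.4472) in every supplied
    group's SC matrix.
    """
    if not sc_list:
        raise ValueError("need at least one SC matrix")
    P = sc_list[0].P
    for sc in sc_list:
        if sc.P != P:
            raise ValueError("SC matrices differ in size")
    values = np.stack([sc.edge_values() for sc in sc_list])
    keep = np.max(values**2, axis=0) >= r2_threshold
    return EdgeMask(keep, P)


def edge_contrast(
    scA: SCMatrix, scB: SCMatrix, mask: Optional[EdgeMask] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-edge SC difference A - B on retained edges.

    Returns ``(edge_indices, deltas)``.  The sign convention is "first
    group minus second group" (e.g. HC - ET_pre, or ET_post - ET_pre).
    """
    if scA.P != scB.P:
        raise ValueError("SC matrices differ in size")
    delta = scA.edge_values() - scB.edge_values()
    if mask is None:
        edges = np.arange(delta.size)
        return edges, delta
    if mask.P != scA.P:
        raise ValueError("mask size does not match SC matrices")
    edges = np.flatnonzero(mask.mask)
    return edges, delta[edges]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the subject-reshuffling null.

    ``n_perm`` defaults to 300,000 null realizations; tests and examples
    use far fewer.  ``paired=True`` replaces group reshuffling with random
    within-patient swaps of the two conditions (an alternative respecting
    the paired design; off by default, which matches the plain reshuffling
    procedure).
    """

    n_perm: int = 300_000
    seed: Optional[int] = None
    two_sided: bool = True
    paired: bool = False
    chunk: int = 256

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.chunk < 1:
            raise ValueError("chunk must be >= 1")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Z-score columns of each (n x P) slice of a (k x n x P) stack."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _edge_corr_batch(X: np.ndarray, iu, ju) -> np.ndarray:
    """Edge correlations for a batch of permuted datasets.

    ``X`` has shape (k, n, P); returns (k, n_edges) Pearson correlations
    at the requested upper-triangle positions.
    """
    Z = _standardize_rows(X)
    n = X.shape[1]
    R = np.einsum("kni,knj->kij", Z, Z, optimize=True) / n
    return R[:, iu, ju]


def permutation_test_edges(
    tableA: MorphometryTable,
    tableB: MorphometryTable,
    mask: Optional[EdgeMask],
    cfg: PermutationConfig,
    alpha: float = 0.05,
    region_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Edge-wise permutation test of the SC difference A - B.

    The observed per-edge correlation difference is compared with a null
    built by randomly reassigning the pooled subjects to two groups of the
    original sizes and recomputing the difference, ``cfg.n_perm`` times.
    The two-sided p-value uses the add-one estimator
    ``p = (1 + #{|null| >= |obs|}) / (1 + n_perm)`` so p is never zero,
    and Benjamini-Hochberg q-values are attached across the retained edges
    (one familywise correction per measure and contrast).

    Residuals are NOT recomputed per permutation: the shuffling operates on
    the residualized values (re-residualization being a property of the
    preprocessing, not of the group assignment).
    """
    if tableA.n_regions != tableB.n_regions:
        raise ValueError("tables differ in region count")
    P = tableA.n_regions
    nA, nB = tableA.n_subjects, tableB.n_subjects
    if nA < 3 or nB < 3:
        raise ValueError("each group needs at least 3 subjects")
    if mask is None:
        mask = EdgeMask(np.ones(n_edges(P), dtype=bool), P)
    if mask.P != P:
        raise ValueError("mask size does not match tables")

    iu_all, ju_all = edge_pairs(P)
    kept = np.flatnonzero(mask.mask)
    iu, ju = iu_all[kept], ju_all[kept]

    scA = compute_sc(tableA)
    scB = compute_sc(tableB)
    obs = scA.R[iu, ju] - scB.R[iu, ju]

    pooled = np.vstack([tableA.values, tableB.values])
    n = nA + nB
    rng = np.random.default_rng(cfg.seed)
    exceed = np.zeros(kept.size, dtype=np.int64)
    abs_obs = np.abs(obs) if cfg.two_sided else obs

    if cfg.paired and nA != nB:
        raise ValueError("paired permutation requires equal group sizes")

    done = 0
    while done < cfg.n_perm:
        k = min(cfg.chunk, cfg.n_perm - done)
        if cfg.paired:
            # random within-patient swap of the two conditions
            swap = rng.random((k, nA)) < 0.5
            A_rows = np.where(swap[:, :, None], tableB.values, tableA.values)
            B_rows = np.where(swap[:, :, None], tableA.values, tableB.values)
            rA = _edge_corr_batch(A_rows, iu, ju)
            rB = _edge_corr_batch(B_rows, iu, ju)
        else:
            order = np.argsort(rng.random((k, n)), axis=1)
            permuted = pooled[order]
            rA = _edge_corr_batch(permuted[:, :nA, :], iu, ju)
            rB = _edge_corr_batch(permuted[:, nA:, :], iu, ju)
        null = rA - rB
        # ties count as exceedances (within numerical jitter), keeping the
        # estimator conservative
        if cfg.two_sided:
            exceed += (np.abs(null) >= abs_obs[None, :] - 1e-12).sum(axis=0)
        else:
            exceed += (null >= abs_obs[None, :] - 1e-12).sum(axis=0)
        done += k

    pvals = (1.0 + exceed) / (1.0 + cfg.n_perm)
    qvals, signif = fdr_bh(pvals, alpha=alpha)

    out = pd.DataFrame(
        {
            "edge": kept,
            "region_i": iu,
            "region_j": ju,
            "sc_a": scA.R[iu, ju],
            "sc_b": scB.R[iu, ju],
            "delta": obs,
            "p_perm": pvals,
            "q_fdr": qvals,
            "significant": signif,
        }
    )
    if region_names is not None:
        names = list(region_names)
        out.insert(1, "name_i", [names[i] for i in iu])
        out.insert(2, "name_j", [names[j] for j in ju])
    return out


def exhaustive_permutation_test(
    tableA: MorphometryTable,
    tableB: MorphometryTable,
    mask: Optional[EdgeMask] = None,
) -> pd.DataFrame:
    """Exact permutation p-values by enumerating all group reassignments.

    Feasible only for tiny samples (C(nA+nB, nA) splits); serves as the
    independent oracle for the Monte-Carlo test.  The identity assignment
    is part of the enumeration, so p >= 1 / n_splits.
    """
    P = tableA.n_regions
    nA = tableA.n_subjects
    pooled = np.vstack([tableA.values, tableB.values])
    n = pooled.shape[0]
    if mask is None:
        mask = EdgeMask(np.ones(n_edges(P), dtype=bool), P)
    iu_all, ju_all = edge_pairs(P)
    kept = np.flatnonzero(mask.mask)
    iu, ju = iu_all[kept], ju_all[kept]

    obs = compute_sc(tableA).R[iu, ju] - compute_sc(tableB).R[iu, ju]

    splits = list(combinations(range(n), nA))
    deltas = np.empty((len(splits), kept.size))
    for s, groupA in enumerate(splits):
        selA = np.array(groupA)
        selB = np.setdiff1d(np.arange(n), selA)
        XA = pooled[selA][None, :, :]
        XB = pooled[selB][None, :, :]
        deltas[s] = _edge_corr_batch(XA, iu, ju)[0] - _edge_corr_batch(XB, iu, ju)[0]
    pvals = (np.abs(deltas) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
    return pd.DataFrame(
        {"edge": kept, "region_i": iu, "region_j": ju, "delta": obs, "p_exact": pvals}
    )


def fdr_bh(pvals: Iterable[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and significance flags.

    q-values are monotonicity-enforced; an edge is significant iff
    q <= alpha.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def rank_sum_z(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Wilcoxon rank-sum z (normal approximation, tie-corrected) and
    two-sided p for sample ``a`` relative to ``b``.

    z < 0 when ``a`` is stochastically smaller than ``b``; identical value
    multisets give z = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    W = ranks[:n1].sum()
    N = n1 + n2
    mean_W = n1 * (N + 1) / 2.0
    # tie correction to the rank variance
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1)) if N > 1 else 0.0
    var_W = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var_W <= 0:
        return 0.0, 1.0
    z = (W - mean_W) / np.sqrt(var_W)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def rank_sum_global(
    scA: SCMatrix, scB: SCMatrix, mask: Optional[EdgeMask] = None
) -> Tuple[float, float]:
    """Wilcoxon rank-sum comparison of the two groups' retained SC values.

    The two samples are the upper-triangle SC values of A and B at the
    retained edges (the same mask applied to both).
    """
    a = scA.edge_values()
    b = scB.edge_values()
    if mask is not None:
        if mask.P != scA.P:
            raise ValueError("mask size does not match SC matrices")
        a = a[mask.mask]
        b = b[mask.mask]
    return rank_sum_z(a, b)
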