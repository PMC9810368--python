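import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphosca.edgewise import (
    EdgeMask,
    PermutationConfig,
    SCMatrix,
    compute_sc,
    edge_contrast,
    edge_index,
    exclude_noise_edges,
    exhaustive_permutation_test,
    fdr_bh,
    kept_percentage,
    n_edges,
    permutation_test_edges,
    rank_sum_global,
    rank_sum_z,
)


def sc_from_r(r_vals, P, group="HC"):
    """SCMatrix with given upper-triangle values (linear edge order)."""
    R = np.eye(P)
    iu, ju = np.triu_indices(P, k=1)
    R[iu, ju] = r_vals
    R[ju, iu] = r_vals
    return SCMatrix(group, "CT", R, 30)


class TestEdgeIndexing:
    def test_edge_count_default_atlas_size(self):
        assert n_edges(87) == 3741

    def test_linear_index_row_major(self):
        # P=4: (0,1)->0 (0,2)->1 (0,3)->2 (1,2)->3 (1,3)->4 (2,3)->5
        expected = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4, (2, 3): 5}
        for (i, j), k in expected.items():
            assert edge_index(4, i, j) == k
            assert edge_index(4, j, i) == k  # unordered


class TestComputeSC:
    def test_identical_and_flipped_columns(self, table_factory):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        t = table_factory(np.column_stack([x, x, -x]))
        R = compute_sc(t).R
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)

    def test_hand_computed_pearson(self, table_factory):
        # covariance / (sx*sy) on ((1,2),(2,1),(3,4),(4,5)) gives 6/sqrt(50)
        t = table_factory([[1, 2], [2, 1], [3, 4], [4, 5]])
        assert compute_sc(t).R[0, 1] == pytest.approx(6 / np.sqrt(50))

    def test_zero_variance_column_rejected(self, table_factory):
        t = table_factory([[1.0, 5], [2, 5], [3, 5]])
        with pytest.raises(ValueError, match="zero-variance"):
            compute_sc(t)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-100, max_value=100),
        flip=st.booleans(),
    )
    def test_affine_rescaling_invariance(self, a, b, flip):
        from conftest import make_table

        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 3))
        scale = -a if flip else a
        Y = X.copy()
        Y[:, 1] = scale * Y[:, 1] + b
        R0 = compute_sc(make_table(X)).R
        R1 = compute_sc(make_table(Y)).R
        sign = np.sign(scale)
        assert R1[0, 1] == pytest.approx(sign * R0[0, 1], abs=1e-9)
        assert R1[1, 2] == pytest.approx(sign * R0[1, 2], abs=1e-9)
        assert R1[0, 2] == pytest.approx(R0[0, 2], abs=1e-9)


class TestNoiseMask:
    def test_retained_iff_some_group_reaches_r2(self):
        P = 3  # edges (0,1) (0,2) (1,2)
        groups = [
            sc_from_r([0.9, 0.3, 0.1], P),
            sc_from_r([0.1, -0.2, -0.3], P),
            sc_from_r([0.1, 0.44, 0.2], P),
        ]
        mask = exclude_noise_edges(groups)
        # edge 0: one group at 0.9 -> kept; edges 1,2: all R^2 < 0.2 -> dropped
        assert mask.mask.tolist() == [True, False, False]
        assert mask.n_excluded == 2

    def test_threshold_boundary_value(self):
        # |R| just above sqrt(0.2) ~ 0.4472 is kept, just below is dropped
        assert np.sqrt(0.2) == pytest.approx(0.4472, abs=5e-5)
        mask = exclude_noise_edges([sc_from_r([0.448, 0.446, 0.0], 3)])
        assert mask.mask.tolist() == [True, False, False]

    def test_published_exclusion_counts_to_percent(self):
        assert kept_percentage(3741, 2206) == 41.03
        assert kept_percentage(3741, 2990) == 20.07
        assert kept_percentage(3741, 1408) == 62.36

    def test_mask_length_for_default_size(self):
        mask = EdgeMask(np.ones(n_edges(87), bool), 87)
        assert mask.n_total == 3741


class TestEdgeContrast:
    def test_identical_matrices_zero_delta(self):
        sc = sc_from_r([0.5, 0.2, -0.3], 3)
        _, delta = edge_contrast(sc, sc)
        assert np.allclose(delta, 0.0)

    def test_reported_recovery_delta(self):
        pre = sc_from_r([0.13], 2, group="ET_pre")
        post = sc_from_r([0.86], 2, group="ET_post")
        _, delta = edge_contrast(post, pre)
        assert delta[0] == pytest.approx(0.73)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        a = sc_from_r(rng.uniform(-1, 1, 6), 4)
        b = sc_from_r(rng.uniform(-1, 1, 6), 4)
        _, d1 = edge_contrast(a, b)
        _, d2 = edge_contrast(b, a)
        assert np.allclose(d1, -d2)

    def test_mask_restricts_edges(self):
        a = sc_from_r([0.5, 0.2, -0.3], 3)
        b = sc_from_r([0.1, 0.2, 0.3], 3)
        mask = EdgeMask(np.array([True, False, True]), 3)
        edges, delta = edge_contrast(a, b, mask)
        assert edges.tolist() == [0, 2]
        assert delta == pytest.approx([0.4, -0.6])


class TestPermutationTest:
    def test_no_exceedance_gives_add_one_floor(self, table_factory):
        rng = np.random.default_rng(1)
        # overwhelming planted difference: A correlated, B anticorrelated
        x = rng.normal(size=40)
        A = table_factory(np.column_stack([x, x + 0.01 * rng.normal(size=40)]),
                          group="A")
        y = rng.normal(size=40)
        B = table_factory(np.column_stack([y, -y + 0.01 * rng.normal(size=40)]),
                          group="B", prefix="t")
        cfg = PermutationConfig(n_perm=200, seed=0)
        res = permutation_test_edges(A, B, None, cfg)
        assert res.p_perm.iloc[0] == pytest.approx(1 / 201)

    def test_monte_carlo_matches_exhaustive_three_vs_three(self, table_factory):
        rng = np.random.default_rng(2)
        A = table_factory(rng.normal(size=(3, 2)), group="A")
        B = table_factory(rng.normal(size=(3, 2)), group="B", prefix="t")
        exact = exhaustive_permutation_test(A, B).p_exact.iloc[0]
        cfg = PermutationConfig(n_perm=100_000, seed=3, chunk=2048)
        mc = permutation_test_edges(A, B, None, cfg).p_perm.iloc[0]
        assert mc == pytest.approx(exact, abs=0.02)

    def test_deterministic_given_seed(self, table_factory):
        rng = np.random.default_rng(4)
        A = table_factory(rng.normal(size=(10, 4)), group="A")
        B = table_factory(rng.normal(size=(12, 4)), group="B", prefix="t")
        cfg = PermutationConfig(n_perm=500, seed=42)
        r1 = permutation_test_edges(A, B, None, cfg)
        r2 = permutation_test_edges(A, B, None, cfg)
        assert np.array_equal(r1.p_perm.values, r2.p_perm.values)

    def test_tiny_groups_rejected(self, table_factory):
        A = table_factory(np.random.default_rng(0).normal(size=(2, 2)), group="A")
        B = table_factory(np.random.default_rng(1).normal(size=(5, 2)),
                          group="B", prefix="t")
        with pytest.raises(ValueError, match="at least 3"):
            permutation_test_edges(A, B, None, PermutationConfig(n_perm=10))


class TestFdrBH:
    def test_constant_pvector_unchanged(self):
        q, sig = fdr_bh([0.01] * 10)
        assert np.allclose(q, 0.01)
        assert sig.all()

    def test_hand_applied_step_up(self):
        # sorted p * m / rank, then monotone from the back:
        # (0.04, 0.04, 0.0533..., 0.5)
        q, _ = fdr_bh([0.01, 0.02, 0.04, 0.5])
        assert q == pytest.approx([0.04, 0.04, 0.16 / 3, 0.5])

    def test_single_pvalue_is_its_own_q(self):
        q, _ = fdr_bh([0.037])
        assert q[0] == pytest.approx(0.037)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 0.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40))
    def test_qvalues_bounded_and_dominate_uniformly_scaled_p(self, pvals):
        q, _ = fdr_bh(pvals)
        p = np.array(pvals)
        assert np.all(q <= 1.0 + 1e-12)
        assert np.all(q >= p / len(p) - 1e-12)  # q >= p*m/rank >= p/m


class TestRankSum:
    def test_identical_multisets_give_zero(self):
        z, p = rank_sum_z([1.0, 2, 2, 3], [3.0, 2, 2, 1])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_separated_samples(self):
        # W = 6, mean = 10.5, var = 5.25 -> z = -4.5/sqrt(5.25)
        z, p = rank_sum_z([1.0, 2, 3], [4.0, 5, 6])
        assert z == pytest.approx(-4.5 / np.sqrt(5.25))
        assert z < 0  # first sample stochastically smaller

    def test_matches_scipy_normal_approximation(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(6)
        a = rng.normal(size=25)
        b = rng.normal(0.7, 1, size=30)
        z, p = rank_sum_z(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_shift_increases_magnitude_monotonically(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        zs = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            z, _ = rank_sum_z(a, a + shift)
            zs.append(z)
        assert zs[0] == pytest.approx(0.0)
        assert all(zs[k + 1] <= zs[k] for k in range(3))  # more negative

    def test_global_test_uses_masked_edges(self):
        a = sc_from_r([0.9, 0.1, 0.2], 3)
        b = sc_from_r([0.5, 0.8, 0.9], 3)
        mask = EdgeMask(np.array([True, True, False]), 3)
        z_masked, _ = rank_sum_global(a, b, mask)
        z_manual, _ = rank_sum_z([0.9, 0.1], [0.5, 0.8])
        assert z_masked == pytest.approx(z_manual)
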