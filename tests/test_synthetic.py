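import numpy as np
import pandas as pd
import pytest

import morphosca as m
from morphosca.synthetic import (
    ClinicalModel,
    build_model,
    inject_severity_link,
    make_psd,
    paper_like_model,
    simulate_clinical,
    simulate_group,
    simulate_study,
)


def single_edge_config(r, n, seed=0, extra=None):
    from morphosca.synthetic import _tiny_atlas

    zero_betas = {k: (0.0, 0.0, 0.0) for k in ("CT", "SA", "MC", "VOL")}
    cfg = {
        "atlas": _tiny_atlas(2),
        "measures": ("CT",),
        "group_sizes": {"HC": n},
        "planted_edges": [{"measure": "CT", "i": 0, "j": 1, "r": r}] if r else [],
        "confound_betas": zero_betas,
        "seed": seed,
    }
    cfg.update(extra or {})
    return cfg


class TestBuildModel:
    def test_empty_config_reproduces_study_dimensions(self):
        model = build_model({})
        assert model.group_sizes == {"HC": 29, "ET_pre": 34, "ET_post": 34}
        assert model.atlas.n_regions == 87
        assert model.measures == ("CT", "SA", "MC")

    def test_extreme_planted_r_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            model = build_model(
                {"planted_edges": [{"measure": "CT", "i": 0, "j": 1, "r": 0.99}]}
            )
        assert model.corr("HC", "CT")[0, 1] == pytest.approx(0.95)

    def test_identity_targets_need_no_projection(self):
        C, projected = make_psd(np.eye(5))
        assert not projected
        assert np.allclose(C, np.eye(5))

    def test_nonsymmetric_correlation_rejected(self):
        from morphosca.synthetic import _tiny_atlas

        C = np.eye(3)
        C[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            build_model({"atlas": _tiny_atlas(3), "measures": ("CT",),
                         "group_sizes": {"HC": 10},
                         "correlation": {("HC", "CT"): C}})

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="< 5"):
            build_model({"group_sizes": {"HC": 4}})

    def test_psd_projection_repairs_and_flags(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        out, projected = make_psd(C)
        assert projected
        w = np.linalg.eigvalsh(out)
        assert w.min() >= -1e-12
        assert np.allclose(np.diag(out), 1.0)


class TestSimulateGroup:
    def test_identity_null_structure_at_large_n(self):
        from morphosca.synthetic import _tiny_atlas

        cfg = single_edge_config(None, 10_000)
        cfg["atlas"] = _tiny_atlas(6)
        model = build_model(cfg)
        table, _ = simulate_group(model, "HC", "CT", seed=1)
        R = np.corrcoef(table.values, rowvar=False)
        off = R[np.triu_indices(6, k=1)]
        assert np.max(np.abs(off)) < 0.05  # ~3/sqrt(n)

    def test_planted_edge_converges_to_target(self):
        model = build_model(single_edge_config(0.7, 50_000))
        table, _ = simulate_group(model, "HC", "CT", seed=2)
        r = np.corrcoef(table.values[:, 0], table.values[:, 1])[0, 1]
        assert r == pytest.approx(0.7, abs=0.01)  # ~3(1-r^2)/sqrt(n)

    def test_convergence_rate_with_n(self):
        errs = {}
        for n in (100, 10_000):
            model = build_model(single_edge_config(0.5, n))
            table, _ = simulate_group(model, "HC", "CT", seed=3)
            r = np.corrcoef(table.values[:, 0], table.values[:, 1])[0, 1]
            errs[n] = abs(r - 0.5)
        assert errs[10_000] < 0.03
        assert errs[100] < 0.3

    def test_zero_betas_make_raw_equal_centered_residuals(self, tmp_path):
        model = build_model(single_edge_config(0.4, 1000))
        table, conf = simulate_group(model, "HC", "CT", seed=4)
        resid = m.residualize(table, conf)
        raw_centered = table.values - table.values.mean(axis=0)
        # no confound signal was added, so residualization only removes
        # chance association: columns stay statistically identical
        assert np.corrcoef(resid.values[:, 0], raw_centered[:, 0])[0, 1] > 0.99

    def test_reproducible_bit_identical(self):
        model = paper_like_model(seed=5)
        with pytest.warns(UserWarning):
            t1, c1, k1 = simulate_study(model, seed=11)
        with pytest.warns(UserWarning):
            t2, c2, k2 = simulate_study(model, seed=11)
        key = ("ET_pre", "MC")
        assert np.array_equal(t1[key].values, t2[key].values)
        assert k1.frame.equals(k2.frame)

    def test_paired_design_shares_ids_and_volumes(self):
        model = paper_like_model(seed=0)
        with pytest.warns(UserWarning):
            tables, conf, _ = simulate_study(model, seed=6)
        assert tables[("ET_pre", "CT")].subject_ids == tables[("ET_post", "CT")].subject_ids
        # the 19 noncortical volume columns are shared across measures
        assert np.array_equal(
            tables[("ET_pre", "CT")].values[:, 68:],
            tables[("ET_pre", "SA")].values[:, 68:],
        )


class TestSimulateClinical:
    def test_baseline_tsth_matches_configured_mean(self):
        model = build_model({"group_sizes": {"ET_pre": 10_000, "ET_post": 10_000}})
        clin = simulate_clinical(model, seed=7)
        assert clin.frame["TSTH_pre"].mean() == pytest.approx(20.41, abs=0.2)
        assert clin.frame["TSTH_pre"].between(0, 36).all()

    def test_full_improvement_zeroes_post_scores(self):
        model = build_model(
            {
                "group_sizes": {"ET_pre": 50, "ET_post": 50},
                "clinical": ClinicalModel(improvement=(100.0, 0.0)),
            }
        )
        clin = simulate_clinical(model, seed=8)
        assert np.allclose(clin.frame["TSTH_post"], 0.0)
        imp = clin.percent_improvement("TSTH").dropna()
        assert np.allclose(imp, 100.0)

    def test_zero_improvement_means_zero_drop(self):
        model = build_model(
            {
                "group_sizes": {"ET_pre": 50, "ET_post": 50},
                "clinical": ClinicalModel(improvement=(0.0, 0.0)),
            }
        )
        clin = simulate_clinical(model, seed=9)
        assert np.allclose(clin.frame["TSTH_post"], clin.frame["TSTH_pre"])
        assert np.allclose(clin.change("TSTH"), 0.0)

    def test_requested_missingness_injected(self):
        model = build_model(
            {
                "group_sizes": {"ET_pre": 34, "ET_post": 34},
                "clinical": ClinicalModel(missing={"QUEST_pre": 8, "QUEST_post": 9}),
            }
        )
        clin = simulate_clinical(model, seed=10)
        assert clin.frame["QUEST_pre"].isna().sum() == 8
        assert clin.frame["QUEST_post"].isna().sum() == 9


class TestSeverityLink:
    def test_kappa_out_of_range_rejected(self):
        model = build_model(single_edge_config(0.1, 100, extra={
            "group_sizes": {"ET_pre": 100, "ET_post": 100}}))
        with pytest.raises(ValueError, match="kappa"):
            inject_severity_link(model, (0, 1), 1.5)

    def test_link_requires_patient_group(self):
        model = build_model(single_edge_config(0.1, 100))
        with pytest.raises(ValueError, match="clinical"):
            inject_severity_link(model, (0, 1), 0.5, group="HC")

    def test_linked_edge_correlation_tracks_severity_tertiles(self):
        # with kappa > 0, top-severity patients carry a visibly stronger
        # correlation than bottom-severity patients
        model = m.severity_link_demo_model(kappa=0.6, n_per_group=3000)
        tables, conf, clin = simulate_study(model, seed=12)
        vals = tables[("ET_pre", "CT")].values
        s = clin.frame["TSTH_pre"].to_numpy()
        order = np.argsort(s)
        lo, hi = order[:1000], order[-1000:]
        r_lo = np.corrcoef(vals[lo, 0], vals[lo, 1])[0, 1]
        r_hi = np.corrcoef(vals[hi, 0], vals[hi, 1])[0, 1]
        assert r_hi - r_lo > 0.3  # kappa * spread of tertile means
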