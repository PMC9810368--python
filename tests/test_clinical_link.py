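import numpy as np
import pandas as pd
import pytest

import morphosca as m
from morphosca.clinical import (
    classify_association,
    evaluate_link,
    leaveout_curves,
    link_metrics,
    order_by_score,
)
from morphosca.data import ClinicalTable


def clinical_from(ids, tsth_pre, tsth_post=None):
    frame = pd.DataFrame({"subject_id": ids, "TSTH_pre": tsth_pre})
    if tsth_post is not None:
        frame["TSTH_post"] = tsth_post
    return ClinicalTable(frame)


class TestOrderByScore:
    def test_ascending_order(self):
        clin = clinical_from(["a", "b", "c"], [5.0, 1.0, 3.0])
        ranked, excluded = order_by_score(clin, "TSTH_baseline")
        assert ranked == ["b", "c", "a"]
        assert excluded == []

    def test_ties_keep_input_order(self):
        clin = clinical_from(["a", "b", "c", "d"], [2.0, 1.0, 2.0, 2.0])
        ranked, _ = order_by_score(clin, "TSTH_baseline")
        assert ranked == ["b", "a", "c", "d"]

    def test_missing_scores_excluded_first(self):
        clin = clinical_from(["a", "b", "c", "d", "e"],
                             [4.0, np.nan, 2.0, 1.0, 3.0])
        ranked, excluded = order_by_score(clin, "TSTH_baseline")
        assert excluded == ["b"]
        assert len(ranked) == 4
        assert ranked == ["d", "c", "e", "a"]

    def test_improvement_score_ordering(self):
        clin = clinical_from(["a", "b", "c"], [20.0, 20.0, 20.0],
                             [15.0, 5.0, 10.0])
        ranked, _ = order_by_score(clin, "TSTH_percent_improvement")
        assert ranked == ["a", "c", "b"]  # 25% < 50% < 75%


class TestLinkMetrics:
    def test_identical_curves_give_zero(self):
        sc = np.array([0.4, 0.5, 0.6])
        mu, beta = link_metrics(sc, sc)
        assert mu == 0.0 and beta == 0.0

    def test_hand_ols_on_three_points(self):
        # |SC2|-|SC1| = (0.1, 0.2, 0.3) over r = 1..3
        sc1 = np.zeros(3)
        sc2 = np.array([0.1, 0.2, 0.3])
        mu, beta = link_metrics(sc1, sc2)
        assert mu == pytest.approx(0.2)
        assert beta == pytest.approx(0.1)

    def test_constant_difference_has_zero_slope(self):
        sc1 = np.full(10, 0.2)
        sc2 = np.full(10, 0.45)
        mu, beta = link_metrics(sc1, sc2)
        assert mu == pytest.approx(0.25)
        assert beta == pytest.approx(0.0, abs=1e-12)


class TestClassifyAssociation:
    @pytest.mark.parametrize(
        "mu,beta,expected",
        [
            (0.024, 0.0069, True),    # reported associated recovery edge
            (-0.0062, 0.0002, False), # reported non-associated edge
            (0.0, 0.5, False),        # strict positivity at the boundary
            (0.5, 0.0, False),
            (1e-9, 1e-9, True),
        ],
    )
    def test_rule(self, mu, beta, expected):
        assert classify_association(mu, beta) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_association(np.nan, 0.1)


class TestLeaveoutCurves:
    def _study(self, kappa, seed, n=400):
        model = m.severity_link_demo_model(kappa=kappa, n_per_group=n)
        return m.build_study(model, seed=seed)

    def test_r_zero_equals_full_sample_delta(self):
        study = self._study(0.0, seed=1)
        tables = {g: study.table(g, "CT") for g in ("HC", "ET_pre")}
        sc1, sc2 = leaveout_curves(
            tables, study.clinical, (0, 1), "HC_vs_ETpre", r_max=3,
            include_zero=True,
        )
        hc = np.corrcoef(tables["HC"].values[:, 0], tables["HC"].values[:, 1])[0, 1]
        pre = np.corrcoef(tables["ET_pre"].values[:, 0],
                          tables["ET_pre"].values[:, 1])[0, 1]
        assert sc1[0] == pytest.approx(hc - pre, abs=1e-12)
        assert sc2[0] == pytest.approx(hc - pre, abs=1e-12)

    def test_curve_length_matches_r_max(self):
        study = self._study(0.0, seed=2)
        tables = {g: study.table(g, "CT") for g in ("HC", "ET_pre")}
        sc1, sc2 = leaveout_curves(tables, study.clinical, (0, 1),
                                   "HC_vs_ETpre", r_max=7)
        assert sc1.shape == sc2.shape == (7,)

    def test_r_max_too_large_rejected(self):
        study = self._study(0.0, seed=3, n=12)
        tables = {g: study.table(g, "CT") for g in ("HC", "ET_pre")}
        with pytest.raises(ValueError, match="fewer than 5"):
            leaveout_curves(tables, study.clinical, (0, 1), "HC_vs_ETpre",
                            r_max=10)

    def test_unknown_contrast_rejected(self):
        study = self._study(0.0, seed=4)
        tables = {g: study.table(g, "CT") for g in ("HC", "ET_pre")}
        with pytest.raises(ValueError, match="contrast"):
            leaveout_curves(tables, study.clinical, (0, 1), "HC_vs_post")

    def test_planted_link_detected_and_null_not_biased(self):
        # kappa = 0.6: most-impaired exclusion magnifies the contrast
        hits = 0
        null_mus = []
        for rep in range(15):
            study = self._study(0.6, seed=100 + rep, n=2000)
            tables = {g: study.table(g, "CT") for g in ("HC", "ET_pre")}
            res = evaluate_link(tables, study.clinical, (0, 1), "HC_vs_ETpre")
            hits += res.associated
            null_study = self._study(0.0, seed=200 + rep, n=2000)
            ntables = {g: null_study.table(g, "CT") for g in ("HC", "ET_pre")}
            nres = evaluate_link(ntables, null_study.clinical, (0, 1),
                                 "HC_vs_ETpre")
            null_mus.append(nres.mu_sc)
        assert hits >= 14
        # null mu_SC centered at zero
        null_mus = np.array(null_mus)
        sem = null_mus.std(ddof=1) / np.sqrt(len(null_mus))
        assert abs(null_mus.mean()) < 4 * sem + 1e-4

    def test_paired_contrast_removes_patient_from_both_conditions(self,
                                                                  table_factory):
        rng = np.random.default_rng(9)
        n = 12
        pre = table_factory(rng.normal(size=(n, 3)), group="ET_pre", prefix="p")
        post = table_factory(rng.normal(size=(n, 3)), group="ET_post", prefix="p")
        clin = clinical_from(list(pre.subject_ids),
                             np.linspace(10, 30, n), np.linspace(5, 10, n))
        tables = {"ET_pre": pre, "ET_post": post}
        sc1, sc2 = leaveout_curves(tables, clin, (0, 1), "ETpost_vs_ETpre",
                                   r_max=2)
        # recompute by hand for r = 1: drop the worst recoverer (lowest
        # percent improvement) from both tables
        imp = clin.percent_improvement("TSTH")
        worst = imp.idxmin()
        pre_r = pre.drop_subjects([worst]).values
        post_r = post.drop_subjects([worst]).values
        expected = (np.corrcoef(post_r[:, 0], post_r[:, 1])[0, 1]
                    - np.corrcoef(pre_r[:, 0], pre_r[:, 1])[0, 1])
        assert sc1[0] == pytest.approx(expected, abs=1e-12)

    def test_swapping_exclusion_direction_negates_metrics(self):
        study = self._study(0.6, seed=55, n=1000)
        tables = {g: study.table(g, "CT") for g in ("HC", "ET_pre")}
        sc1, sc2 = leaveout_curves(tables, study.clinical, (0, 1),
                                   "HC_vs_ETpre")
        mu, beta = link_metrics(sc1, sc2)
        mu_swapped, beta_swapped = link_metrics(sc2, sc1)
        assert mu_swapped == pytest.approx(-mu)
        assert beta_swapped == pytest.approx(-beta)
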