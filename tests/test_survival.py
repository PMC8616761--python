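"""Serum-marker calibration, KM/log-rank/MH machinery, enrichment scans."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import prosubtype as ps
from prosubtype.containers import ValidationError


class TestCalibratePAP:
    def test_exact_linear_fit(self):
        slope, intercept, conv = ps.calibrate_pap([(1, 2), (2, 4), (3, 6)], [5])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert conv[0] == pytest.approx(10.0)

    def test_flat_relation(self):
        slope, intercept, conv = ps.calibrate_pap([(0, 1), (1, 1), (2, 1)], [17.0])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert conv[0] == pytest.approx(1.0)

    def test_ols_consistency_under_noise(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 1000)
        y = 3 * x - 1 + rng.uniform(-1, 1, 1000)
        slope, _, _ = ps.calibrate_pap(list(zip(x, y)), [])
        assert 2.9 <= slope <= 3.1

    def test_degenerate_x_is_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            ps.calibrate_pap([(1, 2), (1, 3), (1, 4)], [2])

    def test_negative_conversions_floored(self, caplog):
        with caplog.at_level("WARNING", logger="prosubtype"):
            _, _, conv = ps.calibrate_pap([(0, 0), (1, 1), (2, 2)], [-5.0])
        assert conv[0] == 0.0


class TestRatios:
    def test_ppr_twenty_goes_to_low_group(self):
        ppr = ps.psa_pap_ratio(100.0, 5.0)
        assert ppr == 20.0
        assert ps.dichotomize([ppr]) == ["low"]  # boundary belongs to <=20

    def test_just_above_cutoff_is_high(self):
        assert ps.dichotomize([20.0001]) == ["high"]

    def test_zero_psa_gives_zero_ratio(self):
        assert ps.psa_pap_ratio(0.0, 5.0) == 0.0

    def test_zero_pap_is_error(self):
        with pytest.raises(ValidationError):
            ps.psa_pap_ratio(10.0, 0.0)

    def test_transcript_log_ratio_is_subtraction(self):
        assert ps.klk3_acp3_log_ratio(10.0, 6.0) == 4.0

    def test_empty_dichotomize(self):
        assert ps.dichotomize([]) == []


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        curve = ps.km_estimate([1, 2, 3, 4], [True] * 4)
        surv_at = [curve.at(t) for t in (1, 2, 3, 4)]
        np.testing.assert_allclose(surv_at, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2.0

    def test_all_censored_flat_curve(self):
        curve = ps.km_estimate([5, 6, 7], [False] * 3)
        assert (curve.survival == 1.0).all()
        assert np.isnan(curve.median)

    def test_single_event(self):
        curve = ps.km_estimate([5], [True])
        assert curve.at(5) == 0.0
        assert curve.median == 5.0

    def test_curve_monotone_from_one(self):
        rng = np.random.default_rng(0)
        curve = ps.km_estimate(rng.exponential(10, 50), rng.random(50) < 0.7)
        assert curve.survival[0] == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            ps.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        g = ([1, 2, 3], [True, True, False])
        chi2, p = ps.logrank_test(g, g)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_hand_enumerated_risk_sets(self):
        # A events at 1,2; B events at 3,4: O_A=2, E_A=1/2+1/3,
        # V=1/4+2/9 -> chi2 = (7/6)^2 / (17/36) = 49/17
        chi2, p = ps.logrank_test(([1, 2], [True, True]), ([3, 4], [True, True]))
        assert chi2 == pytest.approx(49 / 17, abs=1e-12)

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(10, 40), rng.exponential(20, 35)
        ea, eb = rng.random(40) < 0.8, rng.random(35) < 0.8
        chi2, p = ps.logrank_test((ta, ea), (tb, eb))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(1000):
            ta = rng.exponential(10, 50)
            tb = rng.exponential(10, 50)
            _, p = ps.logrank_test((ta, [True] * 50), (tb, [True] * 50))
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_events_is_error(self):
        with pytest.raises(ValidationError):
            ps.logrank_test(([1, 2], [False, False]), ([3], [False]))


class TestMantelHaenszel:
    def test_identical_groups_hr_one(self):
        g = ([1, 2, 3, 4], [True, True, True, False])
        hr, lo, hi = ps.mh_hazard_ratio(g, g)
        assert hr == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_group_swap_inverts_hr(self):
        rng = np.random.default_rng(2)
        a = (rng.exponential(5, 30), [True] * 30)
        b = (rng.exponential(15, 30), [True] * 30)
        hr_ab, lo_ab, hi_ab = ps.mh_hazard_ratio(a, b)
        hr_ba, lo_ba, hi_ba = ps.mh_hazard_ratio(b, a)
        assert hr_ab == pytest.approx(1 / hr_ba, rel=1e-9)
        assert lo_ab == pytest.approx(1 / hi_ba, rel=1e-9)

    def test_direction_agrees_with_observed_vs_expected(self):
        rng = np.random.default_rng(3)
        fast = (rng.exponential(5, 40), [True] * 40)
        slow = (rng.exponential(25, 40), [True] * 40)
        hr, _, _ = ps.mh_hazard_ratio(fast, slow)
        assert hr > 1.0

    def test_consistency_for_true_hr(self):
        rng = np.random.default_rng(0)
        n = 10000
        ta = rng.exponential(100 / np.log(2), n)
        tb = rng.exponential(340 / np.log(2), n)  # hazard ratio 3.4
        hr, _, _ = ps.mh_hazard_ratio((ta, [True] * n), (tb, [True] * n))
        assert 3.0 <= hr <= 3.8

    def test_no_events_in_one_group_is_error(self):
        with pytest.raises(ValidationError):
            ps.mh_hazard_ratio(([1, 2], [True, True]), ([3], [False]))


class TestAvpcMs:
    def test_two_altered_genes_flagged(self):
        assert ps.avpc_ms({"TP53": "mutated", "PTEN": "deleted", "RB1": "wildtype"})

    def test_single_alteration_not_flagged(self):
        assert not ps.avpc_ms({"TP53": "mutated", "PTEN": "wildtype", "RB1": "wildtype"})

    def test_mutated_and_deleted_counts_once(self):
        assert not ps.avpc_ms(
            {"TP53": "mutated_and_deleted", "PTEN": "wildtype", "RB1": "wildtype"}
        )

    def test_missing_status_is_error(self):
        with pytest.raises(ValidationError, match="RB1"):
            ps.avpc_ms({"TP53": "mutated", "PTEN": "deleted"})


class TestEnrichmentScan:
    def test_perfectly_aligned_feature_strongly_enriched(self):
        labels = pd.Series(["A"] * 50 + ["B"] * 50, index=[f"s{i}" for i in range(100)])
        feats = pd.DataFrame({"flag": (labels == "A").astype(int)})
        out = ps.enrichment_scan(labels, feats)
        assert out["bh_q"].iloc[0] < 1e-10

    def test_single_feature_q_equals_p(self):
        rng = np.random.default_rng(0)
        labels = pd.Series(rng.choice(["A", "B"], 60), index=[f"s{i}" for i in range(60)])
        feats = pd.DataFrame({"f": rng.choice([0, 1], 60)}, index=labels.index)
        out = ps.enrichment_scan(labels, feats)
        assert out["bh_q"].iloc[0] == pytest.approx(out["chi2_p"].iloc[0])

    def test_constant_feature_skipped(self):
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=[f"s{i}" for i in range(10)])
        feats = pd.DataFrame({"const": [1] * 10}, index=labels.index)
        out = ps.enrichment_scan(labels, feats)
        assert len(out) == 0

    def test_bh_false_positive_control(self):
        rng = np.random.default_rng(1)
        labels = pd.Series(rng.choice(["A", "B"], 80), index=[f"s{i}" for i in range(80)])
        hits = 0
        reps = 200
        for _ in range(reps):
            feats = pd.DataFrame(
                rng.choice([0, 1], size=(80, 5)), index=labels.index,
                columns=[f"f{j}" for j in range(5)],
            )
            out = ps.enrichment_scan(labels, feats)
            hits += int((out["bh_q"] < 0.05).any())
        assert hits / reps <= 0.10  # FDR 0.05 with binomial slack

    def test_q_at_least_p(self):
        rng = np.random.default_rng(2)
        labels = pd.Series(rng.choice(["A", "B"], 50), index=[f"s{i}" for i in range(50)])
        feats = pd.DataFrame(
            rng.choice([0, 1], size=(50, 8)), index=labels.index,
            columns=[f"f{j}" for j in range(8)],
        )
        out = ps.enrichment_scan(labels, feats)
        assert (out["bh_q"] >= out["chi2_p"] - 1e-12).all()
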