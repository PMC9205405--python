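"""Rates, decision rules, exact binomial CIs, regression and the
logistic-regression baseline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from snnhfo.clinical_stats import (
    LR_WEIGHTS,
    clopper_pearson,
    confusion_metrics,
    hfo_area,
    hfo_rate,
    lr_baseline_score,
    predict_epilepsy_scalp,
    predict_outcome_ecog,
    predict_outcome_ieeg,
    rate_seizure_regression,
    snr,
)
from snnhfo.event_detection import HFOEvent


def _events(n, status="HFO"):
    return [HFOEvent("ch0", i * 0.1, i * 0.1 + 0.015, 1, status)
            for i in range(n)]


class TestRates:
    def test_zero_events(self):
        assert hfo_rate([], 5.0) == 0.0

    def test_rate_is_count_over_minutes(self):
        assert hfo_rate(_events(12), 4.0) == pytest.approx(3.0)

    def test_only_accepted_events_counted(self):
        evs = _events(6) + _events(4, status="rejected_artifact")
        assert hfo_rate(evs, 2.0) == pytest.approx(3.0)

    def test_nonpositive_duration(self):
        with pytest.raises(ValueError):
            hfo_rate(_events(1), 0.0)


class TestHfoArea:
    def test_all_equal_rates_empty_area(self):
        assert hfo_area({f"c{i}": 2.0 for i in range(10)}) == set()

    def test_single_hot_channel(self):
        rates = {f"c{i}": 0.0 for i in range(19)}
        rates["hot"] = 10.0
        assert hfo_area(rates) == {"hot"}

    def test_area_shrinks_with_percentile(self):
        rng = np.random.default_rng(0)
        rates = pd.Series(rng.exponential(2.0, 40),
                          index=[f"c{i}" for i in range(40)])
        a90 = hfo_area(rates, 90)
        a95 = hfo_area(rates, 95)
        a99 = hfo_area(rates, 99)
        assert a99 <= a95 <= a90
        assert a95 <= set(rates.index)

    def test_needs_two_channels(self):
        with pytest.raises(ValueError):
            hfo_area({"only": 1.0})


class TestDecisionRules:
    def test_empty_area_always_resected_outcome_free_is_tn(self):
        assert predict_outcome_ieeg(set(), {"AR1-2"}, "seizure_free") == "TN"

    def test_unresected_area_with_recurrence_is_tp(self):
        assert predict_outcome_ieeg({"A"}, {"B", "C"}, "recurrence") == "TP"

    def test_fully_resected_area_with_recurrence_is_fn(self):
        assert predict_outcome_ieeg({"A"}, {"A", "B"}, "recurrence") == "FN"

    def test_unresected_area_but_seizure_free_is_fp(self):
        assert predict_outcome_ieeg({"A"}, set(), "seizure_free") == "FP"

    def test_unknown_outcome(self):
        with pytest.raises(ValueError):
            predict_outcome_ieeg(set(), set(), "cured")

    def test_ecog_residual_rate_rule(self):
        assert predict_outcome_ecog({"a": 0.0, "b": 0.0}) == "seizure_free"
        assert predict_outcome_ecog({"a": 0.2, "b": 1.3}) == "recurrence"
        assert predict_outcome_ecog({"a": 0.9}) == "seizure_free"
        with pytest.raises(ValueError):
            predict_outcome_ecog({})

    def test_scalp_median_rate_rule(self):
        assert predict_epilepsy_scalp({"c1": 0.0, "c2": 0.0}) == "seizure_free"
        assert predict_epilepsy_scalp(
            {"c1": 0.1, "c2": 0.3, "c3": 0.5}) == "active_epilepsy"
        # median 0.25 is not > 0.25
        assert predict_epilepsy_scalp({"c1": 0.25}) == "seizure_free"


class TestConfusion:
    def test_depth_electrode_cohort_metrics(self):
        """Nine surgical patients, one unresected-area recurrence (TP=1),
        six correctly predicted seizure-free (TN=6), two relapses under
        full resection (FN=2)."""
        s = confusion_metrics(TP=1, TN=6, FP=0, FN=2)
        r = s.rounded()
        assert r["accuracy"] == (78, 40, 97)
        assert r["specificity"] == (100, 54, 100)
        assert r["sensitivity"] == (33, 1, 91)
        assert r["npv"] == (75, 35, 97)
        assert r["ppv"] == (100, 3, 100)

    def test_perfect_classifier(self):
        s = confusion_metrics(TP=5, TN=5, FP=0, FN=0)
        assert all(v[0] == 100 for v in s.rounded().values())

    def test_specificity_six_of_six_lower_bound(self):
        lo, hi = clopper_pearson(6, 6)
        assert lo == pytest.approx(0.025 ** (1 / 6), abs=1e-12)
        assert round(100 * lo) == 54
        assert hi == 1.0

    def test_ten_of_ten_lower_bound(self):
        lo, _ = clopper_pearson(10, 10)
        assert round(100 * lo) == 69

    def test_zero_denominator_metric_undefined(self):
        s = confusion_metrics(TP=0, TN=6, FP=0, FN=0)
        assert s.metrics["sensitivity"] is None
        assert s.metrics["ppv"] is None
        assert "sensitivity: –" in s.render()

    def test_exhaustive_small_cohorts_match_beta_quantiles(self):
        """For every confusion table with N <= 6, each metric and its CI
        equal the direct Beta-quantile formulas."""
        alpha = 0.05
        for tp, tn, fp, fn in itertools.product(range(4), repeat=4):
            if not 0 < tp + tn + fp + fn <= 6:
                continue
            s = confusion_metrics(tp, tn, fp, fn)
            for name, (x, n) in s.fractions.items():
                if n == 0:
                    assert s.metrics[name] is None
                    continue
                point, lo, hi = s.metrics[name]
                assert point == pytest.approx(100 * x / n)
                exp_lo = 0.0 if x == 0 else sstats.beta.ppf(
                    alpha / 2, x, n - x + 1)
                exp_hi = 1.0 if x == n else sstats.beta.ppf(
                    1 - alpha / 2, x + 1, n - x)
                assert lo == pytest.approx(100 * exp_lo, abs=1e-10)
                assert hi == pytest.approx(100 * exp_hi, abs=1e-10)

    def test_closed_form_boundaries(self):
        for n in (1, 6, 8, 10):
            lo, hi = clopper_pearson(n, n)
            assert lo == pytest.approx(0.025 ** (1 / n), abs=1e-12)
            lo0, hi0 = clopper_pearson(0, n)
            assert hi0 == pytest.approx(1 - 0.025 ** (1 / n), abs=1e-12)
            assert lo0 == 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 2)
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestCohortSelfConsistency:
    def test_rule_consistent_cohort_has_no_false_positives(self):
        """Patients generated to satisfy the resection rule exactly are
        classified without false positives."""
        rng = np.random.default_rng(1)
        counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for k in range(12):
            channels = [f"c{i}" for i in range(20)]
            rates = pd.Series(rng.exponential(0.5, 20), index=channels)
            hot = f"c{k % 20}"
            rates[hot] = 30.0
            area = hfo_area(rates)
            resect_area = k % 3 != 0  # two thirds get the area removed
            resected = set(channels) - (set() if resect_area else area)
            outcome = "seizure_free" if resect_area else "recurrence"
            counts[predict_outcome_ieeg(area, resected, outcome)] += 1
        assert counts["FP"] == 0
        assert counts["FN"] == 0
        assert counts["TP"] + counts["TN"] == 12


class TestRegression:
    def test_noiseless_power_law_recovered_exactly(self):
        rates = np.array([0.3, 1.0, 3.0, 8.0, 20.0])
        freq = 10 ** 0.7 * rates ** 2.27
        out = rate_seizure_regression(rates, freq)
        assert out["slope"] == pytest.approx(2.27, abs=1e-12)
        assert out["intercept"] == pytest.approx(0.7, abs=1e-12)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_monotone_pairs_give_unit_spearman(self):
        out = rate_seizure_regression(np.array([1, 2, 4, 9.0]),
                                      np.array([2, 5, 6, 30.0]))
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(42)
        rates = 10 ** rng.uniform(-1, 1.5, 100)
        logf = 2.27 * np.log10(rates) + 0.7 + rng.normal(0, 0.2, 100)
        out = rate_seizure_regression(rates, 10 ** logf)
        assert abs(out["slope"] - 2.27) < 0.1
        assert out["n_used"] == 100

    def test_zero_pairs_excluded_and_counted(self):
        out = rate_seizure_regression(np.array([0.0, 1, 2, 4.0]),
                                      np.array([5.0, 2, 5, 20.0]))
        assert out["n_used"] == 3
        assert out["n_excluded"] == 1

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            rate_seizure_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestSnr:
    def test_event_identical_to_background_is_unity(self):
        fs = 2000.0
        t = np.arange(int(3 * fs)) / fs
        x = np.sin(2 * np.pi * 130 * t)
        ratio = snr(x, fs, np.array([[1.0, 1.5]]))[0]
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_flank_shrunk_at_edge_with_warning(self):
        fs = 2000.0
        x = np.random.default_rng(0).normal(size=int(1 * fs))
        with pytest.warns(UserWarning, match="flank"):
            out = snr(x, fs, np.array([[0.05, 0.3]]))
        assert out.size == 1 and out[0] > 0


class TestLrBaseline:
    def test_silent_trains_zero_scores(self):
        out = lr_baseline_score([np.array([])] * 4, duration=0.5)
        assert np.all(out["score"] == 0.0)
        assert not out["label"].any()

    def test_window_layout_45ms_with_10ms_overlap(self):
        out = lr_baseline_score([np.array([])] * 4, duration=0.115)
        np.testing.assert_allclose(out["start_s"], [0.0, 0.035, 0.070])
        np.testing.assert_allclose(out["end_s"] - out["start_s"], 0.045)

    def test_score_is_weighted_sum_of_rates(self):
        # one 45 ms window; 9 spikes per train -> 200 spikes/s each
        trains = [np.linspace(0.001, 0.044, 9)] * 4
        out = lr_baseline_score(trains, duration=0.045)
        assert len(out) == 1
        assert out.loc[0, "score"] == pytest.approx(200 * sum(LR_WEIGHTS))

    def test_weight_ordering_dn_ripple_dominates(self):
        w_upr, w_dnr, w_upfr, w_dnfr = LR_WEIGHTS
        assert w_dnr > w_upr > w_upfr
        assert w_dnfr > w_upfr

    def test_window_longer_than_recording(self):
        with pytest.raises(ValueError):
            lr_baseline_score([np.array([])] * 4, duration=0.01)
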