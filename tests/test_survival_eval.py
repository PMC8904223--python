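"""Metric correctness against brute-force oracles and library cross-checks."""

import numpy as np
import pandas as pd
import pytest

from serap import (
    auc_t,
    binary_outcome_at,
    bootstrap_ci,
    classification_at_cutoff,
    evaluate_many,
    harrell_c,
    iauc,
    km_estimate,
    logrank_test,
    optimal_cutoff,
)
from serap.survival_eval import UndefinedMetricError

from conftest import brute_auc_t, brute_harrell_c, brute_iauc, brute_km


class TestHarrellC:
    def test_perfect_concordance(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        scores = np.array([4.0, 3.0, 2.0, 1.0])  # higher score, earlier event
        assert harrell_c(scores, times, np.ones(4, int)) == 1.0

    def test_constant_scores_give_half(self):
        times = np.array([1.0, 2.0, 3.0])
        assert harrell_c(np.zeros(3), times, np.ones(3, int)) == 0.5

    def test_matches_brute_force_enumeration(self, random_survival_instance):
        for seed in range(10):
            s, t, e = random_survival_instance(50, seed)
            assert harrell_c(s, t, e) == pytest.approx(
                brute_harrell_c(s, t, e), abs=1e-12)

    def test_cross_check_against_scikit_survival(self, random_survival_instance):
        from sksurv.metrics import concordance_index_censored
        s, t, e = random_survival_instance(80, seed=42)
        ours = harrell_c(s, t, e)
        theirs = concordance_index_censored(e.astype(bool), t, s)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(UndefinedMetricError):
            harrell_c(np.array([1.0, 2.0]), np.array([5.0, 5.0]),
                      np.array([0, 0]))

    def test_invariant_under_monotone_transform(self, random_survival_instance):
        s, t, e = random_survival_instance(60, seed=7)
        assert harrell_c(s, t, e) == pytest.approx(
            harrell_c(np.exp(s), t, e), abs=1e-12)


class TestAucT:
    def test_perfect_separation(self):
        times = np.array([5.0, 10.0, 90.0, 90.0])
        events = np.array([1, 1, 0, 0])
        scores = np.array([9.0, 8.0, 1.0, 2.0])
        assert auc_t(scores, times, events, 30) == 1.0

    def test_constant_scores_give_half(self):
        times = np.array([5.0, 90.0])
        events = np.array([1, 0])
        assert auc_t(np.zeros(2), times, events, 30) == 0.5

    def test_matches_brute_force_enumeration(self, random_survival_instance):
        for seed in range(10):
            s, t, e = random_survival_instance(50, seed)
            for horizon in (5, 10, 15):
                try:
                    expected = brute_auc_t(s, t, e, horizon)
                except ValueError:
                    continue
                assert auc_t(s, t, e, horizon) == pytest.approx(
                    expected, abs=1e-12)

    def test_undefined_without_cases_or_controls(self):
        with pytest.raises(UndefinedMetricError):
            auc_t(np.array([1.0, 2.0]), np.array([90.0, 90.0]),
                  np.array([0, 0]), 30)

    def test_invariant_under_monotone_transform(self, random_survival_instance):
        s, t, e = random_survival_instance(60, seed=11)
        assert auc_t(s, t, e, 10) == pytest.approx(
            auc_t(3 * s + 7, t, e, 10), abs=1e-12)


class TestIauc:
    def test_constant_auc_window_average(self):
        # perfectly separating scores: AUC(t) = 1 at every event time
        times = np.array([5.0, 20.0, 90.0, 90.0, 90.0])
        events = np.array([1, 1, 0, 0, 0])
        scores = np.array([9.0, 8.0, 1.0, 2.0, 3.0])
        assert iauc(scores, times, events, 1, 90) == 1.0

    def test_two_event_times_equal_weights(self):
        # one event at t=3 and one at t=6, plus shared controls:
        # iAUC must be the plain average of the two AUC values
        times = np.array([3.0, 6.0, 90.0, 90.0])
        events = np.array([1, 1, 0, 0])
        scores = np.array([5.0, 1.5, 1.0, 2.0])
        a = auc_t(scores, times, events, 3)
        b = auc_t(scores, times, events, 6)
        assert iauc(scores, times, events, 1, 90) == pytest.approx((a + b) / 2)

    def test_matches_direct_summation_oracle(self, random_survival_instance):
        s, t, e = random_survival_instance(200, seed=3)
        assert iauc(s, t, e, 1, 19) == pytest.approx(
            brute_iauc(s, t, e, 1, 19), abs=1e-10)

    def test_bounded_by_auc_range(self, random_survival_instance):
        s, t, e = random_survival_instance(150, seed=9)
        aucs = []
        for tk in np.unique(t[(e == 1)]):
            try:
                aucs.append(auc_t(s, t, e, tk))
            except UndefinedMetricError:
                pass
        val = iauc(s, t, e, 1, 90)
        assert min(aucs) - 1e-12 <= val <= max(aucs) + 1e-12

    def test_no_events_in_window_raises(self):
        with pytest.raises(UndefinedMetricError):
            iauc(np.array([1.0, 2.0]), np.array([90.0, 90.0]),
                 np.array([0, 0]), 1, 90)


class TestBootstrapCI:
    def test_constant_metric_degenerate_interval(self):
        est = bootstrap_ci(lambda d: 7.0, np.arange(10), B=50, seed=1)
        assert est.point == est.lower == est.upper == 7.0

    def test_same_seed_identical(self):
        data = np.random.default_rng(0).normal(size=40)
        a = bootstrap_ci(np.mean, data, B=100, seed=5)
        b = bootstrap_ci(np.mean, data, B=100, seed=5)
        assert a == b

    def test_mostly_undefined_metric_refused(self):
        # defined on the full sample (all values distinct) but undefined on
        # virtually every bootstrap resample (duplicates appear)
        def needs_distinct(d):
            if len(np.unique(d)) != len(d):
                raise UndefinedMetricError("duplicate values")
            return float(np.mean(d))
        with pytest.raises(UndefinedMetricError, match="resamples"):
            bootstrap_ci(needs_distinct, np.arange(10), B=20, seed=0)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.0) == pytest.approx(1 / 3)
        assert km(2.5) == pytest.approx(1 / 3)  # right-continuous step
        assert km(0.0) == 1.0

    def test_no_events_survival_stays_one(self):
        km = km_estimate([5.0, 10.0, 20.0], [0, 0, 0])
        assert km(90.0) == 1.0

    def test_all_events_at_one_drop_to_zero(self):
        km = km_estimate([1.0, 1.0, 1.0], [1, 1, 1])
        assert km(1.0) == 0.0

    def test_without_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(4)
        times = rng.integers(1, 30, 100).astype(float)
        km = km_estimate(times, np.ones(100, int))
        for t in (1, 5, 10, 29):
            assert km(float(t)) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_hand_oracle_with_censoring(self):
        rng = np.random.default_rng(8)
        times = rng.integers(1, 15, 60).astype(float)
        events = rng.integers(0, 2, 60)
        km = km_estimate(times, events)
        for tk, s in brute_km(times, events):
            assert km(tk) == pytest.approx(s, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_duplicated_data_yields_null(self):
        times = np.r_[np.arange(1, 21), np.arange(1, 21)].astype(float)
        events = np.r_[np.ones(20), np.ones(20)].astype(int)
        group = np.r_[np.zeros(20), np.ones(20)]
        stat, p = logrank_test(times, events, group)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_complete_separation_significant_at_n40(self):
        times = np.r_[np.arange(1, 21), np.arange(40, 60)].astype(float)
        events = np.ones(40, int)
        group = np.r_[np.zeros(20), np.ones(20)]
        _, p = logrank_test(times, events, group)
        assert p < 0.05

    def test_statistic_invariant_to_label_permutation(self):
        rng = np.random.default_rng(2)
        times = rng.integers(1, 30, 50).astype(float)
        events = rng.integers(0, 2, 50)
        group = rng.integers(0, 2, 50)
        s1, _ = logrank_test(times, events, group)
        s2, _ = logrank_test(times, events, 1 - group)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_pvalue_agrees_with_permutation_null_at_small_n(self):
        rng = np.random.default_rng(6)
        n = 30
        times = rng.integers(1, 20, n).astype(float)
        events = rng.integers(0, 2, n)
        group = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
        stat, p = logrank_test(times, events, group)
        perm_stats = []
        for _ in range(400):
            g = rng.permutation(group)
            s, _ = logrank_test(times, events, g)
            perm_stats.append(s)
        p_perm = np.mean(np.asarray(perm_stats) >= stat)
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 400)
        assert abs(p - p_perm) <= max(4 * se, 0.05)


class TestBinaryOutcome:
    def test_contract_cases(self):
        times = np.array([10.0, 90.0, 20.0])
        events = np.array([1, 0, 0])
        out = binary_outcome_at(times, events, 30)
        assert out.n_excluded == 1
        np.testing.assert_array_equal(out.mask, [True, True, False])
        np.testing.assert_array_equal(out.labels, [1, 0])

    def test_censored_exactly_at_horizon_is_negative(self):
        out = binary_outcome_at(np.array([30.0]), np.array([0]), 30)
        assert out.n_excluded == 0 and out.labels[0] == 0


class TestOptimalCutoff:
    def test_textbook_example(self):
        cut = optimal_cutoff(np.array([1.0, 2.0, 3.0, 4.0]),
                             np.array([0, 0, 1, 1]))
        assert cut == 3.0

    def test_perfect_separation_returns_lowest_zero_distance_threshold(self):
        cut = optimal_cutoff(np.array([1.0, 2.0, 10.0, 11.0]),
                             np.array([0, 0, 1, 1]))
        assert cut == 10.0

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            scores = rng.integers(0, 15, 100).astype(float)
            labels = rng.integers(0, 2, 100)
            if labels.min() == labels.max():
                continue
            best, best_d = None, np.inf
            for c in sorted(set(scores)):
                sens = np.mean(scores[labels == 1] >= c)
                spec = np.mean(scores[labels == 0] < c)
                d = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
                if d < best_d - 1e-15:
                    best, best_d = c, d
            assert optimal_cutoff(scores, labels) == best

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff(np.array([1.0, 2.0]), np.array([1, 1]))


class TestClassification:
    def test_hand_confusion_matrix(self):
        # TP=3 FP=1 FN=1 TN=5 at cutoff 5
        scores = np.array([5, 6, 7, 5, 1, 2, 3, 4, 0, 1], dtype=float)
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        blk = classification_at_cutoff(scores, labels, 5.0)
        assert (blk.tp, blk.fp, blk.fn, blk.tn) == (3, 1, 1, 5)
        assert blk.sensitivity.point == pytest.approx(0.75)
        assert blk.specificity.point == pytest.approx(5 / 6)
        assert blk.ppv.point == pytest.approx(0.75)
        assert blk.npv.point == pytest.approx(5 / 6)
        assert blk.lr_positive.point == pytest.approx(0.75 / (1 - 5 / 6))
        assert blk.lr_negative.point == pytest.approx((1 - 0.75) / (5 / 6))

    def test_cutoff_below_all_scores(self):
        scores = np.array([1.0, 2.0, 3.0])
        labels = np.array([1, 0, 1])
        blk = classification_at_cutoff(scores, labels, 0.0)
        assert blk.sensitivity.point == 1.0
        assert blk.specificity.point == 0.0
        # everything predicted positive: TN+FN = 0, so NPV and LR- are undefined
        assert "npv" in blk.undefined and np.isnan(blk.npv.point)
        assert "lr_negative" in blk.undefined

    def test_perfect_classifier(self):
        scores = np.array([1.0, 2.0, 9.0, 8.0])
        labels = np.array([0, 0, 1, 1])
        blk = classification_at_cutoff(scores, labels, 8.0)
        assert blk.sensitivity.point == 1.0 and blk.specificity.point == 1.0


class TestEvaluateMany:
    def test_shared_resamples_and_report_shape(self, random_survival_instance):
        s, t, e = random_survival_instance(120, seed=21)
        reports, digest = evaluate_many({"a": s, "b": s + 1}, t, e,
                                        horizons=(5, 10), B=25, seed=3)
        # b is a monotone transform of a: identical rank metrics, same resamples
        assert reports["a"].cindex.point == pytest.approx(
            reports["b"].cindex.point, abs=1e-12)
        assert reports["a"].iauc.point == pytest.approx(
            reports["b"].iauc.point, abs=1e-12)
        assert len(digest) == 64
        for rep in reports.values():
            assert rep.iauc.lower <= rep.iauc.point <= rep.iauc.upper
            assert 0 <= rep.cindex.point <= 1
            frame = rep.to_frame()
            assert {"metric", "point", "ci_lower", "ci_upper"} <= set(frame.columns)
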