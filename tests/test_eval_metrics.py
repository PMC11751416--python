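"""Censored-data metrics: hand-computed cases, brute-force equivalence,
invariances, and cross-checks against lifelines/scikit-learn."""

import numpy as np
import pytest

from _oracles import brute_force_auroc, brute_force_cindex
from conftest import make_labels, random_censored_labels
from ecgsurv.eval_metrics import (
    auroc, bootstrap_ci, calibration_gap, km_curve,
    log_rank_test, time_dependent_cindex,
)


def constant_cif(scores):
    return np.tile(np.asarray(scores, dtype=float)[:, None], (1, 12))


class TestTimeDependentCindex:
    def test_three_subject_hand_case(self):
        # A events in bin 0, C events in bin 2, B censored in bin 5.
        # Pairs: (A,B) F_A(0)=0.9>0.1, (A,C) 0.9>0.5, (C,B) 0.7>0.2 -> 1.0
        F = np.zeros((3, 12))
        F[0] = np.linspace(0.9, 1.0, 12)            # A
        F[1] = np.linspace(0.1, 0.2, 12)            # B
        F[2, :] = [0.5, 0.6, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7]
        labels = make_labels([0.5, 5.5, 2.5], [1, 0, 1])
        assert time_dependent_cindex(F, labels) == 1.0

    def test_identical_predictions_give_half(self):
        labels = make_labels([1.5, 3.5, 7.0, 12.0], [1, 1, 1, 0])
        assert time_dependent_cindex(constant_cif([0.4] * 4), labels) == 0.5

    def test_reversed_ordering_gives_zero(self):
        labels = make_labels([1.5, 3.5, 7.0, 9.0], [1, 1, 1, 1])
        # risk increasing with survival time = fully anti-concordant
        assert time_dependent_cindex(
            constant_cif([0.1, 0.2, 0.3, 0.4]), labels) == 0.0

    def test_matches_brute_force_on_random_censored_data(self, rng):
        for _ in range(10):
            labels = random_censored_labels(rng, 120)
            F = np.sort(rng.random((120, 12)), axis=1)
            assert time_dependent_cindex(F, labels) == pytest.approx(
                brute_force_cindex(F, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        labels = random_censored_labels(rng, 80)
        F = np.sort(rng.random((80, 12)), axis=1)
        a = time_dependent_cindex(F, labels)
        b = time_dependent_cindex(np.exp(3.0 * F) - 0.5, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        labels = make_labels([5.0, 5.2], [0, 0])
        with pytest.raises(ValueError):
            time_dependent_cindex(constant_cif([0.1, 0.9]), labels)


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        res = bootstrap_ci(lambda idx: 0.7, 20, n_boot=50, seed=1)
        assert res.ci_low == res.ci_high == res.point == 0.7

    def test_same_seed_identical_interval(self, rng):
        data = rng.normal(size=30)

        def metric(idx):
            return float(np.mean(data[idx]))

        a = bootstrap_ci(metric, 30, n_boot=100, seed=5)
        b = bootstrap_ci(metric, 30, n_boot=100, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_cindex_interval_contains_point_estimate(self, rng):
        labels = random_censored_labels(rng, 200)
        F = np.sort(rng.random((200, 12)), axis=1)

        def metric(idx):
            return time_dependent_cindex(F[idx], [labels[i] for i in idx])

        res = bootstrap_ci(metric, 200, n_boot=100, seed=3)
        assert res.ci_low <= res.point <= res.ci_high

    def test_patient_level_resampling_keeps_records_together(self):
        ids = ["p1", "p1", "p2", "p3", "p3", "p3"]
        seen = []

        def metric(idx):
            seen.append(np.sort(idx))
            return 0.0

        bootstrap_ci(metric, ids, n_boot=20, seed=2)
        counts = {tuple(np.sort(s)) for s in seen[1:]}
        for pick in counts:
            # records 0,1 (p1) and 2 (p2) and 3,4,5 (p3) travel as blocks
            arr = np.array(pick)
            assert np.isin(arr, [0, 1]).sum() % 2 == 0
            assert np.isin(arr, [3, 4, 5]).sum() % 3 == 0


class TestKaplanMeier:
    def test_three_subject_hand_case(self):
        # times (1,2,3), events (1,0,1): S = 2/3, 2/3, 0
        km = km_curve(make_labels([1.0, 2.0, 3.0], [1, 0, 1]))
        assert np.allclose(km.event_times, [1.0, 3.0])
        assert np.allclose(km.survival, [2 / 3, 0.0])
        assert km.evaluate(2.5) == pytest.approx(2 / 3)

    def test_no_events_survival_is_one(self):
        km = km_curve(make_labels([2.0, 5.0, 9.0], [0, 0, 0]))
        assert km.evaluate(12.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = np.sort(rng.uniform(0.5, 12.0, 25))
        km = km_curve(make_labels(times, np.ones(25)))
        for i, t in enumerate(times):
            assert km.evaluate(t) == pytest.approx(1 - (i + 1) / 25)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        labels = random_censored_labels(rng, 150)
        km = km_curve(labels)
        kmf = KaplanMeierFitter().fit(
            [l.time_months for l in labels], [l.event for l in labels])
        grid = np.linspace(0.1, 12.0, 40)
        ours = km.evaluate(grid)
        theirs = kmf.predict(grid).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-12)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = make_labels([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        stat, p = log_rank_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        early = make_labels(rng.uniform(0.5, 3.0, 200), np.ones(200))
        late = make_labels(rng.uniform(8.0, 12.0, 200), np.ones(200))
        stat, p = log_rank_test(early, late)
        assert p < 0.001

    def test_symmetric_in_group_order(self, rng):
        a = random_censored_labels(rng, 60)
        b = random_censored_labels(rng, 80)
        assert log_rank_test(a, b)[0] == pytest.approx(
            log_rank_test(b, a)[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test([], make_labels([1.0], [1]))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_point_hand_case(self):
        assert auroc([0.9, 0.4, 0.6, 0.2], [1, 0, 1, 0]) == 1.0

    def test_matches_exhaustive_pair_count(self, rng):
        scores = rng.random(50).round(1)     # force ties
        labels = rng.integers(0, 2, 50)
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_equals_cindex_for_binary_uncensored_outcome(self, rng):
        """Two distinct event times and no censoring reduce the
        time-dependent C-index to the AUROC of early-vs-late."""
        n = 40
        early = rng.integers(0, 2, n)
        times = np.where(early, 1.5, 8.5)
        scores = rng.random(n)
        labels = make_labels(times, np.ones(n))
        c = time_dependent_cindex(constant_cif(scores), labels)
        a = auroc(scores, early)
        assert c == pytest.approx(a, abs=1e-12)


class TestCalibrationGap:
    def test_exact_match_gives_zero(self, rng):
        labels = random_censored_labels(rng, 100)
        km = km_curve(labels)
        s = km.evaluate(np.arange(1.0, 13.0))
        assert calibration_gap(s, km) == 0.0

    def test_constant_offset_recovered(self, rng):
        labels = random_censored_labels(rng, 100)
        km = km_curve(labels)
        s = km.evaluate(np.arange(1.0, 13.0))
        assert calibration_gap(s + 0.03, km) == pytest.approx(0.03)

    def test_wrong_length_rejected(self, rng):
        km = km_curve(random_censored_labels(rng, 10))
        with pytest.raises(ValueError):
            calibration_gap(np.ones(10), km)
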