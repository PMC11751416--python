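"""The waveform/survival simulator: shape and rate contracts, seeded
determinism, hazard-model structure, and censoring behaviour."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from _oracles import brute_force_cindex
from ecgsurv.synthetic_ecg import (
    RECORD_SAMPLES, SAMPLING_RATE, BeatParams, SimConfig, SimulatedCohort,
    null_config, oracle_concordance, simulate_cohort, simulate_waveform,
)


class TestSimulateWaveform:
    def test_shape_is_12_by_5000(self):
        w = simulate_waveform(BeatParams(), seed=0)
        assert w.shape == (12, RECORD_SAMPLES)
        assert SAMPLING_RATE == 500

    @pytest.mark.parametrize("seed", [0, 1, 5])
    def test_r_peak_count_at_60_bpm(self, seed):
        """At 60 bpm a 10 s trace holds 9-11 R peaks (edge beats clip)."""
        params = BeatParams(heart_rate=60, noise_sd=0.0,
                            baseline_wander_amp=0.0)
        w = simulate_waveform(params, seed=seed)
        lead_ii = w[1]
        thresh = 0.5 * lead_ii.max()
        above = lead_ii > thresh
        onsets = np.sum(above[1:] & ~above[:-1])
        assert onsets in {9, 10, 11}

    def test_seeded_determinism_bitwise(self):
        p = BeatParams()
        assert np.array_equal(simulate_waveform(p, 42),
                              simulate_waveform(p, 42))
        assert not np.array_equal(simulate_waveform(p, 42),
                                  simulate_waveform(p, 43))

    def test_r_amplitude_scales_lead_ii(self):
        lo = simulate_waveform(BeatParams(r_amp=0.6, noise_sd=0.0,
                                          baseline_wander_amp=0.0), 0)
        hi = simulate_waveform(BeatParams(r_amp=1.6, noise_sd=0.0,
                                          baseline_wander_amp=0.0), 0)
        assert hi[1].max() > lo[1].max()

    @pytest.mark.parametrize("bad", [
        dict(heart_rate=20), dict(heart_rate=250), dict(noise_sd=-0.1),
        dict(r_amp=np.inf),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            BeatParams(**bad)


class TestSimulateCohort:
    def test_component_lengths_and_label_validity(self, small_cohort):
        c = small_cohort
        n = c.config.n_subjects
        assert len(c.records) == len(c.labels) == len(c.latent_risk) == n
        assert c.true_hazard.shape == (n, 12)
        for label in c.labels:
            assert label.time_months > 0
            assert label.event in (0, 1)

    def test_seeded_reproducibility_end_to_end(self):
        cfg = SimConfig(n_subjects=8, seed=99)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.latent_risk, b.latent_risk)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.signal, rb.signal)
        for la, lb in zip(a.labels, b.labels):
            assert la.time_months == lb.time_months and la.event == lb.event

    def test_null_effects_give_uncorrelated_times(self):
        """With zero effect sizes the would-be risk score (default-weight
        combination of morphology features) is uncorrelated with time."""
        from ecgsurv.synthetic_ecg import DEFAULT_EFFECT_SIZES, latent_risk
        c = simulate_cohort(null_config(SimConfig(n_subjects=2000, seed=5)))
        would_be_z = np.array([latent_risk(p, DEFAULT_EFFECT_SIZES)
                               for p in c.beat_params])
        times = np.array([l.time_months for l in c.labels])
        tau = kendalltau(would_be_z, times).statistic
        assert abs(tau) < 0.05

    def test_truncated_geometric_mean_event_bin(self):
        """With hazard 0.5/bin and no signal or censoring, the event bin is
        truncated-geometric: mean = sum_{k=0}^{11} k p(1-p)^k / (1-(1-p)^12)
        ~ 0.9795 for p = 0.5."""
        cfg = SimConfig(n_subjects=4000, seed=21, baseline_hazard=0.5,
                        censoring_rate=0.0,
                        effect_sizes={"r_amp": 0.0})
        c = simulate_cohort(cfg)
        bins = np.array([l.bin for l in c.labels])
        events = np.array([l.event for l in c.labels])
        p = 0.5
        k = np.arange(12)
        expected = np.sum(k * p * (1 - p) ** k) / (1 - (1 - p) ** 12)
        assert events.mean() > 0.99
        assert bins[events == 1].mean() == pytest.approx(expected, abs=0.08)

    def test_censoring_rate_near_target(self):
        c = simulate_cohort(SimConfig(n_subjects=2000, seed=3,
                                      censoring_rate=0.35))
        censored = 1.0 - np.mean([l.event for l in c.labels])
        assert abs(censored - 0.35) < 0.06

    def test_unattainable_censoring_warns(self):
        cfg = SimConfig(n_subjects=300, seed=4, baseline_hazard=0.01,
                        censoring_rate=0.2)
        with pytest.warns(UserWarning, match="censoring"):
            simulate_cohort(cfg)

    def test_monotone_risk_terciles(self):
        """Mean observed event time decreases from low- to high-risk
        tercile under the default strong effects."""
        c = simulate_cohort(SimConfig(n_subjects=1000, seed=13))
        z = c.latent_risk
        times = np.array([l.time_months for l in c.labels])
        events = np.array([l.event for l in c.labels])
        q = np.quantile(z, [1 / 3, 2 / 3])
        means = [times[(z <= q[0]) & (events == 1)].mean(),
                 times[(z > q[0]) & (z <= q[1]) & (events == 1)].mean(),
                 times[(z > q[1]) & (events == 1)].mean()]
        assert means[0] > means[1] > means[2]


class TestOracleConcordance:
    def test_null_cohort_is_chance_level(self):
        c = simulate_cohort(null_config(SimConfig(n_subjects=2000, seed=5)))
        assert 0.45 <= oracle_concordance(c) <= 0.55

    def test_hand_built_cohort_matches_pair_enumeration(self, small_cohort):
        c = small_cohort
        from scipy.special import expit
        F = np.tile(expit(c.latent_risk)[:, None], (1, 12))
        assert oracle_concordance(c) == pytest.approx(
            brute_force_cindex(F, c.labels))

    def test_perfect_ordering_gives_one(self):
        # deterministic times strictly decreasing in z, no censoring
        from conftest import make_labels
        from ecgsurv.synthetic_ecg import WaveformRecord
        z = np.array([-2.0, -0.5, 0.5, 2.0])
        times = 12.0 - 2.4 * (np.argsort(np.argsort(z)) + 1) + 0.2
        labels = make_labels(times, [1, 1, 1, 1])
        records = [WaveformRecord(f"r{i}", f"p{i}",
                                  np.datetime64("2020-01-01"),
                                  np.zeros((12, 10), np.float32))
                   for i in range(4)]
        cohort = SimulatedCohort(
            records=records, labels=labels, latent_risk=z,
            true_hazard=np.zeros((4, 12)), beat_params=[],
            config=SimConfig(n_subjects=4))
        assert oracle_concordance(cohort) == 1.0

    def test_too_few_subjects_rejected(self):
        c = simulate_cohort(SimConfig(n_subjects=1, seed=0))
        with pytest.raises(ValueError):
            oracle_concordance(c)
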