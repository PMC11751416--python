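"""Time discretisation, PMF/CIF algebra, and the likelihood + ranking loss:
closed-form values, invariants, and gradient correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_labels
from ecgsurv.discrete_survival import (
    LossConfig, SurvivalLabel, TimeGrid, assign_bin, labels_to_arrays,
    likelihood_loss, pmf_to_cif, ranking_loss, softmax_tensor, total_loss,
    total_loss_from_logits, validate_pmf,
)
from ecgsurv.nn.autograd import Tensor

UNIFORM = np.full(12, 1 / 12)


class TestAssignBin:
    @pytest.mark.parametrize("t,expected", [
        (0.5, 0), (1.0, 0), (1.001, 1), (3.0, 2), (11.2, 11), (12.0, 11),
    ])
    def test_half_open_monthly_bins(self, t, expected):
        assert assign_bin(t) == expected

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(0.0)

    def test_label_beyond_horizon_rejected(self):
        with pytest.raises(ValueError):
            SurvivalLabel("x", 12.5, 0)

    def test_grid_is_fixed_12_months(self):
        assert TimeGrid().edges[-1] == 12.0
        with pytest.raises(ValueError):
            TimeGrid(n_bins=10)


class TestPmfCif:
    def test_uniform_cumulative(self):
        cif = pmf_to_cif(UNIFORM)
        assert np.allclose(cif, np.arange(1, 13) / 12)

    def test_one_hot_is_step_function(self):
        p = np.zeros(12)
        p[3] = 1.0
        cif = pmf_to_cif(p)
        assert np.allclose(cif, [0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_cif_nondecreasing_and_normalised(self, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(12))
        cif = pmf_to_cif(p)
        assert np.all(np.diff(cif) >= -1e-12)
        assert math.isclose(cif[-1], 1.0, abs_tol=1e-6)

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError):
            validate_pmf(np.full(12, 0.2))
        with pytest.raises(ValueError):
            validate_pmf(np.ones(11) / 11)


class TestLikelihoodLoss:
    def test_event_uniform_pmf_is_ln12(self):
        label = SurvivalLabel("a", 4.5, 1)
        assert likelihood_loss(UNIFORM, label) == pytest.approx(
            math.log(12), abs=1e-6)

    def test_censored_bin3_uniform_pmf(self):
        # survivor mass over bins 3..11 is 9/12
        label = SurvivalLabel("a", 3.5, 0)
        assert likelihood_loss(UNIFORM, label) == pytest.approx(
            -math.log(0.75), abs=1e-6)

    def test_perfect_one_hot_event_is_zero(self):
        p = np.zeros(12)
        p[5] = 1.0
        assert likelihood_loss(p, SurvivalLabel("a", 5.5, 1)) == pytest.approx(
            0.0, abs=1e-6)

    def test_censored_last_bin_is_finite(self):
        # administratively censored subjects all land in bin 11
        label = SurvivalLabel("a", 12.0, 0)
        loss = likelihood_loss(UNIFORM, label)
        assert math.isfinite(loss)
        assert loss == pytest.approx(-math.log(1 / 12), abs=1e-6)

    @given(st.integers(0, 2 ** 32 - 1), st.integers(0, 11))
    @settings(max_examples=30, deadline=None)
    def test_one_hot_minimises_event_loss(self, seed, k):
        label = SurvivalLabel("a", k + 0.5, 1)
        one_hot = np.zeros(12)
        one_hot[k] = 1.0
        other = np.random.default_rng(seed).dirichlet(np.ones(12))
        assert (likelihood_loss(one_hot, label)
                <= likelihood_loss(other, label) + 1e-9)


class TestRankingLoss:
    def test_single_pair_closed_form(self):
        # F_i(k_i)=0.9, F_j(k_i)=0.1, sigma=0.1 -> exp(-8)
        Fi = np.zeros(12); Fi[0] = 0.9; Fi[-1] = 1.0
        Fj = np.zeros(12); Fj[0] = 0.1; Fj[-1] = 1.0
        labels = make_labels([0.5, 5.5], [1, 1])
        val = ranking_loss([np.maximum.accumulate(Fi),
                            np.maximum.accumulate(Fj)], labels, sigma=0.1)
        assert val == pytest.approx(math.exp(-8), rel=1e-9)

    def test_tied_pair_gives_unit_penalty(self):
        F = pmf_to_cif(UNIFORM)
        labels = make_labels([0.5, 5.5], [1, 1])
        assert ranking_loss([F, F], labels, sigma=0.1) == pytest.approx(1.0)

    def test_no_events_gives_zero(self):
        F = pmf_to_cif(UNIFORM)
        labels = make_labels([0.5, 5.5], [0, 0])
        assert ranking_loss([F, F], labels, sigma=0.1) == 0.0

    def test_monotone_in_risk_separation(self):
        labels = make_labels([0.5, 5.5], [1, 0])
        vals = []
        for fi in (0.2, 0.5, 0.8):
            Fi = np.clip(np.linspace(fi, 1, 12), 0, 1)
            Fj = np.clip(np.linspace(0.1, 1, 12), 0, 1)
            vals.append(ranking_loss([Fi, Fj], labels, sigma=0.1))
        assert vals[0] > vals[1] > vals[2]

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            ranking_loss([pmf_to_cif(UNIFORM)], make_labels([1.0], [1]),
                         sigma=0.0)


class TestTotalLoss:
    def test_alpha_zero_equals_mean_likelihood(self, rng):
        pmfs = [rng.dirichlet(np.ones(12)) for _ in range(5)]
        labels = make_labels([1.5, 3.0, 7.2, 9.9, 12.0], [1, 0, 1, 1, 0])
        expected = np.mean([likelihood_loss(p, l)
                            for p, l in zip(pmfs, labels)])
        assert total_loss(pmfs, labels, LossConfig(alpha=0.0)) == \
            pytest.approx(expected)

    def test_two_subject_perfect_prediction_closed_form(self):
        # perfect one-hots: likelihood ~0; single pair with
        # F_i(k_i)=1, F_j(k_i)=0 -> alpha * exp(-1/sigma)
        p1 = np.zeros(12); p1[2] = 1.0
        p2 = np.zeros(12); p2[8] = 1.0
        labels = make_labels([2.5, 8.5], [1, 1])
        cfg = LossConfig(alpha=0.5, sigma=0.25)
        got = total_loss([p1, p2], labels, cfg)
        assert got == pytest.approx(0.5 * math.exp(-4), abs=1e-6)

    def test_single_event_subject_is_likelihood_only(self):
        p = np.full(12, 1 / 12)
        labels = make_labels([3.5], [1])
        assert total_loss([p], labels) == pytest.approx(math.log(12),
                                                        abs=1e-6)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            total_loss([], [])

    def test_autograd_path_matches_closed_form(self, rng):
        logits = rng.normal(size=(6, 12))
        labels = make_labels([0.5, 2.5, 2.7, 6.0, 9.5, 12.0],
                             [1, 0, 1, 1, 0, 0])
        bins, events = labels_to_arrays(labels)
        cfg = LossConfig(alpha=0.3, sigma=0.2)
        tens = total_loss_from_logits(Tensor(logits), bins, events, cfg)
        pmfs = softmax_tensor(Tensor(logits)).data
        assert float(tens.data) == pytest.approx(
            total_loss(list(pmfs), labels, cfg), rel=1e-10)

    def test_gradient_matches_central_differences(self, rng):
        """Analytic gradient of the total loss on a 4-subject batch."""
        logits = rng.normal(size=(4, 12))
        labels = make_labels([0.5, 3.0, 6.2, 12.0], [1, 0, 1, 0])
        bins, events = labels_to_arrays(labels)
        cfg = LossConfig(alpha=0.1, sigma=0.1)
        t = Tensor(logits.copy(), requires_grad=True)
        total_loss_from_logits(t, bins, events, cfg).backward()
        eps = 1e-6
        num = np.zeros_like(logits)
        for i in range(4):
            for j in range(12):
                e = np.zeros_like(logits)
                e[i, j] = eps
                up = total_loss_from_logits(Tensor(logits + e), bins,
                                            events, cfg).data
                dn = total_loss_from_logits(Tensor(logits - e), bins,
                                            events, cfg).data
                num[i, j] = (up - dn) / (2 * eps)
        rel = np.abs(t.grad - num) / np.maximum(np.abs(num), 1e-8)
        assert rel.max() < 1e-4
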