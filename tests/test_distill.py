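"""Unit tests for the spiking ADS network simulation and learning rule."""

import numpy as np
import pytest

from adsnet.distill import (ADSNetworkParameters, FeedbackSchedule,
                            ads_weight_update, evaluate_ads, simulate_ads,
                            train_ads)
from adsnet.dynamics import TimeSeries
from adsnet.tasks import classify_xor
from adsnet.teacher import RateNetworkParameters


@pytest.fixture
def net(tiny_teacher):
    return ADSNetworkParameters.initialise(tiny_teacher, 24,
                                           np.random.default_rng(1))


def _zero_teacher(N_hat=8, d1=2, d2=1):
    """A teacher whose dynamics (and resting state) are identically zero."""
    return RateNetworkParameters(
        tau=np.full(N_hat, 50e-3), F_hat=np.zeros((N_hat, d1)),
        Omega_hat=np.zeros((N_hat, N_hat)), D_hat=np.zeros((d2, N_hat)),
        b=np.zeros(N_hat))


class TestWeightUpdate:
    def test_hand_computed_outer_product(self):
        """N=2, N_hat=1, F=[[1,-1]], e=[0.5], r=[1,0], eta=1 gives
        delta = [[0.5, 0], [-0.5, 0]]."""
        out = ads_weight_update(np.zeros((2, 2)), r=np.array([1.0, 0.0]),
                                e=np.array([0.5]), F=np.array([[1.0, -1.0]]),
                                eta=1.0)
        np.testing.assert_allclose(out, [[0.5, 0.0], [-0.5, 0.0]])

    def test_zero_error_or_zero_trace_is_noop(self):
        F = np.random.default_rng(0).standard_normal((3, 5))
        W = np.random.default_rng(1).standard_normal((5, 5))
        out = ads_weight_update(W, np.ones(5), np.zeros(3), F, 0.1)
        np.testing.assert_array_equal(out, W)
        out = ads_weight_update(W, np.zeros(5), np.ones(3), F, 0.1)
        np.testing.assert_array_equal(out, W)

    def test_input_not_mutated(self):
        W = np.zeros((2, 2))
        ads_weight_update(W, np.ones(2), np.ones(1), np.ones((1, 2)), 1.0)
        np.testing.assert_array_equal(W, 0)


class TestSimulateADS:
    def test_zero_input_zero_baseline_is_silent(self):
        teacher = _zero_teacher()
        net = ADSNetworkParameters.initialise(teacher, 24,
                                              np.random.default_rng(2))
        c = TimeSeries(np.zeros((2, 200)), 1e-3)
        res = simulate_ads(net, c)
        assert res.raster.spikes.sum() == 0
        np.testing.assert_array_equal(res.x_tilde.values, 0.0)
        np.testing.assert_array_equal(res.y_tilde.values, 0.0)

    def test_k_zero_ignores_teacher_trajectory(self, net, tiny_teacher):
        """With no error feedback the dynamics cannot depend on whatever
        teacher trajectory is supplied."""
        rng = np.random.default_rng(3)
        c = TimeSeries(rng.standard_normal((2, 150)), 1e-3)
        xh_a = TimeSeries(rng.standard_normal((8, 150)), 1e-3)
        xh_b = TimeSeries(rng.standard_normal((8, 150)), 1e-3)
        a = simulate_ads(net, c, xh_a, k=0.0)
        b = simulate_ads(net, c, xh_b, k=0.0)
        np.testing.assert_array_equal(a.raster.spikes, b.raster.spikes)

    def test_k_positive_requires_teacher(self, net):
        c = TimeSeries(np.zeros((2, 10)), 1e-3)
        with pytest.raises(ValueError, match="teacher"):
            simulate_ads(net, c, x_hat=None, k=10.0)

    def test_bit_exact_reproducibility_with_noise(self, net):
        c = TimeSeries(np.random.default_rng(4).standard_normal((2, 100)),
                       1e-3)
        a = simulate_ads(net, c, noise_sigma=0.05,
                         rng=np.random.default_rng(7))
        b = simulate_ads(net, c, noise_sigma=0.05,
                         rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.raster.spikes, b.raster.spikes)
        np.testing.assert_array_equal(a.x_tilde.values, b.x_tilde.values)

    def test_at_most_one_spike_per_neuron_per_step(self, net):
        c = TimeSeries(
            10 * np.random.default_rng(5).standard_normal((2, 200)), 1e-3)
        res = simulate_ads(net, c)
        assert res.raster.spikes.dtype == bool  # binary by construction

    def test_decode_is_baseline_plus_filtered_spikes(self, net):
        from adsnet.dynamics import filter_spikes

        c = TimeSeries(
            3 * np.random.default_rng(6).standard_normal((2, 150)), 1e-3)
        res = simulate_ads(net, c)
        r = filter_spikes(res.raster, net.lif.tau_slow).values
        expected = net.x_baseline[:, None] + net.F @ r
        np.testing.assert_allclose(res.x_tilde.values, expected, atol=1e-9)
        np.testing.assert_allclose(res.y_tilde.values,
                                   net.D_hat @ res.x_tilde.values, atol=1e-9)

    def test_dt_mismatch_rejected(self, net):
        with pytest.raises(ValueError, match="dt"):
            simulate_ads(net, TimeSeries(np.zeros((2, 10)), 2e-3))


class TestErrorFeedbackClamping:
    def test_tracking_error_non_increasing_in_k(self, net, tiny_teacher):
        """Time-averaged reconstruction error of an untrained network is
        non-increasing in the feedback rate over k in {0, 25, 75, 200}."""
        rng = np.random.default_rng(8)
        t = np.arange(400) * 1e-3
        sig = np.stack([np.sin(2 * np.pi * 2 * t),
                        np.cos(2 * np.pi * 3 * t)])
        dirs = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        xh = TimeSeries(dirs @ sig * 2.0, 1e-3)
        c = TimeSeries(np.zeros((2, 400)), 1e-3)
        errs = []
        for k in (0.0, 25.0, 75.0, 200.0):
            res = simulate_ads(net, c, xh, k=k)
            errs.append(res.reconstruction_mse)
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:])), errs


class TestTrainADS:
    def _const_sampler(self, rng):
        c = np.zeros((2, 120))
        c[:, 30:90] = 1.0
        from adsnet.tasks import LabeledSample
        return LabeledSample(TimeSeries(c, 1e-3),
                             TimeSeries(np.zeros((1, 120)), 1e-3), 1)

    def test_empty_schedule_returns_init(self, net, tiny_teacher):
        sched = FeedbackSchedule(stages=[], eta=1e-5)
        out, rec = train_ads(tiny_teacher, net, self._const_sampler, sched,
                             np.random.default_rng(0))
        np.testing.assert_array_equal(out.Omega_s, net.Omega_s)
        assert rec.mse == []

    def test_zero_eta_leaves_weights_unchanged(self, net, tiny_teacher):
        sched = FeedbackSchedule(stages=[(75.0, 3)], eta=0.0)
        out, rec = train_ads(tiny_teacher, net, self._const_sampler, sched,
                             np.random.default_rng(0))
        np.testing.assert_array_equal(out.Omega_s, net.Omega_s)
        assert len(rec.mse) == 3

    def test_training_is_bit_exact_under_seed(self, net, tiny_teacher):
        sched = FeedbackSchedule(stages=[(75.0, 3)], eta=1e-4)
        a, _ = train_ads(tiny_teacher, net, self._const_sampler, sched,
                         np.random.default_rng(5))
        b, _ = train_ads(tiny_teacher, net, self._const_sampler, sched,
                         np.random.default_rng(5))
        np.testing.assert_array_equal(a.Omega_s, b.Omega_s)

    def test_nhat_mismatch_rejected(self, net):
        other = _zero_teacher(N_hat=5)
        with pytest.raises(ValueError, match="N_hat"):
            train_ads(other, net, self._const_sampler,
                      FeedbackSchedule(stages=[(75.0, 1)], eta=1e-5),
                      np.random.default_rng(0))


class TestSchedule:
    def test_presets(self):
        xor = FeedbackSchedule.xor(n_samples=100)
        assert xor.stages == [(75.0, 100)]
        assert xor.eta == 1e-5
        speech = FeedbackSchedule.speech(n_samples=80)
        assert len(speech.stages) == 8
        assert speech.stages[0][0] == 200.0
        assert speech.stages[-1][0] == 25.0
        assert speech.n_samples == 80
        assert speech.eta == 1e-4
        ks = [k for k, _ in speech.stages]
        np.testing.assert_allclose(np.diff(ks), -25.0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            FeedbackSchedule(stages=[(-1.0, 10)], eta=1e-5)

    def test_frozen_high_final_k_warns(self):
        with pytest.warns(UserWarning, match="feedback rate"):
            FeedbackSchedule(stages=[(200.0, 10), (150.0, 10)], eta=1e-5)


class TestEvaluate:
    def test_teacher_evaluates_through_its_own_readout(self, xor_teacher,
                                                       sampler):
        """Passing the teacher itself gives its own accuracy: a sanity check
        that the evaluation harness is architecture-agnostic."""
        teacher, _ = xor_teacher
        out = evaluate_ads(teacher, sampler, 20, classify_xor,
                           np.random.default_rng(0))
        assert 0.8 <= out["accuracy"] <= 1.0

    def test_degenerate_silent_network_is_at_chance_or_below(self):
        """An all-zero network abstains everywhere: accuracy 0 on the
        balanced label set (abstention counts as incorrect)."""
        teacher = _zero_teacher(d1=1)
        net = ADSNetworkParameters.initialise(teacher, 16,
                                              np.random.default_rng(0))
        from adsnet.tasks import xor_sampler
        out = evaluate_ads(net, xor_sampler(), 20, classify_xor,
                           np.random.default_rng(1))
        assert out["accuracy"] <= 0.5
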