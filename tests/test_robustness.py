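"""Tests for the perturbation models and statistical comparisons."""

import itertools
import warnings

import numpy as np
import pytest

from adsnet.distill import ADSNetworkParameters, simulate_ads
from adsnet.dynamics import LIFParameters, TimeSeries
from adsnet.robustness import (MismatchSpec, apply_mismatch,
                               compare_distributions, quantize_network,
                               quantize_weights, silence_neurons)
from adsnet.teacher import RateNetworkParameters


@pytest.fixture
def small_ads(tiny_teacher):
    return ADSNetworkParameters.initialise(tiny_teacher, 24,
                                           np.random.default_rng(0))


class TestQuantizer:
    def test_grid_already_exact(self):
        W = np.array([0.0, 1.0, 2.0, 3.0])
        np.testing.assert_array_equal(quantize_weights(W, 2), W)

    def test_hand_computed_codebook(self):
        """rho = 2/7 for [-1, 0.3, 1] at 3 bits; 0.3/rho = 1.05 rounds to
        1 -> 2/7, and +-1/rho = +-3.5 rounds half away from zero to +-4
        -> +-8/7."""
        W = np.array([-1.0, 0.3, 1.0])
        q = quantize_weights(W, 3)
        rho = 2.0 / 7.0
        np.testing.assert_allclose(q, [-4 * rho, rho, 4 * rho])

    def test_codebook_size_bound(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((40, 40))
        for bits in (2, 3, 4):
            q = quantize_weights(W, bits)
            assert np.unique(q).size <= 2**bits + 1

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((20, 20))
        q1 = quantize_weights(W, 4)
        # note: re-quantising uses the quantised matrix's own (possibly
        # wider) range, so idempotence is checked at matched rho
        q2 = quantize_weights(q1, 4)
        span1 = q1.max() - q1.min()
        span0 = W.max() - W.min()
        if span1 == pytest.approx(span0):
            np.testing.assert_allclose(q1, q2, atol=1e-12)

    def test_constant_matrix_warns_and_passes_through(self):
        W = np.full((3, 3), 0.7)
        with pytest.warns(UserWarning, match="constant"):
            q = quantize_weights(W, 4)
        np.testing.assert_array_equal(q, W)

    def test_network_quantisation_is_per_matrix(self, small_ads):
        q = quantize_network(small_ads, 4)
        for name in ("F", "Omega_f", "F_hat", "D_hat"):
            full = getattr(small_ads, name)
            quant = getattr(q, name)
            span = full.max() - full.min()
            if span == 0:
                continue
            rho = span / (2**4 - 1)
            # every quantised value sits on that matrix's own grid
            assert np.allclose(quant / rho, np.round(quant / rho), atol=1e-9)


class TestMismatch:
    def test_zero_delta_is_identity(self, small_ads):
        out = apply_mismatch(small_ads, MismatchSpec(0.0),
                             np.random.default_rng(0))
        np.testing.assert_array_equal(out.Omega_f, small_ads.Omega_f)
        np.testing.assert_array_equal(out.F, small_ads.F)

    def test_input_untouched(self, small_ads):
        before = small_ads.F.copy()
        apply_mismatch(small_ads, MismatchSpec(0.2),
                       np.random.default_rng(1))
        np.testing.assert_array_equal(small_ads.F, before)

    def test_moment_recovery(self):
        """On 10^4 equal weights w, the sample std over |w| recovers delta
        within 3 standard errors."""
        n = 10**4
        delta = 0.2
        w = np.full(n, -0.7)
        draw = w + np.random.default_rng(2).standard_normal(n) * \
            (delta * np.abs(w))
        ratio = draw.std() / 0.7
        se = delta / np.sqrt(2 * n)
        assert abs(ratio - delta) < 3 * se

    def test_zero_parameters_stay_zero(self, small_ads):
        out = apply_mismatch(small_ads, MismatchSpec(0.2),
                             np.random.default_rng(3))
        assert np.all(out.Omega_s == 0)  # untrained slow weights are zero

    def test_linear_mean_variance_law(self):
        """Across parameter magnitudes, the fitted slope of sample std
        versus |mean| equals delta within 5%."""
        delta = 0.1
        rng = np.random.default_rng(4)
        mags = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        stds = []
        for m in mags:
            w = np.full(20000, m)
            draw = w + rng.standard_normal(w.size) * (delta * np.abs(w))
            stds.append(draw.std())
        slope = np.polyfit(mags, stds, 1)[0]
        assert slope == pytest.approx(delta, rel=0.05)

    def test_scalar_neuron_parameters_become_vectors(self, small_ads):
        out = apply_mismatch(small_ads, MismatchSpec(0.1),
                             np.random.default_rng(5))
        assert np.asarray(out.lif.tau_mem).shape == (small_ads.N,)
        assert np.asarray(out.lif.V_thresh).shape == (small_ads.N,)
        assert np.all(np.asarray(out.lif.tau_mem) > 0)
        assert np.all(np.asarray(out.lif.V_thresh)
                      > np.asarray(out.lif.V_reset))

    def test_reproducible_under_seed(self, small_ads):
        a = apply_mismatch(small_ads, MismatchSpec(0.1),
                           np.random.default_rng(6))
        b = apply_mismatch(small_ads, MismatchSpec(0.1),
                           np.random.default_rng(6))
        np.testing.assert_array_equal(a.Omega_f, b.Omega_f)
        np.testing.assert_array_equal(np.asarray(a.lif.tau_mem),
                                      np.asarray(b.lif.tau_mem))

    def test_target_subsets_respected(self, small_ads):
        out = apply_mismatch(
            small_ads, MismatchSpec(0.2, frozenset({"tau_mem"})),
            np.random.default_rng(7))
        np.testing.assert_array_equal(out.F, small_ads.F)
        assert np.asarray(out.lif.tau_mem).shape == (small_ads.N,)
        assert np.isscalar(out.lif.V_thresh) or \
            np.asarray(out.lif.V_thresh).ndim == 0


class TestSilencing:
    def test_zero_fraction_reproduces_trajectory(self, small_ads):
        c = TimeSeries(np.random.default_rng(0).standard_normal((2, 200)),
                       1e-3)
        win = silence_neurons(small_ads.N, 0.0, 50, 150,
                              np.random.default_rng(1))
        a = simulate_ads(small_ads, c)
        b = simulate_ads(small_ads, c, silence=win)
        np.testing.assert_array_equal(a.raster.spikes, b.raster.spikes)
        np.testing.assert_array_equal(a.x_tilde.values, b.x_tilde.values)

    def test_silenced_neurons_emit_no_spikes(self, small_ads):
        c = TimeSeries(
            5.0 * np.random.default_rng(2).standard_normal((2, 300)), 1e-3)
        win = silence_neurons(small_ads.N, 0.4, 100, 250,
                              np.random.default_rng(3))
        res = simulate_ads(small_ads, c, silence=win)
        assert not res.raster.spikes[win.indices, 100:250].any()

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            silence_neurons(10, 1.0, 0, 10, np.random.default_rng(0))

    def test_subset_size(self):
        win = silence_neurons(100, 0.4, 0, 10, np.random.default_rng(4))
        assert win.indices.size == 40
        assert np.unique(win.indices).size == 40


class TestCompareDistributions:
    def test_exact_u_pvalue_matches_enumeration(self):
        """For a={1,2,3}, b={4,5,6} the exact two-sided p-value is 0.1
        (2/20 of all rank assignments are as extreme)."""
        out = compare_distributions([1, 2, 3], [4, 5, 6])
        assert out["u_pvalue"] == pytest.approx(0.1)

    def test_exact_distribution_by_full_enumeration(self):
        """The U-test p-value matches brute-force enumeration of all
        C(n1+n2, n1) rank assignments for small samples."""
        a = np.array([1.3, 2.7, 0.2, 5.1])
        b = np.array([3.3, 4.9, 6.0])
        obs_u = compare_distributions(a, b)["u_statistic"]
        pooled = np.concatenate([a, b])
        n1 = len(a)
        ranks = np.argsort(np.argsort(pooled)) + 1
        us = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            r1 = ranks[list(combo)].sum()
            us.append(r1 - n1 * (n1 + 1) / 2)
        us = np.array(us)
        # two-sided: double the smaller tail (U or its reflection)
        mean_u = n1 * len(b) / 2
        tail = min(np.mean(us <= obs_u), np.mean(us >= obs_u))
        p_enum = min(1.0, 2 * tail)
        assert compare_distributions(a, b)["u_pvalue"] == \
            pytest.approx(p_enum)

    def test_identical_samples_give_p_one(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["u_pvalue"] > 0.99

    def test_degenerate_ties_flagged(self):
        with pytest.warns(UserWarning, match="identical"):
            out = compare_distributions([1.0] * 5, [1.0] * 5)
        assert out["u_pvalue"] == 1.0

    def test_levene_detects_scale_difference(self):
        """Samples differing 10x in scale at n=50 drive the Levene p-value
        below 0.05."""
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 10, 50)
        out = compare_distributions(a, b)
        assert out["levene_pvalue"] < 0.05

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0, 2.0], [3.0, 4.0, 5.0])
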