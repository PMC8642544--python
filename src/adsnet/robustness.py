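"""Perturbation models and the robustness-evaluation harness.

Four perturbations model the non-idealities of mixed-signal neuromorphic
deployment:

* **Device mismatch** — frozen parameter noise: every targeted parameter
  value ``theta`` is replaced by a draw from ``N(theta, delta * |theta|)``,
  reproducing the linear mean-variance relationship measured on analog
  neuron/synapse circuits.  Typical fabrication levels are 5-20 %.
* **Weight quantisation** — post-training rounding of each weight matrix to
  a ``2^bits``-level uniform grid spanning that matrix's range.
* **Thermal noise** — per-step white perturbation of the membrane
  potentials, scaled to the threshold-to-reset gap.
* **Neuron silencing** — a random subset of neurons clamped to the reset
  potential for part of a trial (sudden neuron death).

The harness evaluates a network over a grid of perturbations and levels,
recording output MSE against the teacher and task accuracy per trial, and
provides the rank-sum and variance tests used to compare architectures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distill import (ADSNetworkParameters, SilenceWindow, evaluate_ads)
from .dynamics import LIFParameters
from .teacher import RateNetworkParameters

__all__ = [
    "MismatchSpec",
    "apply_mismatch",
    "quantize_weights",
    "quantize_network",
    "silence_neurons",
    "summarise_robustness",
    "run_robustness_suite",
    "compare_distributions",
]

ALL_MISMATCH_TARGETS = frozenset(
    {"weights", "thresholds", "biases", "tau_mem", "tau_syn"})


@dataclass(frozen=True)
class MismatchSpec:
    """Level and scope of simulated device mismatch.

    ``delta`` is the fractional mismatch level (the per-parameter standard
    deviation is ``delta * |value|``); ``targets`` selects which parameter
    groups are perturbed.  ``biases`` maps to the resting potential, the
    LIF neuron's constant drive term.
    """

    delta: float
    targets: frozenset = ALL_MISMATCH_TARGETS

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("mismatch level must be non-negative")
        unknown = set(self.targets) - ALL_MISMATCH_TARGETS
        if unknown:
            raise ValueError(f"unknown mismatch targets: {sorted(unknown)}")


def _mismatch_draw(value, delta: float, rng: np.random.Generator,
                   size=None) -> np.ndarray:
    """Draw from N(value, delta * |value|) elementwise; zeros stay zero."""
    value = np.asarray(value, dtype=float)
    if size is not None:
        value = np.broadcast_to(value, size)
    return value + rng.standard_normal(value.shape if value.shape else None) \
        * (delta * np.abs(value))


def apply_mismatch(params: ADSNetworkParameters, spec: MismatchSpec,
                   rng: np.random.Generator,
                   tau_floor: float = 0.1e-3,
                   gap_floor_fraction: float = 0.01) -> ADSNetworkParameters:
    """Return a mismatched copy of the network (the input is untouched).

    Scalar neuron parameters become per-neuron vectors, since mismatch is
    independent across silicon neurons.  Time constants are clipped to
    ``tau_floor`` (0.1 ms) and thresholds to at least 1 % of the nominal
    threshold-to-reset gap above the reset potential.
    """
    out = params.copy()
    lif = out.lif
    N = lif.N
    if spec.delta == 0 or not spec.targets:
        return out
    nominal_gap = lif.threshold_gap
    if "weights" in spec.targets:
        out.Omega_f = _mismatch_draw(out.Omega_f, spec.delta, rng)
        out.Omega_s = _mismatch_draw(out.Omega_s, spec.delta, rng)
        out.F = _mismatch_draw(out.F, spec.delta, rng)
        out.F_hat = _mismatch_draw(out.F_hat, spec.delta, rng)
        out.D_hat = _mismatch_draw(out.D_hat, spec.delta, rng)
    kw = {}
    if "thresholds" in spec.targets:
        thresh = _mismatch_draw(lif.V_thresh, spec.delta, rng, size=(N,))
        floor = np.asarray(lif.V_reset) + gap_floor_fraction * nominal_gap
        kw["V_thresh"] = np.maximum(thresh, floor)
    if "biases" in spec.targets:
        rest = _mismatch_draw(lif.V_rest, spec.delta, rng, size=(N,))
        kw["V_rest"] = np.clip(rest, np.asarray(lif.V_reset),
                               np.asarray(kw.get("V_thresh", lif.V_thresh))
                               - 1e-9)
    if "tau_mem" in spec.targets:
        kw["tau_mem"] = np.maximum(
            _mismatch_draw(lif.tau_mem, spec.delta, rng, size=(N,)), tau_floor)
    if "tau_syn" in spec.targets:
        kw["tau_fast"] = np.maximum(
            _mismatch_draw(lif.tau_fast, spec.delta, rng, size=(N,)), tau_floor)
        kw["tau_slow"] = np.maximum(
            _mismatch_draw(lif.tau_slow, spec.delta, rng, size=(N,)), tau_floor)
    if kw:
        # keep dt well-posed even if a fast synapse draw lands below dt
        if "tau_fast" in kw:
            kw["tau_fast"] = np.maximum(kw["tau_fast"], lif.dt)
        if "tau_mem" in kw:
            kw["tau_mem"] = np.maximum(kw["tau_mem"], lif.dt)
        out.lif = LIFParameters(
            N=N, dt=lif.dt,
            tau_mem=kw.get("tau_mem", lif.tau_mem),
            V_thresh=kw.get("V_thresh", lif.V_thresh),
            V_reset=lif.V_reset,
            V_rest=kw.get("V_rest", lif.V_rest),
            tau_fast=kw.get("tau_fast", lif.tau_fast),
            tau_slow=kw.get("tau_slow", lif.tau_slow))
    return out


def quantize_weights(W: np.ndarray, bits: int) -> np.ndarray:
    """Round a weight matrix to a uniform ``2^bits``-level grid.

    The grid step is ``rho = (max(W) - min(W)) / (2^bits - 1)`` and the
    quantised weights are ``rho * round(W / rho)`` with rounding half away
    from zero.  A constant matrix is returned unchanged with a warning.
    """
    if bits < 1:
        raise ValueError("bits must be at least 1")
    W = np.asarray(W, dtype=float)
    span = float(W.max() - W.min())
    if span == 0.0:
        warnings.warn("constant weight matrix: quantisation is a no-op",
                      stacklevel=2)
        return W.copy()
    rho = span / (2**bits - 1)
    scaled = W / rho
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return rho * rounded


def quantize_network(params: ADSNetworkParameters,
                     bits: int) -> ADSNetworkParameters:
    """Quantise every weight matrix of the network separately."""
    out = params.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in ("F", "Omega_f", "Omega_s", "F_hat", "D_hat"):
            setattr(out, name, quantize_weights(getattr(out, name), bits))
    return out


def silence_neurons(N: int, fraction: float, onset: int, offset: int,
                    rng: np.random.Generator) -> SilenceWindow:
    """Choose a random subset of neurons to clamp during [onset, offset)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    n_silence = int(round(fraction * N))
    indices = rng.choice(N, size=n_silence, replace=False)
    return SilenceWindow(indices=np.sort(indices), onset=onset, offset=offset)


def run_robustness_suite(network: ADSNetworkParameters,
                         teacher: RateNetworkParameters,
                         task_sampler, readout,
                         grid: list[tuple[str, float]],
                         n_draws: int = 10, n_trials: int = 1,
                         n_samples: int = 20,
                         rng: np.random.Generator | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Evaluate the network over a perturbation grid.

    ``grid`` is a list of ``(kind, level)`` pairs with kinds ``"none"``,
    ``"mismatch"`` (level = delta), ``"quantise"`` (level = bits),
    ``"thermal"`` (level = sigma) and ``"silence"`` (level = fraction).  For
    every grid point, ``n_draws`` perturbation instantiations are each
    evaluated on ``n_trials`` batches of ``n_samples`` task samples at
    k = 0.  Evaluation batches are seeded identically across grid points,
    so comparisons between levels are paired.

    Returns a tidy DataFrame with one row per (perturbation, level, draw,
    trial) carrying the output MSE against the teacher and the task
    accuracy.
    """
    if not grid:
        raise ValueError("perturbation grid must be non-empty")
    rows = []
    for kind, level in grid:
        for draw in range(n_draws):
            draw_rng = np.random.default_rng([seed, 101, draw])
            noise_sigma = 0.0
            silence = None
            perturbed = network
            if kind == "none" or level == 0:
                pass
            elif kind == "mismatch":
                perturbed = apply_mismatch(network, MismatchSpec(level),
                                           draw_rng)
            elif kind == "quantise":
                perturbed = quantize_network(network, int(level))
            elif kind == "thermal":
                noise_sigma = float(level)
            elif kind == "silence":
                pass  # window drawn per trial below
            else:
                raise ValueError(f"unknown perturbation kind {kind!r}")
            for trial in range(n_trials):
                eval_rng = np.random.default_rng([seed, 202, draw, trial])
                if kind == "silence" and level > 0:
                    win_rng = np.random.default_rng([seed, 303, draw, trial])
                    # clamp during the middle half of the trial
                    silence = silence_neurons(network.N, level,
                                              onset=0, offset=10**9,
                                              rng=win_rng)
                try:
                    summary = evaluate_ads(
                        perturbed, task_sampler, n_samples, readout,
                        eval_rng, teacher=teacher,
                        noise_sigma=noise_sigma, silence=silence)
                except FloatingPointError as exc:
                    raise FloatingPointError(
                        f"simulation failed for perturbation={kind} "
                        f"level={level} draw={draw} trial={trial}: {exc}"
                    ) from exc
                rows.append({
                    "perturbation": kind, "level": level,
                    "draw": draw, "trial": trial,
                    "mse": summary["mse"],
                    "accuracy": summary["accuracy"],
                })
    return pd.DataFrame(rows)


def summarise_robustness(results: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of MSE and accuracy per (perturbation, level)."""
    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1

    return results.groupby(["perturbation", "level"]).agg(
        mse_median=("mse", "median"), mse_iqr=("mse", iqr),
        accuracy_median=("accuracy", "median"),
        accuracy_iqr=("accuracy", iqr)).reset_index()


def compare_distributions(a, b) -> dict:
    """Two-sided Mann-Whitney U test and Levene variance test.

    The U test uses the exact null distribution when both samples have at
    most 8 observations and no ties span the groups, matching full
    enumeration of rank assignments; larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample must contain at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical: tests are degenerate",
                      stacklevel=2)
        return {"u_statistic": a.size * b.size / 2, "u_pvalue": 1.0,
                "levene_statistic": 0.0, "levene_pvalue": 1.0}
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) \
        else "asymptotic"
    u = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    lev = stats.levene(a, b)
    return {"u_statistic": float(u.statistic), "u_pvalue": float(u.pvalue),
            "levene_statistic": float(lev.statistic),
            "levene_pvalue": float(lev.pvalue)}
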