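"""Forward-Euler simulation primitives for leaky integrate-and-fire (LIF)
neurons with fast and slow exponential synapses.

All simulations in this package are clock-driven with a uniform step ``dt``
(1 ms by default).  A neuron's membrane potential integrates its input
currents, leaks toward the resting potential, and emits a spike whenever it
exceeds the firing threshold, after which it is reset.  Synaptic currents are
exponentially filtered spike trains; the same kernel (with unit weight) is
used to produce the filtered population trace ``r`` that downstream modules
decode linearly.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TimeSeries",
    "LIFParameters",
    "LIFState",
    "SpikeRaster",
    "lif_step",
    "synapse_step",
    "filter_spikes",
]


@dataclass
class TimeSeries:
    """A uniformly sampled multichannel signal.

    Parameters
    ----------
    values
        Real matrix of shape ``(channels, steps)``.
    dt
        Sampling interval in seconds (strictly positive).
    t0
        Time of the first sample in seconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps)

    def copy(self) -> "TimeSeries":
        return TimeSeries(self.values.copy(), self.dt, self.t0)

    def to_csv(self, path) -> None:
        """Write as headered CSV: one row per channel, dt/t0 in the header."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([f"# dt={self.dt!r} t0={self.t0!r}"])
            for row in self.values:
                writer.writerow([f"{float(v):.17g}" for v in row])

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        with open(path, newline="") as fh:
            header = fh.readline().strip().lstrip('"').rstrip('"')
            if not header.startswith("# dt="):
                raise ValueError(f"not a TimeSeries CSV: bad header {header!r}")
            parts = header[2:].split()
            dt = float(parts[0].split("=")[1])
            t0 = float(parts[1].split("=")[1])
            values = np.loadtxt(io.StringIO(fh.read()), delimiter=",", ndmin=2)
        return cls(values, dt, t0)


@dataclass
class LIFParameters:
    """Constants of a population of LIF neurons.

    Defaults follow the mixed-signal-oriented parameterisation used
    throughout this package: ``tau_mem`` = 50 ms, ``V_reset`` = 0,
    ``V_rest`` = 0.5, ``V_thresh`` = 1, fast/slow synaptic time constants of
    1 ms and 70 ms, and a simulation step of 1 ms.

    ``V_thresh``, ``V_reset``, ``V_rest``, ``tau_mem``, ``tau_fast`` and
    ``tau_slow`` may each be either a scalar (shared by all neurons) or an
    ``(N,)`` vector (e.g. after applying simulated device mismatch).
    """

    N: int
    tau_mem: float | np.ndarray = 50e-3
    V_thresh: float | np.ndarray = 1.0
    V_reset: float | np.ndarray = 0.0
    V_rest: float | np.ndarray = 0.5
    tau_fast: float | np.ndarray = 1e-3
    tau_slow: float | np.ndarray = 70e-3
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be at least 1")
        for name in ("tau_mem", "tau_fast", "tau_slow"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if not np.all(np.asarray(self.V_reset) <= np.asarray(self.V_rest)):
            raise ValueError("require V_reset <= V_rest")
        if not np.all(np.asarray(self.V_rest) < np.asarray(self.V_thresh)):
            raise ValueError("require V_rest < V_thresh")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > min(np.min(np.asarray(self.tau_fast)),
                         np.min(np.asarray(self.tau_mem))):
            raise ValueError("dt must not exceed min(tau_fast, tau_mem)")

    @property
    def lambda_leak(self) -> float | np.ndarray:
        """Membrane leak rate, the reciprocal of the membrane time constant."""
        return 1.0 / self.tau_mem

    @property
    def threshold_gap(self) -> float:
        """Mean distance between firing threshold and reset potential."""
        return float(np.mean(np.asarray(self.V_thresh) - np.asarray(self.V_reset)))

    def copy(self) -> "LIFParameters":
        kw = {}
        for name in ("tau_mem", "V_thresh", "V_reset", "V_rest",
                     "tau_fast", "tau_slow"):
            v = getattr(self, name)
            kw[name] = v.copy() if isinstance(v, np.ndarray) else v
        return replace(self, **kw)


@dataclass
class LIFState:
    """Instantaneous state of a LIF population."""

    V: np.ndarray
    I_fast: np.ndarray
    I_slow: np.ndarray
    I_inp: np.ndarray
    I_err: np.ndarray
    r: np.ndarray

    @classmethod
    def zeros(cls, N: int, V0: float | np.ndarray = 0.0) -> "LIFState":
        V = np.broadcast_to(np.asarray(V0, dtype=float), (N,)).copy()
        return cls(V=V, I_fast=np.zeros(N), I_slow=np.zeros(N),
                   I_inp=np.zeros(N), I_err=np.zeros(N), r=np.zeros(N))


@dataclass
class SpikeRaster:
    """Binary spike events per neuron per time step."""

    spikes: np.ndarray  # (N, steps), boolean
    dt: float

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=bool)
        if self.spikes.ndim != 2:
            raise ValueError("spike raster must be 2-D (neurons x steps)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def N(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    def spike_counts(self) -> np.ndarray:
        return self.spikes.sum(axis=1)

    def to_pairs(self) -> np.ndarray:
        """Sparse (neuron, step) representation."""
        return np.argwhere(self.spikes)

    @classmethod
    def from_pairs(cls, pairs: np.ndarray, N: int, n_steps: int,
                   dt: float) -> "SpikeRaster":
        raster = np.zeros((N, n_steps), dtype=bool)
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        raster[pairs[:, 0], pairs[:, 1]] = True
        return cls(raster, dt)


def lif_step(state: LIFState, params: LIFParameters, inputs: np.ndarray,
             noise_sigma: float = 0.0, rng: np.random.Generator | None = None,
             step_index: int | None = None,
             direct_drive: np.ndarray | float = 0.0):
    """Advance a LIF population by one Euler step.

    ``inputs`` is the summed per-neuron input current (input drive, slow
    PSPs, error current); it enters the membrane equation through the leaky
    integration ``dt/tau_mem * (V_rest - V + I)``.  ``direct_drive`` is an
    optional per-neuron voltage increment applied without the membrane
    attenuation — the fast balancing feedback uses it so that a spike's
    self-inhibition spans the full threshold-to-reset gap, which is what
    the fast-weight scaling presumes.

    Thermal noise is modelled as a white perturbation of the membrane
    potential: each step every neuron receives an independent draw from
    ``N(0, noise_sigma * (V_thresh - V_reset))`` added directly to ``V``,
    so ``noise_sigma`` is the per-step membrane fluctuation expressed as a
    fraction of the threshold-to-reset gap.

    Returns the updated state and the boolean spike vector.  Exactly the
    neurons whose updated potential exceeds ``V_thresh`` spike; they are
    reset to ``V_reset`` regardless of overshoot.  There is no refractory
    period: the one-spike-per-step limit is inherent to the clocked update.
    """
    V = state.V
    if V.shape[0] != params.N:
        raise ValueError(f"state has {V.shape[0]} neurons, params.N={params.N}")
    alpha = params.dt / np.asarray(params.tau_mem)
    V_new = V + alpha * (np.asarray(params.V_rest) - V + inputs) + direct_drive
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        gap = np.asarray(params.V_thresh) - np.asarray(params.V_reset)
        V_new = V_new + rng.normal(0.0, 1.0, size=params.N) * (noise_sigma * gap)
    if not np.all(np.isfinite(V_new)):
        bad = int(np.flatnonzero(~np.isfinite(V_new))[0])
        where = "" if step_index is None else f" at step {step_index}"
        raise FloatingPointError(
            f"non-finite membrane potential in neuron {bad}{where}")
    spikes = V_new > np.asarray(params.V_thresh)
    if np.any(spikes):
        V_new = np.where(spikes, np.asarray(params.V_reset), V_new)
    new_state = LIFState(V=V_new, I_fast=state.I_fast, I_slow=state.I_slow,
                         I_inp=state.I_inp, I_err=state.I_err, r=state.r)
    return new_state, spikes


def synapse_step(I: np.ndarray, W: np.ndarray, spikes: np.ndarray,
                 tau_syn: float | np.ndarray, dt: float) -> np.ndarray:
    """One Euler step of an exponential synapse driven by a spike vector.

    Implements ``I <- I + dt/tau_syn * (-I + (W @ o) * tau_syn / dt)``, i.e.
    an isolated presynaptic spike through weight ``w`` produces an
    instantaneous current jump of ``w`` that then decays with ``tau_syn``.
    The discrete time-integral of the resulting PSP equals ``w * tau_syn``.
    """
    W = np.asarray(W)
    spikes = np.asarray(spikes)
    if W.ndim != 2 or W.shape[1] != spikes.shape[0]:
        raise ValueError(
            f"weight matrix {W.shape} incompatible with spike vector "
            f"of length {spikes.shape[0]}")
    if np.any(np.asarray(tau_syn) <= 0):
        raise ValueError("tau_syn must be strictly positive")
    decay = dt / np.asarray(tau_syn)
    return I + decay * (-I) + W @ spikes.astype(float)


def filter_spikes(raster: SpikeRaster, tau: float) -> TimeSeries:
    """Exponentially filter each neuron's spike train.

    Uses the same kernel as :func:`synapse_step` with unit weight: a spike
    adds 1 to the trace, which decays with time constant ``tau``.  The
    resulting trace is the quantity decoded linearly elsewhere in the
    package.
    """
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    from scipy.signal import lfilter

    decay = 1.0 - raster.dt / tau
    traces = lfilter([1.0], [1.0, -decay], raster.spikes.astype(float), axis=1)
    return TimeSeries(traces, raster.dt)
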