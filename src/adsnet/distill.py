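"""Simulation and training of the spiking ADS network.

The ADS ("arbitrary dynamical system") network is a recurrent population of
LIF neurons that learns to reproduce the internal state trajectory
``x_hat(t)`` of a trained teacher rate network.  Its membrane dynamics
receive four currents: the projected task input ``F^T (F_hat c)``, fast
balancing feedback ``-Omega_f o`` (1 ms synapses), learned slow feedback
``+Omega_s o`` (70 ms synapses), and an error-feedback current
``k F^T (x_hat - x_tilde)`` that clamps the population to the teacher
trajectory during learning.  The decoded estimate is ``x_tilde = F r`` with
``r`` the 70 ms-filtered spike trains, and the task output is
``y_tilde = D_hat x_tilde`` through the teacher's readout.

The slow weights are learned online with the local rule

    dOmega_s[i, j] = eta * (F^T e)[i] * r[j]

(postsynaptic projected error times presynaptic filtered trace), applied at
every simulation step while the error feedback holds the network near the
target.  As learning progresses, ``Omega_s r`` comes to supply the current
the error feedback was providing, so the feedback rate ``k`` can be lowered
and finally removed: at inference the network runs with ``k = 0`` and no
teacher.

Sign convention: the error reported in records is ``e = x_tilde - x_hat``
(estimate minus target); the feedback current and the learning rule both use
the *corrective* direction ``x_hat - x_tilde``, which is what drives neurons
whose encoding vectors point along the deficit to fire and is the only
stable closed loop.

Fast feedback is instantaneous on the simulation clock (its synaptic time
constant equals the step): threshold crossings within a step are resolved
sequentially, most-suprathreshold first, each spike's ``-Omega_f`` column
applied before the next candidate is chosen, and the self-inhibition
(spanning the threshold-to-reset gap) performs the reset.  Routing the fast
PSPs through the leaky membrane integration instead would attenuate them
by dt/tau_mem and reduce the balancing feedback to a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .balance import init_fast_weights, sample_encoder
from .dynamics import LIFParameters, SpikeRaster, TimeSeries
from .teacher import RateNetworkParameters, simulate_rnn

__all__ = [
    "ADSNetworkParameters",
    "FeedbackSchedule",
    "TrainingRecord",
    "SimulationResult",
    "simulate_ads",
    "ads_weight_update",
    "train_ads",
    "evaluate_ads",
]


@dataclass
class ADSNetworkParameters:
    """All parameters of a spiking ADS network.

    ``F`` is the ``(N_hat, N)`` encoder; ``Omega_f``/``Omega_s`` are the
    ``(N, N)`` fast and slow recurrent weights; ``F_hat`` and ``D_hat`` are
    copies of the teacher's input and output weights.
    """

    lif: LIFParameters
    F: np.ndarray
    Omega_f: np.ndarray
    Omega_s: np.ndarray
    F_hat: np.ndarray
    D_hat: np.ndarray
    x_baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        N = self.lif.N
        self.F = np.asarray(self.F, dtype=float)
        if self.x_baseline is None:
            self.x_baseline = np.zeros(self.F.shape[0])
        else:
            self.x_baseline = np.asarray(self.x_baseline, dtype=float)
        self.Omega_f = np.asarray(self.Omega_f, dtype=float)
        self.Omega_s = np.asarray(self.Omega_s, dtype=float)
        self.F_hat = np.atleast_2d(np.asarray(self.F_hat, dtype=float))
        self.D_hat = np.atleast_2d(np.asarray(self.D_hat, dtype=float))
        if self.F.shape[1] != N or self.Omega_f.shape != (N, N) \
                or self.Omega_s.shape != (N, N):
            raise ValueError("weight shapes inconsistent with lif.N")
        if self.F_hat.shape[0] != self.N_hat or self.D_hat.shape[1] != self.N_hat:
            raise ValueError("teacher I/O weights inconsistent with encoder")
        if not np.all(np.isfinite(self.Omega_s)):
            raise ValueError("non-finite slow weights")

    @property
    def N(self) -> int:
        return self.lif.N

    @property
    def N_hat(self) -> int:
        return self.F.shape[0]

    def copy(self) -> "ADSNetworkParameters":
        return ADSNetworkParameters(
            self.lif.copy(), self.F.copy(), self.Omega_f.copy(),
            self.Omega_s.copy(), self.F_hat.copy(), self.D_hat.copy(),
            self.x_baseline.copy())

    @classmethod
    def initialise(cls, teacher: RateNetworkParameters, N: int,
                   rng: np.random.Generator,
                   lif: LIFParameters | None = None,
                   mu: float | None = None,
                   encoder_norm: float | None = None,
                   x_baseline: np.ndarray | str | None = None,
                   ) -> "ADSNetworkParameters":
        """Fresh network: random encoder, analytic fast weights, zero slow
        weights (a pure balanced autoencoder), teacher I/O weights copied.

        The sampled encoder is rescaled by a single scalar so that the
        root-mean-square column norm equals ``encoder_norm`` — by default a
        quarter of the threshold-to-reset gap.  The column norm is the
        network's spike quantum: it sets the decode resolution and, through
        the projections ``F^T (F_hat c)`` and ``k F^T e``, the strength of
        the input and error drives relative to the firing threshold.  A
        quarter-gap quantum leaves the task input strong enough to elicit
        spikes without error feedback (the network must run autonomously at
        inference) while keeping the error drive at the standard feedback
        rates well below one threshold per step, which avoids synchronous
        over-correction volleys.
        """
        lif = lif or LIFParameters(N=N, dt=teacher.dt)
        if lif.N != N:
            raise ValueError("lif.N must equal N")
        if encoder_norm is None:
            encoder_norm = 0.25 * lif.threshold_gap
        F = sample_encoder(teacher.N_hat, N, rng)
        col_sq = float(np.mean(np.sum(F * F, axis=0)))
        F = F * (encoder_norm / np.sqrt(col_sq))
        Omega_f = init_fast_weights(F, lif, mu=mu)
        # Decoding is centred on the teacher's trial-start state (the
        # origin by default): the silent network codes the baseline for
        # free, and spikes only represent deviations.  This presumes a
        # teacher whose zero-input trajectories stay near the baseline —
        # which the teacher's activity regulariser enforces.  Pass
        # x_baseline="resting" to centre on the teacher's relaxed
        # zero-input state instead, or an explicit vector.
        if isinstance(x_baseline, str):
            if x_baseline != "resting":
                raise ValueError(f"unknown baseline mode {x_baseline!r}")
            from .teacher import resting_state
            x_base = resting_state(teacher)
        else:
            x_base = x_baseline  # None -> zeros in __post_init__
        return cls(lif=lif, F=F, Omega_f=Omega_f, Omega_s=np.zeros((N, N)),
                   F_hat=teacher.F_hat.copy(), D_hat=teacher.D_hat.copy(),
                   x_baseline=x_base)


@dataclass
class FeedbackSchedule:
    """Ordered stages of (error-feedback rate k, number of samples).

    The feedback rate should decay to a small value before training ends,
    otherwise the network learns to lean on the error current and
    generalises poorly once it is removed.  Two presets mirror the
    configurations used for the built-in tasks.
    """

    stages: list[tuple[float, int]]
    eta: float

    def __post_init__(self) -> None:
        if any(k < 0 for k, _ in self.stages):
            raise ValueError("feedback rates must be non-negative")
        if any(n < 0 for _, n in self.stages):
            raise ValueError("stage lengths must be non-negative")
        if self.stages and self.stages[-1][0] > self.stages[0][0] / 8 \
                and len(self.stages) > 1:
            warnings.warn(
                "final feedback rate is not small relative to the initial "
                "rate; k=0 generalisation may suffer", stacklevel=2)

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.stages)

    def k_trace(self) -> np.ndarray:
        return np.concatenate([np.full(n, k) for k, n in self.stages]) \
            if self.stages else np.empty(0)

    @classmethod
    def xor(cls, n_samples: int = 1000, k: float = 75.0,
            eta: float = 1e-5) -> "FeedbackSchedule":
        """Fixed feedback rate k=75 and learning rate 1e-5."""
        return cls(stages=[(k, n_samples)], eta=eta)

    @classmethod
    def speech(cls, n_samples: int = 1000, k_start: float = 200.0,
               k_end: float = 25.0, n_stages: int = 8,
               eta: float = 1e-4) -> "FeedbackSchedule":
        """Step decay of k from 200 to 25 in 8 evenly spaced steps."""
        ks = np.linspace(k_start, k_end, n_stages)
        base, extra = divmod(n_samples, n_stages)
        stages = [(float(k), base + (1 if i < extra else 0))
                  for i, k in enumerate(ks)]
        return cls(stages=stages, eta=eta)


@dataclass
class TrainingRecord:
    """Per-sample reconstruction error and feedback-rate trace."""

    mse: list[float] = field(default_factory=list)
    k: list[float] = field(default_factory=list)
    stage_boundaries: list[int] = field(default_factory=list)


@dataclass
class SimulationResult:
    """Outputs of one ADS simulation run."""

    x_tilde: TimeSeries
    y_tilde: TimeSeries
    raster: SpikeRaster
    reconstruction_mse: float | None


@dataclass
class SilenceWindow:
    """Neurons clamped to the reset potential within [onset, offset)."""

    indices: np.ndarray
    onset: int
    offset: int


def ads_weight_update(Omega_s: np.ndarray, r: np.ndarray, e: np.ndarray,
                      F: np.ndarray, eta: float) -> np.ndarray:
    """One application of the local learning rule.

    ``delta[i, j] = eta * (F^T e)[i] * r[j]`` — the postsynaptic neuron's
    projected error times the presynaptic filtered trace.  Returns the
    updated slow-weight matrix (the input is not modified).
    """
    return Omega_s + eta * np.outer(F.T @ e, r)


def _run_ads(params: ADSNetworkParameters, c: TimeSeries,
             x_hat: TimeSeries | None, k: float, noise_sigma: float,
             rng: np.random.Generator | None, eta: float = 0.0,
             learn: bool = False, silence: SilenceWindow | None = None,
             v_init: str = "rest"):
    """Clock-driven simulation shared by inference and training paths.

    ``v_init`` selects the trial-start membrane potentials: ``"rest"``
    (all at V_rest; fully deterministic) or ``"uniform"`` (independent
    draws from U(V_reset, V_thresh), requiring ``rng``).  Uniform
    initialisation models analog neurons whose potentials are arbitrary at
    trial onset; it also guarantees that a weak input drive finds neurons
    close to threshold, so the network can ignite from silence without
    error feedback.  The training and evaluation routines use it for every
    trial.
    """
    lif = params.lif
    N, N_hat = params.N, params.N_hat
    dt = lif.dt
    if abs(c.dt - dt) > 1e-12:
        raise ValueError(f"input dt {c.dt} does not match network dt {dt}")
    if k > 0 and x_hat is None:
        raise ValueError("error feedback (k > 0) requires a teacher trajectory")
    T = c.n_steps
    Xh = x_hat.values if x_hat is not None else None

    F, Omega_f = params.F, params.Omega_f
    xb = params.x_baseline
    Omega_s = params.Omega_s.copy() if learn else params.Omega_s
    Ft = F.T
    # the task input drive is the same for every step loop iteration
    I_inp_all = Ft @ (params.F_hat @ c.values)   # (N, T)

    decay_slow = 1.0 - dt / np.asarray(lif.tau_slow)
    alpha = dt / np.asarray(lif.tau_mem)
    V_rest = np.asarray(lif.V_rest, dtype=float)
    V_reset = np.asarray(lif.V_reset, dtype=float)
    V_thresh = np.asarray(lif.V_thresh, dtype=float)
    gap = np.asarray(lif.V_thresh) - np.asarray(lif.V_reset)
    if v_init == "uniform":
        if rng is None:
            raise ValueError("uniform membrane initialisation requires rng")
        lo = np.broadcast_to(V_reset, (N,))
        hi = np.broadcast_to(V_thresh, (N,))
        V = lo + (hi - lo) * rng.random(N)
    elif v_init == "rest":
        V = np.broadcast_to(V_rest, (N,)).astype(float).copy()
    else:
        raise ValueError(f"unknown v_init mode {v_init!r}")
    I_slow = np.zeros(N)
    r = np.zeros(N)
    spikes = np.zeros(N, dtype=bool)
    raster = np.zeros((N, T), dtype=bool)
    X_tilde = np.empty((N_hat, T))
    sq_err = 0.0
    silenced = silence.indices if silence is not None else None

    for t in range(T):
        # slow PSPs from the previous step's spikes
        if spikes.any():
            idx = np.flatnonzero(spikes)
            I_slow = I_slow * decay_slow + Omega_s[:, idx].sum(axis=1)
        else:
            I_slow = I_slow * decay_slow

        total = I_inp_all[:, t] + I_slow
        if Xh is not None and k > 0:
            # corrective direction: target minus current decode
            proj_err = Ft @ (Xh[:, t] - xb - F @ r)
            total = total + k * proj_err
        V = V + alpha * (V_rest - V + total)
        if noise_sigma > 0:
            V = V + rng.normal(0.0, 1.0, size=N) * (noise_sigma * gap)
        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise FloatingPointError(
                f"non-finite membrane potential in neuron {bad} at step {t}")
        in_window = silenced is not None and silence.onset <= t < silence.offset

        # Fast feedback is instantaneous on the simulation clock
        # (tau_fast = dt): threshold crossings are resolved one at a time,
        # most-suprathreshold first, each spike's column of -Omega_f applied
        # before the next candidate is chosen.  The self-inhibition
        # (~ threshold-to-reset gap) performs the reset; sub-threshold
        # neurons whose drive was balanced away stay silent.  At most one
        # spike per neuron per step.
        spikes = np.zeros(N, dtype=bool)
        margin = V - V_thresh
        if in_window:
            margin[silenced] = -np.inf
        for _ in range(N):
            j = int(np.argmax(margin))
            if margin[j] <= 0:
                break
            spikes[j] = True
            V -= Omega_f[:, j]
            margin -= Omega_f[:, j]
            margin[j] = -np.inf
        if in_window:
            V[silenced] = V_reset if V_reset.ndim == 0 else V_reset[silenced]
        if learn and k > 0:
            Omega_s += eta * np.outer(proj_err, r)
        r = r * decay_slow + spikes
        raster[:, t] = spikes
        xt = xb + F @ r
        X_tilde[:, t] = xt
        if Xh is not None:
            d = xt - Xh[:, t]
            sq_err += float(d @ d)

    x_tilde = TimeSeries(X_tilde, dt, c.t0)
    y_tilde = TimeSeries(params.D_hat @ X_tilde, dt, c.t0)
    mse = sq_err / (N_hat * T) if Xh is not None else None
    result = SimulationResult(x_tilde, y_tilde,
                              SpikeRaster(raster, dt), mse)
    return result, Omega_s


def simulate_ads(params: ADSNetworkParameters, c: TimeSeries,
                 x_hat: TimeSeries | None = None, k: float = 0.0,
                 noise_sigma: float = 0.0,
                 rng: np.random.Generator | None = None,
                 silence: SilenceWindow | None = None,
                 v_init: str = "rest") -> SimulationResult:
    """Simulate the ADS network over an input signal (no learning).

    With ``k = 0`` (inference) no teacher trajectory is needed and the
    network runs autonomously from the task input.  When ``x_hat`` is given,
    the per-step reconstruction error is recorded in the result.  The
    default rest initialisation makes a bare call fully deterministic; the
    training/evaluation harnesses draw the trial-start potentials uniformly
    instead (see :func:`_run_ads`).
    """
    result, _ = _run_ads(params, c, x_hat, k, noise_sigma, rng,
                         silence=silence, v_init=v_init)
    return result


def train_ads(teacher: RateNetworkParameters, init: ADSNetworkParameters,
              task_sampler, schedule: FeedbackSchedule,
              rng: np.random.Generator, noise_sigma: float = 0.0,
              divergence_bound: float = 1e4, verbose: bool = False):
    """Distill the teacher into the spiking network.

    For each training sample the teacher is simulated to obtain the target
    trajectory ``x_hat``, then the spiking network runs under the current
    stage's feedback rate with the slow weights updated online at every
    step.  Returns the trained parameters and a :class:`TrainingRecord` of
    per-sample reconstruction MSE.
    """
    if teacher.N_hat != init.N_hat:
        raise ValueError("teacher and spiking network disagree on N_hat")
    params = init.copy()
    record = TrainingRecord()
    i_sample = 0
    for k, n_stage in schedule.stages:
        for _ in range(n_stage):
            sample = task_sampler(rng)
            c = sample[0] if isinstance(sample, tuple) else sample.c
            # teacher trajectories start from the resting state the silent
            # spiking network decodes, so train and test conditions match
            traj = simulate_rnn(teacher, c, x0=params.x_baseline)
            result, Omega_s = _run_ads(params, c, traj.x_hat, k,
                                       noise_sigma, rng,
                                       eta=schedule.eta, learn=True,
                                       v_init="uniform")
            if not np.all(np.isfinite(Omega_s)) or \
                    np.linalg.norm(Omega_s) > divergence_bound:
                raise FloatingPointError(
                    f"slow weights diverged at sample {i_sample}")
            params.Omega_s = Omega_s
            record.mse.append(result.reconstruction_mse)
            record.k.append(k)
            i_sample += 1
            if verbose and i_sample % 100 == 0:
                print(f"sample {i_sample}/{schedule.n_samples}: "
                      f"k={k:g} mse={result.reconstruction_mse:.5f}")
        record.stage_boundaries.append(i_sample)
    return params, record


def _network_output(net, c: TimeSeries, noise_sigma: float = 0.0,
                    rng: np.random.Generator | None = None,
                    silence: SilenceWindow | None = None) -> TimeSeries:
    """Task output of either network type on an input signal."""
    if isinstance(net, RateNetworkParameters):
        return simulate_rnn(net, c).y_hat
    if isinstance(net, ADSNetworkParameters):
        return simulate_ads(net, c, noise_sigma=noise_sigma, rng=rng,
                            silence=silence, v_init="uniform").y_tilde
    return net.output(c)  # any object exposing output(c) -> TimeSeries


def evaluate_ads(params, task_sampler, n_samples: int, readout,
                 rng: np.random.Generator,
                 teacher: RateNetworkParameters | None = None,
                 noise_sigma: float = 0.0,
                 silence: SilenceWindow | None = None) -> dict:
    """Evaluate a network at k = 0 (no teacher clamping).

    ``readout`` maps an output :class:`TimeSeries` to a class label;
    abstentions (label 0) count as incorrect.  When a teacher is supplied,
    the output MSE against the teacher's readout is reported as well.
    Returns a dict with ``accuracy``, ``mse`` (mean), and per-sample lists.
    """
    correct = 0
    mses: list[float] = []
    labels: list[int] = []
    predictions: list[int] = []
    for _ in range(n_samples):
        sample = task_sampler(rng)
        y = _network_output(params, sample.c, noise_sigma, rng, silence)
        pred = readout(y)
        predictions.append(pred)
        labels.append(sample.label)
        if pred == sample.label:
            correct += 1
        if teacher is not None:
            x0 = params.x_baseline \
                if isinstance(params, ADSNetworkParameters) else None
            y_ref = simulate_rnn(teacher, sample.c, x0=x0).y_hat
            mses.append(float(np.mean((y.values - y_ref.values) ** 2)))
    return {
        "accuracy": correct / n_samples,
        "mse": float(np.mean(mses)) if mses else None,
        "per_sample_mse": mses,
        "labels": labels,
        "predictions": predictions,
    }
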