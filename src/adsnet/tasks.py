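"""Task generators, signal front-ends and readout rules.

Two temporal tasks are provided:

* **Temporal XOR** — a 1 s single-channel signal whose first two thirds carry
  two Gaussian-smoothed activity bumps of sign +-1 and random width; the last
  third holds the target bump whose sign is the XOR of the two input signs.
  This is the package's fully synthetic benchmark.
* **Keyword detection** — 16-channel instantaneous-power features from a
  Butterworth filterbank applied to audio.  A synthetic keyword generator
  (formant-like chirp sequences embedded in coloured noise at 10 dB SNR)
  stands in for real speech corpora; real mono WAV files can be fed through
  the same front-end.

Readouts: first threshold crossing at +-0.5 for the XOR task, and a gated
output integral with a validation-chosen cut for keyword detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfilt

from .dynamics import TimeSeries

__all__ = [
    "XORSampleSpec",
    "FilterbankSpec",
    "KeywordSpec",
    "LabeledSample",
    "generate_xor_sample",
    "xor_sampler",
    "classify_xor",
    "filterbank_features",
    "synthetic_keyword_generator",
    "keyword_sampler",
    "classify_integral",
    "output_integral",
    "select_integral_threshold",
    "load_wav",
]


@dataclass(frozen=True)
class XORSampleSpec:
    """Geometry of a temporal-XOR sample.

    A sample lasts ``duration`` seconds; the first ``input_fraction`` holds
    the two input bumps and the remainder holds the target bump.  Bump
    widths are drawn uniformly from ``bump_width_range`` (66-157 ms); bumps
    are placed at random non-overlapping positions separated by at least
    ``margin``.  Rectangular bumps of magnitude +-1 are smoothed with a
    Gaussian filter of standard deviation ``smooth_std``.
    """

    duration: float = 1.0
    dt: float = 1e-3
    input_fraction: float = 2.0 / 3.0
    bump_width_range: tuple[float, float] = (66e-3, 157e-3)
    margin: float = 20e-3
    smooth_std: float = 10e-3
    target_width: float = 200e-3

    def __post_init__(self) -> None:
        w_max = self.bump_width_range[1]
        if 2 * w_max + 3 * self.margin > self.duration * self.input_fraction:
            raise ValueError("two maximal bumps do not fit in the input window")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def input_steps(self) -> int:
        return int(round(self.n_steps * self.input_fraction))


@dataclass
class LabeledSample:
    """An (input, target, class) triple with aligned time bases."""

    c: TimeSeries
    target: TimeSeries
    label: int

    def __post_init__(self) -> None:
        if abs(self.c.dt - self.target.dt) > 1e-12:
            raise ValueError("input and target must share the time base")


def generate_xor_sample(rng: np.random.Generator,
                        spec: XORSampleSpec = XORSampleSpec()) -> LabeledSample:
    """Draw one temporal-XOR sample.

    The two input signs are independent fair coin flips; the label is +1
    when they differ and -1 when they agree (an XOR up to relabelling), and
    the target bump carries the label's sign.
    """
    dt = spec.dt
    T = spec.n_steps
    T_in = spec.input_steps
    w1, w2 = (rng.uniform(*spec.bump_width_range) for _ in range(2))
    n1, n2 = int(round(w1 / dt)), int(round(w2 / dt))
    m = int(round(spec.margin / dt))
    slack = T_in - n1 - n2 - 3 * m
    g0, g1 = np.sort(rng.integers(0, slack + 1, size=2))
    start1 = m + g0
    start2 = start1 + n1 + m + (g1 - g0)
    s1, s2 = rng.choice([-1.0, 1.0], size=2)
    label = 1 if s1 != s2 else -1

    c = np.zeros(T)
    c[start1:start1 + n1] = s1
    c[start2:start2 + n2] = s2

    target = np.zeros(T)
    n_t = int(round(spec.target_width / dt))
    t_start = T_in + (T - T_in - n_t) // 2
    target[t_start:t_start + n_t] = float(label)

    sigma = spec.smooth_std / dt
    c = gaussian_filter1d(c, sigma, mode="constant")
    target = gaussian_filter1d(target, sigma, mode="constant")
    return LabeledSample(TimeSeries(c, dt), TimeSeries(target, dt), label)


def xor_sampler(spec: XORSampleSpec = XORSampleSpec()):
    """A sampler closure suitable for the training routines."""
    return lambda rng: generate_xor_sample(rng, spec)


def classify_xor(y: TimeSeries, threshold: float = 0.5,
                 target_window_fraction: float = 2.0 / 3.0) -> int:
    """Classify a single-channel output by its first threshold crossing.

    Returns +1 if the output exceeds ``+threshold`` within the target window
    before ever crossing ``-threshold``, -1 in the symmetric case, and 0
    (abstain, counted as incorrect) if neither threshold is reached.
    """
    if y.n_channels != 1:
        raise ValueError("XOR readout expects a single-channel output")
    start = int(round(y.n_steps * target_window_fraction))
    window = y.values[0, start:]
    above = np.flatnonzero(window > threshold)
    below = np.flatnonzero(window < -threshold)
    if above.size == 0 and below.size == 0:
        return 0
    if below.size == 0 or (above.size > 0 and above[0] < below[0]):
        return 1
    return -1


# ---------------------------------------------------------------------------
# Audio front-end


@dataclass(frozen=True)
class FilterbankSpec:
    """A bank of band-pass Butterworth filters with envelope extraction.

    Channel centre frequencies are evenly spaced from ``f_low`` to
    ``f_high`` (0.4-2.8 kHz over 16 channels gives a 160 Hz spacing, so
    channel ``c`` is centred at 400 + 160 c Hz).  Each band-pass output is
    rectified with ``abs`` and smoothed by a low-pass Butterworth filter to
    estimate the instantaneous power in the band, then downsampled to the
    network time step.  All filtering is causal (single pass).
    """

    n_channels: int = 16
    f_low: float = 400.0
    f_high: float = 2800.0
    order: int = 2
    lp_cutoff: float = 300.0
    lp_order: int = 2
    fs: float = 16000.0
    dt_out: float = 1e-3

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.band_edges[-1][1]:
            raise ValueError("sample rate must exceed twice the top band edge")

    @property
    def centres(self) -> np.ndarray:
        return np.linspace(self.f_low, self.f_high, self.n_channels)

    @property
    def band_edges(self) -> list[tuple[float, float]]:
        half = 0.5 * (self.centres[1] - self.centres[0])
        return [(c - half, c + half) for c in self.centres]


def filterbank_features(waveform: np.ndarray,
                        spec: FilterbankSpec = FilterbankSpec()) -> TimeSeries:
    """Instantaneous band-power features of a mono waveform."""
    waveform = np.asarray(waveform, dtype=float).ravel()
    decim = int(round(spec.fs * spec.dt_out))
    if waveform.size < 4 * decim:
        raise ValueError("waveform too short for the filterbank front-end")
    nyq = spec.fs / 2
    sos_lp = butter(spec.lp_order, spec.lp_cutoff / nyq, "lowpass", output="sos")
    out = np.empty((spec.n_channels, waveform.size // decim))
    for i, (lo, hi) in enumerate(spec.band_edges):
        sos_bp = butter(spec.order, [lo / nyq, hi / nyq], "bandpass",
                        output="sos")
        env = sosfilt(sos_lp, np.abs(sosfilt(sos_bp, waveform)))
        out[i] = env[: out.shape[1] * decim : decim]
    return TimeSeries(out, spec.dt_out)


def mix_at_snr(signal: np.ndarray, noise: np.ndarray, snr_db: float,
               eps: float = 1e-12) -> np.ndarray:
    """Add noise rescaled so the signal-to-noise power ratio is ``snr_db``."""
    p_sig = float(np.mean(signal**2))
    p_noise = float(np.mean(noise**2))
    scale = np.sqrt(p_sig / (p_noise + eps) / 10 ** (snr_db / 10))
    return signal + scale * noise


@dataclass(frozen=True)
class KeywordSpec:
    """Synthetic stand-in for a spoken-keyword corpus.

    A positive sample contains a stereotyped sequence of formant-like chirps
    (band-limited tones with smooth amplitude envelopes) embedded in
    coloured noise at ``snr_db``; a negative sample contains either the same
    chirps in shuffled order or noise alone.  The target is a smooth box
    that is high from keyword onset until shortly after its end.
    """

    duration: float = 5.0
    fs: float = 16000.0
    snr_db: float = 10.0
    chirp_freqs: tuple[tuple[float, float], ...] = (
        (600.0, 900.0), (1400.0, 1100.0), (2000.0, 2400.0))
    chirp_duration: float = 0.3
    keyword_onset: float = 1.0
    target_hold: float = 0.5
    dt_out: float = 1e-3


def _chirp(f0: float, f1: float, duration: float, fs: float) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) * t**2 / duration)
    envelope = np.sin(np.pi * t / duration) ** 2
    return envelope * np.sin(phase)


def _coloured_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = butter(2, 3000.0 / (fs / 2), "lowpass", output="sos")
    return sosfilt(sos, white)


def synthetic_keyword_generator(rng: np.random.Generator, label: int,
                                spec: KeywordSpec = KeywordSpec()):
    """Generate one synthetic keyword (+1) or distractor (-1) waveform.

    Returns ``(waveform, target, label)`` where ``target`` is a
    single-channel :class:`TimeSeries` at the network time step.
    """
    n = int(round(spec.duration * spec.fs))
    noise = _coloured_noise(rng, n, spec.fs)
    chirps = [_chirp(f0, f1, spec.chirp_duration, spec.fs)
              for f0, f1 in spec.chirp_freqs]
    order = list(range(len(chirps)))
    if label <= 0:
        if rng.random() < 0.5:
            # distractor: same chirps, wrong order
            while order == list(range(len(chirps))):
                rng.shuffle(order)
        else:
            order = []  # noise only

    signal = np.zeros(n)
    onset = int(round(spec.keyword_onset * spec.fs))
    pos = onset
    for idx in order:
        ch = chirps[idx]
        signal[pos:pos + ch.size] = ch
        pos += ch.size
    if order:
        waveform = mix_at_snr(signal, noise, spec.snr_db)
    else:
        waveform = noise / max(np.std(noise), 1e-12)

    T = int(round(spec.duration / spec.dt_out))
    target = np.zeros(T)
    if label > 0:
        hi0 = int(round(spec.keyword_onset / spec.dt_out))
        hi1 = int(round((spec.keyword_onset
                         + len(chirps) * spec.chirp_duration
                         + spec.target_hold) / spec.dt_out))
        target[hi0:hi1] = 1.0
        target = gaussian_filter1d(target, 50e-3 / spec.dt_out,
                                   mode="constant")
    return waveform, TimeSeries(target, spec.dt_out), 1 if label > 0 else -1


def keyword_sampler(spec: KeywordSpec = KeywordSpec(),
                    fb: FilterbankSpec | None = None,
                    p_positive: float = 0.5):
    """Sampler producing filterbank features of synthetic keyword audio."""
    fb = fb or FilterbankSpec(fs=spec.fs, dt_out=spec.dt_out)

    def sample(rng: np.random.Generator) -> LabeledSample:
        label = 1 if rng.random() < p_positive else -1
        waveform, target, label = synthetic_keyword_generator(rng, label, spec)
        c = filterbank_features(waveform, fb)
        n = min(c.n_steps, target.n_steps)
        return LabeledSample(TimeSeries(c.values[:, :n], c.dt),
                             TimeSeries(target.values[:, :n], c.dt), label)

    return sample


# ---------------------------------------------------------------------------
# Integral readout


def output_integral(y: TimeSeries, gate: float = 0.5) -> float:
    """Integral of the output over the steps where it exceeds the gate."""
    if y.n_channels != 1:
        raise ValueError("integral readout expects a single-channel output")
    v = y.values[0]
    return float(np.sum(v[v > gate]) * y.dt)


def classify_integral(y: TimeSeries, integral_threshold: float,
                      gate: float = 0.5) -> int:
    """Positive iff the gated output integral reaches the threshold."""
    return 1 if output_integral(y, gate) >= integral_threshold else -1


def select_integral_threshold(integrals, labels) -> float:
    """Choose the integral cut maximising validation accuracy.

    Scans the midpoints of consecutive sorted integral values (plus the two
    outer extremes) and returns the midpoint of the best split; ties go to
    the smallest candidate.
    """
    integrals = np.asarray(integrals, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("validation set must contain both classes")
    order = np.argsort(integrals)
    vals = integrals[order]
    cands = [vals[0] - 1.0]
    cands += [0.5 * (vals[i] + vals[i + 1]) for i in range(len(vals) - 1)]
    cands += [vals[-1] + 1.0]
    best_thr, best_acc = cands[0], -1.0
    for thr in cands:
        pred = np.where(integrals >= thr, 1, -1)
        acc = float(np.mean(pred == labels))
        if acc > best_acc:
            best_acc, best_thr = acc, thr
    return float(best_thr)


def load_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file as a float waveform in [-1, 1]."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(fs)
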