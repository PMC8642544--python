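"""Configuration schema, model archives and the end-to-end experiment runner.

A *model archive* is a single ``.npz`` file holding the parameter arrays
plus a JSON metadata block (format version, configuration snapshot, seeds
and a content hash over the arrays).  Round-trips are bit-exact.

An *experiment* chains the full workflow: train the teacher rate network on
a task, distill it into the spiking network, evaluate both at k = 0, and
optionally sweep the robustness grid.  Every stage draws from its own named
random stream derived from the experiment seed, so changing one stage's
seed leaves the others' draws unchanged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .distill import (ADSNetworkParameters, FeedbackSchedule, evaluate_ads,
                      train_ads)
from .dynamics import LIFParameters
from .robustness import run_robustness_suite, summarise_robustness
from .tasks import (XORSampleSpec, classify_xor, keyword_sampler,
                    output_integral, select_integral_threshold,
                    classify_integral, xor_sampler)
from .teacher import RateNetworkParameters, train_rnn

FORMAT_VERSION = 1

# fixed stream ids: changing one stage's draws never affects another's
_STREAMS = {"teacher_init": 1, "teacher_data": 2, "ads_init": 3,
            "ads_data": 4, "perturbation": 5, "evaluation": 6}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named per-stage random stream for an experiment seed."""
    return np.random.default_rng([seed, _STREAMS[stage]])


# ---------------------------------------------------------------------------
# Model archives


class ModelArchive:
    """In-memory view of a saved model: arrays + metadata."""

    def __init__(self, kind: str, arrays: dict, config: dict,
                 version: int = FORMAT_VERSION, content_hash: str | None = None):
        self.kind = kind
        self.arrays = arrays
        self.config = config
        self.version = version
        self.content_hash = content_hash or _hash_arrays(arrays)


def _hash_arrays(arrays: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        arr = np.ascontiguousarray(arrays[name])
        h.update(name.encode())
        h.update(str(arr.dtype).encode())
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    return h.hexdigest()


def save_model(path, kind: str, arrays: dict, config: dict) -> ModelArchive:
    """Write a model archive; returns the archive object."""
    archive = ModelArchive(kind, arrays, config)
    meta = {"format_version": FORMAT_VERSION, "kind": kind,
            "config": config, "content_hash": archive.content_hash}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)
    return archive


def load_model(path) -> ModelArchive:
    """Load and validate a model archive."""
    import zipfile

    try:
        with np.load(path, allow_pickle=False) as data:
            if "__meta__" not in data:
                raise ValueError(f"{path}: not a model archive (no metadata)")
            meta = json.loads(str(data["__meta__"]))
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
    except (OSError, ValueError, KeyError, EOFError,
            zipfile.BadZipFile, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt or unreadable model archive {path}: {exc}") \
            from exc
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"{path}: archive format version {version} "
                         f"not supported (expected {FORMAT_VERSION})")
    recomputed = _hash_arrays(arrays)
    stored = meta.get("content_hash")
    if stored is not None and stored != recomputed:
        raise ValueError(f"{path}: content hash mismatch, archive corrupted")
    return ModelArchive(meta["kind"], arrays, meta.get("config", {}),
                        version, recomputed)


def save_teacher(path, params: RateNetworkParameters,
                 config: dict | None = None) -> ModelArchive:
    arrays = {"tau": params.tau, "F_hat": params.F_hat,
              "Omega_hat": params.Omega_hat, "D_hat": params.D_hat,
              "b": params.b, "dt": np.asarray(params.dt)}
    return save_model(path, "teacher", arrays, config or {})


def load_teacher(path) -> RateNetworkParameters:
    archive = load_model(path)
    if archive.kind != "teacher":
        raise ValueError(f"{path} holds a {archive.kind!r} model, not a teacher")
    a = archive.arrays
    return RateNetworkParameters(a["tau"], a["F_hat"], a["Omega_hat"],
                                 a["D_hat"], a["b"], float(a["dt"]))


_LIF_FIELDS = ("tau_mem", "V_thresh", "V_reset", "V_rest",
               "tau_fast", "tau_slow")


def save_ads(path, params: ADSNetworkParameters,
             config: dict | None = None) -> ModelArchive:
    arrays = {"F": params.F, "Omega_f": params.Omega_f,
              "Omega_s": params.Omega_s, "F_hat": params.F_hat,
              "D_hat": params.D_hat, "x_baseline": params.x_baseline,
              "lif_N": np.asarray(params.lif.N),
              "lif_dt": np.asarray(params.lif.dt)}
    for name in _LIF_FIELDS:
        arrays[f"lif_{name}"] = np.asarray(getattr(params.lif, name))
    return save_model(path, "ads", arrays, config or {})


def load_ads(path) -> ADSNetworkParameters:
    archive = load_model(path)
    if archive.kind != "ads":
        raise ValueError(f"{path} holds a {archive.kind!r} model, not an "
                         "ADS network")
    a = archive.arrays
    kw = {}
    for name in _LIF_FIELDS:
        v = a[f"lif_{name}"]
        kw[name] = float(v) if v.ndim == 0 else v
    lif = LIFParameters(N=int(a["lif_N"]), dt=float(a["lif_dt"]), **kw)
    return ADSNetworkParameters(lif, a["F"], a["Omega_f"], a["Omega_s"],
                                a["F_hat"], a["D_hat"], a["x_baseline"])


# ---------------------------------------------------------------------------
# Experiment configuration


class TeacherConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_units: int = 64
    epochs: int = 20
    samples_per_epoch: int = 500
    batch_size: int = 50
    learning_rate: float = 2e-3
    recurrent_gain: float = 1.0


class ADSConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_neurons: int = 320
    schedule: str = "xor"  # preset name, or "custom" with explicit stages
    stages: Optional[list[tuple[float, int]]] = None
    eta: Optional[float] = None
    n_samples: int = 1000


class RobustnessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid: list[tuple[str, float]] = Field(default_factory=list)
    n_draws: int = 10
    n_trials: int = 1
    n_samples: int = 20


class ExperimentConfig(BaseModel):
    """Schema-validated experiment description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    task: Literal["xor", "keyword"] = "xor"
    seed: int = 0
    n_eval: int = 200
    teacher: TeacherConfig = Field(default_factory=TeacherConfig)
    ads: ADSConfig = Field(default_factory=ADSConfig)
    robustness: Optional[RobustnessConfig] = None


EXPERIMENT_PRESETS: dict[str, dict] = {
    "xor": {"task": "xor", "teacher": {"n_units": 64, "epochs": 20,
                                       "samples_per_epoch": 500},
            "ads": {"n_neurons": 320, "schedule": "xor",
                    "n_samples": 1000}},
    # quick smoke configuration
    "xor-small": {"task": "xor", "n_eval": 50,
                  "teacher": {"n_units": 32, "epochs": 4,
                              "samples_per_epoch": 100, "batch_size": 25},
                  "ads": {"n_neurons": 80, "schedule": "xor",
                          "n_samples": 100}},
}


def make_schedule(cfg: ADSConfig) -> FeedbackSchedule:
    if cfg.schedule == "xor":
        return FeedbackSchedule.xor(n_samples=cfg.n_samples,
                                    eta=cfg.eta or 1e-5)
    if cfg.schedule == "speech":
        return FeedbackSchedule.speech(n_samples=cfg.n_samples,
                                       eta=cfg.eta or 1e-4)
    if cfg.schedule == "custom":
        if not cfg.stages or cfg.eta is None:
            raise ValueError("custom schedule requires explicit stages and eta")
        return FeedbackSchedule(stages=[(float(k), int(n))
                                        for k, n in cfg.stages], eta=cfg.eta)
    raise ValueError(f"unknown schedule preset {cfg.schedule!r}")


def make_sampler(task: str):
    if task == "xor":
        return xor_sampler(XORSampleSpec()), classify_xor
    if task == "keyword":
        sampler = keyword_sampler()
        return sampler, None  # integral readout is calibrated downstream
    raise ValueError(f"unknown task {task!r}")


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Execute train-teacher -> train-ads -> evaluate, writing artifacts.

    Writes ``teacher.npz``, ``ads.npz``, ``training_record.csv``,
    ``evaluation.json`` and (if configured) ``robustness.csv`` under
    ``out_dir``; returns a summary dict with the evaluation numbers.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.model_dump()
    seed = config.seed
    sampler, readout = make_sampler(config.task)

    # --- stage 1: teacher ---------------------------------------------------
    try:
        t_rng = stage_rng(seed, "teacher_init")
        sample0 = sampler(np.random.default_rng(0))
        d1, d2 = sample0.c.n_channels, sample0.target.n_channels
        teacher0 = RateNetworkParameters.initialise(
            config.teacher.n_units, d1, d2, t_rng,
            recurrent_gain=config.teacher.recurrent_gain)
        teacher, losses = train_rnn(
            sampler, teacher0, config.teacher.epochs,
            config.teacher.samples_per_epoch, config.teacher.learning_rate,
            stage_rng(seed, "teacher_data"),
            batch_size=config.teacher.batch_size)
    except Exception as exc:
        raise RuntimeError(f"stage train-teacher failed: {exc}") from exc
    save_teacher(out_dir / "teacher.npz", teacher,
                 {"experiment": cfg_dict, "seed": seed})
    pd.DataFrame({"loss": losses}).to_csv(out_dir / "teacher_loss.csv",
                                          index=False)

    # --- stage 2: spiking distillation -------------------------------------
    try:
        ads0 = ADSNetworkParameters.initialise(
            teacher, config.ads.n_neurons, stage_rng(seed, "ads_init"))
        schedule = make_schedule(config.ads)
        ads, record = train_ads(teacher, ads0, sampler, schedule,
                                stage_rng(seed, "ads_data"))
    except Exception as exc:
        raise RuntimeError(f"stage train-ads failed: {exc}") from exc
    save_ads(out_dir / "ads.npz", ads, {"experiment": cfg_dict, "seed": seed})
    pd.DataFrame({"mse": record.mse, "k": record.k}).to_csv(
        out_dir / "training_record.csv", index=False)

    # --- stage 3: evaluation ------------------------------------------------
    try:
        if readout is None:
            readout = _calibrated_integral_readout(teacher, sampler, seed)
        eval_teacher = evaluate_ads(teacher, sampler, config.n_eval, readout,
                                    stage_rng(seed, "evaluation"))
        eval_ads = evaluate_ads(ads, sampler, config.n_eval, readout,
                                stage_rng(seed, "evaluation"),
                                teacher=teacher)
    except Exception as exc:
        raise RuntimeError(f"stage evaluate failed: {exc}") from exc

    summary = {
        "config": cfg_dict,
        "stage_seeds": {k: [seed, v] for k, v in _STREAMS.items()},
        "teacher_accuracy": eval_teacher["accuracy"],
        "teacher_final_loss": losses[-1] if losses else None,
        "ads_accuracy": eval_ads["accuracy"],
        "ads_output_mse": eval_ads["mse"],
        "ads_final_reconstruction_mse": record.mse[-1] if record.mse else None,
    }

    if config.robustness is not None and config.robustness.grid:
        results = run_robustness_suite(
            ads, teacher, sampler, readout,
            [(k, float(v)) for k, v in config.robustness.grid],
            n_draws=config.robustness.n_draws,
            n_trials=config.robustness.n_trials,
            n_samples=config.robustness.n_samples, seed=seed)
        results.to_csv(out_dir / "robustness.csv", index=False)
        summarise_robustness(results).to_csv(
            out_dir / "robustness_summary.csv", index=False)

    with open(out_dir / "evaluation.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _calibrated_integral_readout(teacher, sampler, seed, n_validation=40):
    """Calibrate the integral threshold on teacher outputs."""
    from .teacher import simulate_rnn

    rng = np.random.default_rng([seed, 7])
    integrals, labels = [], []
    for _ in range(n_validation):
        s = sampler(rng)
        y = simulate_rnn(teacher, s.c).y_hat
        integrals.append(output_integral(y))
        labels.append(s.label)
    thr = select_integral_threshold(integrals, labels)
    return lambda y: classify_integral(y, thr)


def load_config(path, preset: str | None = None,
                overrides: dict | None = None) -> ExperimentConfig:
    """Build a validated config from a preset name and/or a JSON file."""
    data: dict = {}
    if preset is not None:
        if preset not in EXPERIMENT_PRESETS:
            raise ValueError(f"unknown preset {preset!r}; available: "
                             f"{sorted(EXPERIMENT_PRESETS)}")
        data = json.loads(json.dumps(EXPERIMENT_PRESETS[preset]))
    if path is not None:
        with open(path) as fh:
            data.update(json.load(fh))
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    return ExperimentConfig.model_validate(data)
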