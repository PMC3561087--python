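"""Run configuration, tabular I/O, and synthetic-fixture generation.

Configs are JSON and schema-validated (pydantic) before any computation, so
malformed runs fail with a message naming the offending field.  Trajectories,
datasets and particle populations are CSV with a JSON metadata sidecar;
floats are written with shortest-round-trip formatting so write/read
round-trips are exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import models as _models
from .models import ExperimentSpec, build_akt, build_hes1, build_repressilator_menu
from .priors import ParticlePopulation, UniformPrior
from .simulate import Dataset, SolverSettings, integrate, observe
from .stimulus import StimulusSpec

logger = logging.getLogger("infodesign")

__all__ = [
    "RunConfig", "ConfigError", "load_config", "write_report",
    "write_dataset", "read_dataset", "write_population", "read_population",
    "generate_fixture", "builtin_menu",
]


class ConfigError(ValueError):
    """Configuration file failed validation."""


class EstimatorConfig(BaseModel):
    N: int = Field(1000, ge=2)
    M: int = Field(1000, ge=2)
    K: int = Field(100, ge=1)
    R: int = Field(5, ge=1)
    reuse_outer: bool = False


class SolverConfig(BaseModel):
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-8, gt=0)

    def to_settings(self) -> SolverSettings:
        return SolverSettings(rtol=self.rtol, atol=self.atol)


class StimulusConfig(BaseModel):
    shape: str = "none"
    amplitude: float = Field(0.0, ge=0)
    duration: float = 0.0
    onset: float = 0.0
    n_pulses: int = 1
    spacing: float = 0.0
    background_noise_variance: float = Field(0.0, ge=0)
    noise_grid_dt: float = Field(1.0, gt=0)

    def to_spec(self) -> Optional[StimulusSpec]:
        if self.shape == "none":
            return None
        return StimulusSpec(**self.model_dump())


class ExperimentConfig(BaseModel):
    id: str
    observed: list[str]
    time_grid: list[float]
    noise_variance: dict[str, float]
    overrides: dict[str, tuple[str, float]] = Field(default_factory=dict)
    stimulus: Optional[StimulusConfig] = None
    stimulus_seed: Optional[int] = None

    @field_validator("time_grid")
    @classmethod
    def _increasing(cls, v):
        if len(v) < 2 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("time_grid must be strictly increasing with >= 2 points")
        return v


class RunConfig(BaseModel):
    """Validated top-level run configuration."""

    model: str
    prior: Optional[dict[str, tuple[float, float]]] = None
    experiments: Optional[list[ExperimentConfig]] = None
    estimator: EstimatorConfig = EstimatorConfig()
    solver: SolverConfig = SolverConfig()
    seed: int = 0

    def build_prior(self) -> UniformPrior:
        if self.prior is not None:
            return UniformPrior.from_dict(self.prior)
        return default_prior(self.model)

    def build_experiments(self) -> list:
        base_model = _base_model(self.model)
        if self.experiments is None:
            return builtin_menu(self.model)
        out = []
        for ec in self.experiments:
            stim = ec.stimulus.to_spec() if ec.stimulus is not None else None
            out.append(ExperimentSpec(
                id=ec.id, model=base_model, observed=tuple(ec.observed),
                time_grid=np.asarray(ec.time_grid), noise_variance=ec.noise_variance,
                parameter_overrides={k: tuple(v) for k, v in ec.overrides.items()},
                stimulus=stim, stimulus_seed=ec.stimulus_seed))
        return out


def _base_model(name: str):
    if name == "repressilator":
        return build_repressilator_menu()[0].model
    if name == "hes1":
        return build_hes1()[0]
    if name == "akt":
        return build_akt()[0]
    raise ConfigError(f"unknown model {name!r}; expected repressilator, hes1 or akt")


def default_prior(name: str) -> UniformPrior:
    if name == "repressilator":
        return _models.repressilator_prior()
    if name == "hes1":
        return _models.hes1_prior()
    if name == "akt":
        return _models.akt_prior()
    raise ConfigError(f"unknown model {name!r}")


def builtin_menu(name: str) -> list:
    """The default candidate-experiment menu for a built-in model."""
    if name == "repressilator":
        return build_repressilator_menu()
    if name == "hes1":
        return build_hes1()[1]
    if name == "akt":
        _, candidates, target = build_akt()
        return candidates + [target]
    raise ConfigError(f"unknown model {name!r}")


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors())
        raise ConfigError(f"{path}: {locs}") from exc


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _frame(time_grid, observed, values) -> pd.DataFrame:
    df = pd.DataFrame(values, columns=list(observed))
    df.insert(0, "time", time_grid)
    return df


def _write_csv(df: pd.DataFrame, path):
    # repr-style floats give exact round-trips
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def write_dataset(ds, path, meta_extra=None):
    """Write a Trajectory or Dataset as ``time,<obs...>`` CSV + JSON sidecar."""
    path = Path(path)
    _write_csv(_frame(ds.time_grid, ds.observed, ds.values), path)
    meta = {"experiment_id": ds.experiment_id, "observed": list(ds.observed)}
    if isinstance(ds, Dataset):
        meta["noise_variance"] = list(np.atleast_1d(ds.noise_variance))
        meta["seed"] = ds.seed
    if meta_extra:
        meta.update(meta_extra)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path) -> Dataset:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ConfigError(f"{path}: unreadable CSV: {exc}") from exc
    if "time" not in df.columns or df.shape[1] < 2:
        raise ConfigError(f"{path}: expected columns 'time,<observable...>'")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    observed = tuple(c for c in df.columns if c != "time")
    nv = np.asarray(meta.get("noise_variance", np.zeros(len(observed))), dtype=float)
    return Dataset(meta.get("experiment_id", path.stem), df["time"].to_numpy(),
                   observed, df[list(observed)].to_numpy(), nv,
                   seed=meta.get("seed"))


def write_population(pop: ParticlePopulation, path):
    path = Path(path)
    df = pd.DataFrame(pop.particles, columns=list(pop.names))
    df["weight"] = pop.weights
    _write_csv(df, path)
    side = {"epsilon_schedule": list(pop.epsilon_schedule),
            "acceptance_rates": list(pop.acceptance_rates),
            "generation": pop.generation}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(side, indent=2))


def read_population(path) -> ParticlePopulation:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "weight" not in df.columns:
        raise ConfigError(f"{path}: population CSV needs a 'weight' column")
    names = tuple(c for c in df.columns if c != "weight")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ParticlePopulation(df[list(names)].to_numpy(), df["weight"].to_numpy(),
                              names=names,
                              epsilon_schedule=tuple(meta.get("epsilon_schedule", ())),
                              acceptance_rates=tuple(meta.get("acceptance_rates", ())),
                              generation=meta.get("generation", 0))


def write_report(report, path):
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def generate_fixture(model, experiment: ExperimentSpec, theta_true, seed: int,
                     out_dir=None, prior: Optional[UniformPrior] = None):
    """Simulate the experiment at ``theta_true`` and draw one noisy dataset.

    Returns ``(trajectory, dataset)``; if ``out_dir`` is given, writes
    ``<id>_trajectory.csv`` and ``<id>_data.csv`` (plus sidecars) there.
    Regeneration from the same seed is bit-identical.
    """
    theta_true = np.asarray(theta_true, dtype=float)
    if prior is not None and not prior.contains(theta_true)[0]:
        raise ConfigError("theta_true lies outside the prior support")
    traj = integrate(model, theta_true, experiment)
    noise_rng_seed = np.random.SeedSequence([int(seed), 0xDA7A]).generate_state(1)[0]
    ds = observe(traj, experiment.sigma2_vector(), int(noise_rng_seed))
    ds = Dataset(ds.experiment_id, ds.time_grid, ds.observed, ds.values,
                 ds.noise_variance, seed=int(seed))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_dataset(traj, out_dir / f"{experiment.id}_trajectory.csv",
                      meta_extra={"theta_true": list(theta_true)})
        write_dataset(ds, out_dir / f"{experiment.id}_data.csv",
                      meta_extra={"theta_true": list(theta_true)})
    return traj, ds
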