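"""Deterministic ODE integration, the Gaussian observation model, and the
corresponding log-likelihood.

The observation model is ``y = f(theta, e) + eps`` with ``eps`` uncorrelated
zero-mean Gaussian noise, homoscedastic per observable.  This single model
underlies everything downstream: the mutual-information estimators evaluate
its density, ABC compares noisy data against ``f``, and fixtures are drawn
from it.

Stimulus discontinuities (step edges, pulse edges, noise-grid switches) are
handled by integrating piecewise between breakpoints, since adaptive solvers
assume a smooth right-hand side.  All log-densities are natural-log (nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import odeint

from .models import ExperimentSpec, OdeModel
from .stimulus import StimulusPath

__all__ = [
    "Trajectory",
    "Dataset",
    "SolverSettings",
    "IntegrationError",
    "integrate",
    "observe",
    "log_likelihood",
    "LOG_ZERO",
]

#: Sentinel log-density for rejected / failed samples (safely below any
#: reachable Gaussian log-likelihood, but finite so arithmetic stays defined).
LOG_ZERO = -1e300


class IntegrationError(RuntimeError):
    """ODE solver failure (stiffness, blow-up, non-finite state).

    Carries the offending parameter vector so Monte-Carlo callers can reject
    and redraw while reporting the failure.
    """

    def __init__(self, message, theta=None):
        super().__init__(message)
        self.theta = None if theta is None else np.asarray(theta, float)


@dataclass(frozen=True)
class SolverSettings:
    """LSODA settings. Defaults handle the stiff cascades used here."""

    rtol: float = 1e-6
    atol: float = 1e-8
    mxstep: int = 10_000


@dataclass(frozen=True)
class Trajectory:
    """Noise-free model output f(theta, e) on an observation grid."""

    experiment_id: str
    time_grid: np.ndarray
    observed: tuple
    values: np.ndarray  # (n_times, n_observed)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.time_grid, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "time_grid", t)
        if v.shape != (t.size, len(self.observed)):
            raise ValueError(
                f"values shape {v.shape} does not match grid {t.size} x "
                f"{len(self.observed)} observables")
        if not np.all(np.isfinite(v)):
            raise ValueError("trajectory contains non-finite values")


@dataclass(frozen=True)
class Dataset:
    """A noisy observation of a trajectory (same shape), with provenance."""

    experiment_id: str
    time_grid: np.ndarray
    observed: tuple
    values: np.ndarray
    noise_variance: np.ndarray  # per observable
    seed: Optional[int] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "time_grid", np.asarray(self.time_grid, dtype=float))
        object.__setattr__(self, "noise_variance", np.asarray(self.noise_variance, dtype=float))
        if v.shape != (self.time_grid.size, len(self.observed)):
            raise ValueError("dataset shape inconsistent with grid/observables")


def _integrate_states(model: OdeModel, theta: np.ndarray, time_grid: np.ndarray,
                      path, settings: SolverSettings) -> np.ndarray:
    """Integrate the full state over `time_grid`, splitting at stimulus
    breakpoints.  Returns (n_times, k) state matrix."""
    x = model.x0(theta)
    if not np.all(np.isfinite(x)):
        raise IntegrationError("non-finite initial state", theta)

    t0 = 0.0
    grid = np.asarray(time_grid, dtype=float)
    if grid[0] < 0:
        raise IntegrationError("time grid must be non-negative", theta)

    if path is None:
        def rhs(xv, tv):
            return model.rhs(xv, tv, theta, 0.0)
        segments = [(t0, grid[-1])]
    else:
        def rhs(xv, tv):
            return model.rhs(xv, tv, theta, path(tv))
        bps = path.breakpoints(t0, grid[-1])
        edges = np.concatenate([[t0], bps, [grid[-1]]])
        segments = list(zip(edges[:-1], edges[1:]))

    out = np.empty((grid.size, x.size))
    filled = np.zeros(grid.size, dtype=bool)
    if grid[0] == t0:
        out[0] = x
        filled[0] = True

    with np.errstate(over="ignore", invalid="ignore"):
        for a, b in segments:
            # observation times inside this smooth segment
            idx = np.where((grid > a) & (grid <= b))[0]
            ts = np.concatenate([[a], grid[idx]])
            if idx.size == 0 or grid[idx[-1]] < b:
                ts = np.concatenate([ts, [b]])
            try:
                sol, info = odeint(rhs, x, ts, rtol=settings.rtol, atol=settings.atol,
                                   mxstep=settings.mxstep, full_output=True,
                                   printmessg=False)
            except Exception as exc:  # pragma: no cover - solver internals
                raise IntegrationError(f"solver failure: {exc}", theta) from exc
            if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
                raise IntegrationError("solver failure: " + str(info["message"]), theta)
            out[idx] = sol[1:1 + idx.size]
            filled[idx] = True
            x = sol[-1]
    if not filled.all():
        raise IntegrationError("internal error: grid times lost during segmentation", theta)
    return out


def integrate(model: OdeModel, theta, experiment: ExperimentSpec,
              settings: SolverSettings = SolverSettings()) -> Trajectory:
    """Deterministic model output f(theta, e) at the experiment's grid times.

    Parameter overrides of the experiment are applied first; the stimulus
    path (if any) is fixed by the experiment's ``stimulus_seed`` so the
    right-hand side is fully deterministic.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.n_parameters,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({model.n_parameters},)")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    th = experiment.apply_overrides(theta)

    path = None
    if experiment.stimulus is not None and experiment.stimulus.shape != "none":
        path = StimulusPath(experiment.stimulus, t_max=float(experiment.time_grid[-1]),
                            seed=experiment.stimulus_seed)

    states = _integrate_states(model, th, experiment.time_grid, path, settings)
    C = model.observable_matrix(experiment.observed)
    values = states @ C.T
    if not np.all(np.isfinite(values)):
        raise IntegrationError("non-finite observables", theta)
    return Trajectory(experiment.id, experiment.time_grid, experiment.observed, values)


def observe(trajectory: Trajectory, noise_variance, seed) -> Dataset:
    """Draw y = f + eps with independent Gaussian noise per (time, observable)."""
    s2 = np.atleast_1d(np.asarray(noise_variance, dtype=float))
    if s2.size == 1:
        s2 = np.full(len(trajectory.observed), float(s2[0]))
    if s2.shape != (len(trajectory.observed),):
        raise ValueError("noise_variance must be scalar or one value per observable")
    if np.any(s2 < 0):
        raise ValueError("noise variances must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(s2), size=trajectory.values.shape)
    return Dataset(trajectory.experiment_id, trajectory.time_grid, trajectory.observed,
                   trajectory.values + eps, s2, seed=seed if np.isscalar(seed) else None)


def log_likelihood(dataset, trajectory, noise_variance) -> float:
    """Gaussian log-density of the data given the trajectory, summed over all
    (time, observable) cells.  Accepts Dataset/Trajectory objects or bare
    value matrices of equal shape."""
    y = dataset.values if hasattr(dataset, "values") else np.asarray(dataset, float)
    f = trajectory.values if hasattr(trajectory, "values") else np.asarray(trajectory, float)
    if y.shape != f.shape:
        raise ValueError(f"shape mismatch: data {y.shape} vs trajectory {f.shape}")
    s2 = np.atleast_1d(np.asarray(noise_variance, dtype=float))
    if s2.size == 1:
        s2 = np.full(y.shape[-1] if y.ndim > 1 else 1, float(s2[0]))
    if np.any(s2 <= 0):
        raise ValueError("log_likelihood requires strictly positive variances")
    resid2 = (y - f) ** 2
    if y.ndim == 1:
        resid2 = resid2[:, None]
    n_t = resid2.shape[0]
    ll = -0.5 * np.sum(resid2 / s2) - 0.5 * n_t * np.sum(np.log(2.0 * np.pi * s2))
    return float(ll)
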