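"""Likelihood-free posterior inference by ABC sequential Monte Carlo.

Once data for a selected experiment have been collected (or simulated), the
posterior p(theta | D) is approximated by a particle population: parameters
are sampled, the system simulated, and particles kept when the simulation
lands within a tolerance epsilon of the data.  A sequence of shrinking
tolerances with kernel perturbation and importance weighting turns the prior
population into a posterior approximation.

Two points matter for deterministic ODE models with Gaussian measurement
noise (the observation model used throughout this package):

* simulations entering the distance are themselves *noisy* — the full
  generative process y = f(theta) + eps is simulated.  Comparing noise-free
  trajectories against noisy data makes the accepted region collapse onto
  the best-fitting parameter point as epsilon shrinks, which understates the
  posterior spread; simulating the noise restores the standard ABC limit.
* the default perturbation kernel is a full-covariance Gaussian with twice
  the weighted empirical covariance of the previous population.  Posteriors
  of dynamical models concentrate on correlated ridges, where a
  component-wise kernel wastes almost every proposal; the component-wise
  variant remains available as ``kernel="component"``.

The tolerance schedule takes the q-th quantile (default median) of the
previous generation's accepted distances; the run stops when the acceptance
rate per *simulation* (proposals falling outside the prior are free and not
counted) drops below a floor, or at ``max_generations``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ExperimentSpec, OdeModel
from .priors import ParticlePopulation, UniformPrior
from .simulate import Dataset, IntegrationError, SolverSettings, integrate

__all__ = ["distance", "fit", "fit_multi", "AbcSettings", "AbcError"]


class AbcError(RuntimeError):
    """ABC SMC failed to produce a population."""


@dataclass(frozen=True)
class AbcSettings:
    n_particles: int = 200
    max_generations: int = 8
    quantile: float = 0.5
    min_acceptance_rate: float = 0.01
    max_simulations_per_generation: int = 100_000
    kernel: str = "full"            # "full" | "component"
    noisy_simulations: bool = True  # simulate y = f(theta) + eps in the distance
    solver: SolverSettings = SolverSettings()

    def __post_init__(self):
        if self.kernel not in ("full", "component"):
            raise ValueError("kernel must be 'full' or 'component'")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")


def distance(dataset, simulated, column_scale=None) -> float:
    """Scale-balanced Euclidean distance between data and a simulation.

    Each observable column is divided by the dataset column's standard
    deviation (or by explicit ``column_scale``), then all cells enter a
    plain Euclidean norm.  Zero-variance columns fall back to scale 1.
    """
    y = dataset.values if hasattr(dataset, "values") else np.asarray(dataset, float)
    f = simulated.values if hasattr(simulated, "values") else np.asarray(simulated, float)
    if y.shape != f.shape:
        raise ValueError(f"shape mismatch: data {y.shape} vs simulation {f.shape}")
    y2 = np.atleast_2d(y)
    f2 = np.atleast_2d(f)
    if column_scale is None:
        column_scale = y2.std(axis=0)
    scale = np.where(np.asarray(column_scale) > 0, column_scale, 1.0)
    return float(np.sqrt(np.sum(((y2 - f2) / scale) ** 2)))


def fit(model: OdeModel, experiment: ExperimentSpec, dataset: Dataset,
        prior: UniformPrior, settings: AbcSettings = AbcSettings(),
        seed: int = 0) -> ParticlePopulation:
    """ABC SMC posterior for one experiment's dataset."""
    return fit_multi(model, [(experiment, dataset)], prior, settings, seed)


class _Kernel:
    """Perturbation kernel refreshed per generation from the population."""

    def __init__(self, particles, weights, mode):
        self.mode = mode
        mu = weights @ particles
        centred = particles - mu
        if mode == "component":
            var = weights @ centred ** 2
            self.sd = np.sqrt(2.0 * np.maximum(var, 1e-30))
            self._logconst = -0.5 * np.sum(np.log(2.0 * np.pi * self.sd ** 2))
        else:
            cov = 2.0 * (centred.T * weights) @ centred
            cov += np.eye(cov.shape[0]) * (1e-12 * max(np.trace(cov), 1e-30))
            self.L = np.linalg.cholesky(cov)
            self._logconst = (-0.5 * cov.shape[0] * np.log(2.0 * np.pi)
                              - np.sum(np.log(np.diag(self.L))))

    def perturb(self, theta, rng):
        z = rng.normal(size=theta.size)
        if self.mode == "component":
            return theta + self.sd * z
        return theta + self.L @ z

    def log_density(self, particles, cand):
        diff = particles - cand
        if self.mode == "component":
            q = np.sum((diff / self.sd) ** 2, axis=1)
        else:
            sol = np.linalg.solve(self.L, diff.T)
            q = np.sum(sol ** 2, axis=0)
        return -0.5 * q + self._logconst


def fit_multi(model, experiment_datasets, prior,
              settings: AbcSettings = AbcSettings(), seed: int = 0) -> ParticlePopulation:
    """ABC SMC posterior conditioning on several (experiment, dataset) pairs.

    The per-experiment scale-balanced distances are summed; this is how
    sequential rounds of data enter a single refit from the original prior.
    """
    if not experiment_datasets:
        raise ValueError("at least one (experiment, dataset) pair is required")
    n_p = settings.n_particles
    if n_p < 100:
        raise ValueError("n_particles must be >= 100 for a usable population")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xABC]))
    scales = [np.atleast_2d(ds.values).std(axis=0) for _, ds in experiment_datasets]

    def total_distance(theta):
        d = 0.0
        for (exp, ds), sc in zip(experiment_datasets, scales):
            try:
                traj = integrate(model, theta, exp, settings.solver)
            except IntegrationError:
                return np.inf
            sim = traj.values
            if settings.noisy_simulations:
                s2 = exp.sigma2_vector()
                sim = sim + rng.normal(size=sim.shape) * np.sqrt(s2)
            d += distance(ds.values, sim, column_scale=sc)
            if not np.isfinite(d):
                return np.inf
        return d

    # generation 0: plain prior sample, epsilon = +inf
    particles = prior.sample(n_p, rng)
    dists = np.array([total_distance(t) for t in particles])
    ok = np.isfinite(dists)
    if not ok.any():
        raise AbcError("no prior draw produced a finite distance")
    particles, dists = particles[ok], dists[ok]
    weights = np.full(particles.shape[0], 1.0 / particles.shape[0])
    eps_schedule = []
    acc_rates = [float(ok.mean())]

    prior_lower = getattr(prior, "lower", None)
    prior_upper = getattr(prior, "upper", None)

    for gen in range(1, settings.max_generations + 1):
        eps = float(np.quantile(dists, settings.quantile))
        if eps_schedule and eps >= eps_schedule[-1]:
            eps = np.nextafter(eps_schedule[-1], 0.0)  # enforce strict decrease
        kernel = _Kernel(particles, weights, settings.kernel)

        new_particles = np.empty((n_p, particles.shape[1]))
        new_dists = np.empty(n_p)
        new_weights = np.empty(n_p)
        accepted = 0
        n_sims = 0
        rolled_back = False
        while accepted < n_p:
            if n_sims > settings.max_simulations_per_generation:
                if not rolled_back and accepted == 0:
                    # tolerance rollback: retry once with a looser epsilon
                    eps = float(np.quantile(dists, min(0.9, settings.quantile + 0.25)))
                    n_sims = 0
                    rolled_back = True
                    continue
                if accepted == 0:
                    raise AbcError(
                        f"generation {gen}: no acceptances after rollback "
                        f"(epsilon={eps:.4g})")
                break  # keep the truncated generation
            idx = rng.choice(particles.shape[0], p=weights)
            cand = kernel.perturb(particles[idx], rng)
            if prior_lower is not None and (
                    np.any(cand < prior_lower) or np.any(cand > prior_upper)):
                continue  # outside the prior: free rejection, no simulation
            n_sims += 1
            d = total_distance(cand)
            if d <= eps:
                # uniform prior: numerator of the importance weight is constant
                log_dens = kernel.log_density(particles, cand)
                m = float(log_dens.max())
                log_denom = m + np.log(np.sum(weights * np.exp(log_dens - m)))
                new_particles[accepted] = cand
                new_dists[accepted] = d
                new_weights[accepted] = np.exp(np.clip(-log_denom, -700, 700))
                accepted += 1
        particles = new_particles[:accepted]
        dists = new_dists[:accepted]
        weights = new_weights[:accepted] / new_weights[:accepted].sum()
        eps_schedule.append(eps)
        rate = accepted / max(n_sims, 1)
        acc_rates.append(float(rate))
        if rate < settings.min_acceptance_rate:
            break

    return ParticlePopulation(
        particles, weights, names=tuple(getattr(prior, "names", ())),
        epsilon_schedule=tuple(eps_schedule), acceptance_rates=tuple(acc_rates),
        generation=len(eps_schedule),
    )
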