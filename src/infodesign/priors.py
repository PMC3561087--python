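"""Prior distributions over ODE model parameters.

Two concrete sampleable priors are provided:

* :class:`UniformPrior` — independent uniform marginals with per-parameter
  bounds, the analytic prior used throughout the case studies;
* :class:`ParticlePopulation` — a weighted particle set produced by ABC SMC,
  used as a "posterior-as-prior" sampling distribution for sequential design.

The mutual-information estimators only require draws (never densities), which
is what makes the posterior-as-prior mechanism work.  The single-component
estimator additionally needs conditional draws with one coordinate pinned,
which is only well-defined here for priors with independent components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UniformPrior",
    "ParticlePopulation",
    "IndependentGaussianPrior",
]


class UnsupportedPriorOperation(RuntimeError):
    """Raised when a conditional draw is requested from a dependent prior."""


@dataclass(frozen=True)
class UniformPrior:
    """Independent uniform marginals, one ``(lower, upper)`` pair per parameter."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "names", tuple(self.names))
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be 1-D arrays of equal length")
        if len(self.names) != lo.size:
            raise ValueError("names must match the number of bounds")
        if not np.all(lo < hi):
            raise ValueError("every prior interval needs lower < upper")

    @classmethod
    def from_dict(cls, bounds: dict) -> "UniformPrior":
        names = tuple(bounds)
        lo = np.array([bounds[k][0] for k in names], dtype=float)
        hi = np.array([bounds[k][1] for k in names], dtype=float)
        return cls(names, lo, hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def independent_components(self) -> bool:
        return True

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def resample_others(self, i: int, theta: np.ndarray, n: int,
                        rng: np.random.Generator) -> np.ndarray:
        """Draw *n* vectors from the prior with component *i* pinned to ``theta[i]``."""
        out = self.sample(n, rng)
        out[:, i] = theta[i]
        return out

    def contains(self, theta: np.ndarray) -> np.ndarray:
        t = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((t >= self.lower) & (t <= self.upper), axis=1)

    def variances(self) -> np.ndarray:
        return (self.upper - self.lower) ** 2 / 12.0

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}; have {list(self.names)}")


@dataclass(frozen=True)
class IndependentGaussianPrior:
    """Independent Gaussian marginals.

    Not used by the built-in case studies (those are uniform) but a first-class
    prior: it is the natural sampling distribution for linear-Gaussian
    benchmark problems where the mutual information has a closed form.
    """

    names: tuple
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        object.__setattr__(self, "names", tuple(self.names))
        if np.any(self.std <= 0):
            raise ValueError("standard deviations must be positive")

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def independent_components(self) -> bool:
        return True

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.std, size=(n, self.dim))

    def resample_others(self, i, theta, n, rng):
        out = self.sample(n, rng)
        out[:, i] = theta[i]
        return out

    def contains(self, theta):
        t = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.ones(t.shape[0], dtype=bool)

    def variances(self):
        return self.std ** 2

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ParticlePopulation:
    """Weighted particle approximation of a (posterior) distribution.

    Produced by :func:`infodesign.abc_smc.fit`; usable anywhere a sampleable
    prior is accepted.  ``epsilon_schedule`` and ``acceptance_rates`` record
    the SMC run that generated it.
    """

    particles: np.ndarray
    weights: np.ndarray
    names: tuple = ()
    epsilon_schedule: tuple = ()
    acceptance_rates: tuple = ()
    generation: int = 0

    def __post_init__(self):
        self.particles = np.asarray(self.particles, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.particles.ndim != 2:
            raise ValueError("particles must be an (n_particles, dim) matrix")
        if self.weights.shape != (self.particles.shape[0],):
            raise ValueError("one weight per particle required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must sum to a positive finite value")
        self.weights = self.weights / total
        if not self.names:
            self.names = tuple(f"theta_{i}" for i in range(self.particles.shape[1]))

    @property
    def dim(self) -> int:
        return self.particles.shape[1]

    @property
    def n_particles(self) -> int:
        return self.particles.shape[0]

    @property
    def independent_components(self) -> bool:
        # Particle sets carry arbitrary dependence; conditional draws with one
        # coordinate pinned are not defined for them.
        return False

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(self.n_particles, size=n, replace=True, p=self.weights)
        return self.particles[idx]

    def resample_others(self, i, theta, n, rng):
        raise UnsupportedPriorOperation(
            "single-component mutual information requires a prior with "
            "independent components; particle populations are not supported"
        )

    def resampled(self, n: int, rng: np.random.Generator) -> "ParticlePopulation":
        """Equal-weight population of *n* particles resampled by weight."""
        return ParticlePopulation(
            self.sample(n, rng), np.full(n, 1.0 / n), names=self.names,
            epsilon_schedule=self.epsilon_schedule,
            acceptance_rates=self.acceptance_rates, generation=self.generation,
        )

    def mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def var(self) -> np.ndarray:
        mu = self.mean()
        return self.weights @ (self.particles - mu) ** 2

    def credible_interval(self, i: int, level: float = 0.95) -> tuple:
        """Weighted quantile interval for parameter *i*."""
        order = np.argsort(self.particles[:, i])
        x = self.particles[order, i]
        cw = np.cumsum(self.weights[order])
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        lo = x[np.searchsorted(cw, lo_q, side="left").clip(0, x.size - 1)]
        hi = x[np.searchsorted(cw, hi_q, side="left").clip(0, x.size - 1)]
        return float(lo), float(hi)

    def index_of(self, name: str) -> int:
        return self.names.index(name)
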