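"""Histogram (plug-in) entropy estimation and prior-to-posterior information
gain.

This is the independent check on the mutual-information rankings: fit a
posterior to data from each candidate experiment, then compare the entropy of
the prior with the entropy of each posterior under an *identical*
discretization.  Discretizing parameter space changes the scale of the
entropy and the plug-in estimator is biased, but the bias depends only on the
bin count and sample size — so *differences* between runs that share those
settings remain comparable, while absolute magnitudes are never compared
against mutual-information values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .priors import ParticlePopulation

__all__ = ["EntropySummary", "histogram_entropy", "information_gain"]


@dataclass(frozen=True)
class EntropySummary:
    entropy_prior: float
    entropy_posterior: float
    bins_per_dim: int
    n_samples_prior: int
    n_samples_posterior: int
    dimensions: str = "joint"

    @property
    def gain(self) -> float:
        """Information gain in nats: prior entropy minus posterior entropy."""
        return self.entropy_prior - self.entropy_posterior

    def to_dict(self) -> dict:
        return {
            "entropy_prior_nats": self.entropy_prior,
            "entropy_posterior_nats": self.entropy_posterior,
            "gain_nats": self.gain,
            "bins_per_dim": self.bins_per_dim,
            "n_samples_prior": self.n_samples_prior,
            "n_samples_posterior": self.n_samples_posterior,
            "dimensions": self.dimensions,
        }


def histogram_entropy(samples, bins_per_dim: int, bounds, dims=None) -> float:
    """Discrete Shannon entropy (nats) of the normalized histogram of
    *samples* on the regular grid defined by *bounds*.

    ``bounds`` is a per-dimension sequence of (lower, upper); ``dims``
    optionally restricts to a subset of columns (marginal entropy).
    Out-of-bounds rows are dropped.  No bin-width correction is applied: only
    differences at fixed discretization are meaningful.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("histogram_entropy requires a non-empty sample")
    if bins_per_dim < 2:
        raise ValueError("bins_per_dim must be >= 2")
    bounds = np.asarray(bounds, dtype=float).reshape(-1, 2)
    if dims is not None:
        dims = list(np.atleast_1d(dims))
        x = x[:, dims]
        bounds = bounds[dims]
    if x.shape[1] != bounds.shape[0]:
        raise ValueError("one (lower, upper) pair per retained dimension required")

    inside = np.all((x >= bounds[:, 0]) & (x <= bounds[:, 1]), axis=1)
    x = x[inside]
    if x.shape[0] == 0:
        raise ValueError("all samples fall outside the histogram bounds")
    counts, _ = np.histogramdd(x, bins=bins_per_dim, range=[tuple(b) for b in bounds])
    q = counts.ravel() / counts.sum()
    q = q[q > 0]
    return float(-np.sum(q * np.log(q)))


def information_gain(prior_samples, posterior, bins_per_dim, bounds,
                     dims=None, rng: Optional[np.random.Generator] = None,
                     label: str = "joint") -> EntropySummary:
    """Prior-minus-posterior entropy under one shared discretization.

    ``posterior`` may be a sample matrix or a weighted
    :class:`ParticlePopulation`; populations are resampled (equal weights) to
    the prior sample size, because the validity of the comparison rests on
    both sides sharing bins, bounds and sample size.
    """
    prior_samples = np.atleast_2d(np.asarray(prior_samples, dtype=float))
    n = prior_samples.shape[0]
    if isinstance(posterior, ParticlePopulation):
        rng = rng if rng is not None else np.random.default_rng(0)
        post = posterior.sample(n, rng)
    else:
        post = np.atleast_2d(np.asarray(posterior, dtype=float))
        if post.shape[0] != n:
            raise ValueError(
                "prior and posterior sample sizes must match for a valid "
                "entropy comparison (resample the posterior first)")
    h_prior = histogram_entropy(prior_samples, bins_per_dim, bounds, dims=dims)
    h_post = histogram_entropy(post, bins_per_dim, bounds, dims=dims)
    return EntropySummary(h_prior, h_post, bins_per_dim, n, post.shape[0],
                          dimensions=label)
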