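"""Nested Monte-Carlo estimators of mutual information.

Three estimators are provided, all in nats, all built on the same Gaussian
observation model ``y = f(theta, e) + eps``:

``estimate_mi_joint``
    I(Theta; Y_e), the expected information an experiment carries about the
    full parameter vector.  Outer sample: draw theta_i from the prior,
    simulate f(theta_i) and draw y_i.  The evidence p(y_i | e) is estimated by
    averaging the likelihood over an independent M-sample from the prior, and

        I_hat = (1/N) sum_i [ log p(y_i | theta_i) - log (1/M) sum_j p(y_i | theta'_j) ].

``estimate_mi_component``
    I(Theta_i; Y_e) for a single parameter component.  The numerator
    p(y | theta_i) needs an extra inner integration over the remaining
    components, estimated from K conditional draws that pin component i at
    the outer draw's value (requires an independent-component prior).

``estimate_mi_predictive``
    I(Y_e; Y_e*), the information the outcome of experiment e carries about
    the outcome of a target experiment e*.  Because the two outputs are
    independent given theta, all three densities in

        I_hat = (1/N) sum_n [ log p_hat(y_n, y*_n) - log p_hat(y_n) - log p_hat(y*_n) ]

    are evidence-style averages over one shared M-sample.

Nested estimators are biased at finite inner sample size; the bias shrinks
as M (and K) grow.  Uncertainty is reported as the standard error over R
independent repetitions of the whole estimator, each on its own substream.

All evidence averages run through :func:`log_mean_exp`.  Integration failures
are rejected and redrawn, with the count reported on the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .models import ExperimentSpec, OdeModel
from .simulate import LOG_ZERO, IntegrationError, SolverSettings, integrate

__all__ = [
    "MIEstimate",
    "EstimationError",
    "log_mean_exp",
    "ExperimentSimulator",
    "FunctionSimulator",
    "estimate_mi_joint",
    "estimate_mi_component",
    "estimate_mi_predictive",
]


class EstimationError(RuntimeError):
    """Estimation could not be completed (e.g. all samples failed to integrate)."""


@dataclass(frozen=True)
class MIEstimate:
    """A Monte-Carlo mutual-information estimate in nats.

    ``std_error`` is the sample SD over the R independent repetitions divided
    by sqrt(R) (0.0 when R == 1).  ``n_failed_integrations`` counts rejected
    parameter draws across all repetitions.
    """

    value: float
    std_error: float
    N: int
    M: int
    R: int
    seed: int
    K: Optional[int] = None
    n_failed_integrations: int = 0

    def __post_init__(self):
        if self.std_error < 0 or self.N < 1 or self.M < 1 or self.R < 1:
            raise ValueError("invalid MIEstimate fields")

    def to_dict(self) -> dict:
        return {
            "value_nats": self.value, "std_error": self.std_error,
            "N": self.N, "M": self.M, "K": self.K, "R": self.R,
            "seed": self.seed, "n_failed": self.n_failed_integrations,
        }


def log_mean_exp(values, axis=None):
    """log((1/M) * sum(exp(v))) with max-subtraction for stability.

    Entries at or below the ``LOG_ZERO`` sentinel are treated as exp() = 0;
    an all-sentinel input returns the sentinel.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("log_mean_exp requires a non-empty input")
    vmax = np.max(v, axis=axis, keepdims=True)
    safe_max = np.where(vmax <= LOG_ZERO, 0.0, vmax)
    with np.errstate(divide="ignore"):
        out = np.log(np.mean(np.exp(v - safe_max), axis=axis, keepdims=True)) + safe_max
    out = np.where(vmax <= LOG_ZERO, LOG_ZERO, out)
    if axis is None:
        return float(out.reshape(()))
    return np.squeeze(out, axis=axis)


# ---------------------------------------------------------------------------
# Simulator adapters
# ---------------------------------------------------------------------------

class ExperimentSimulator:
    """Adapter turning (model, experiment) into theta -> flat output vector.

    Output cells are the row-major flattening of the (n_times, n_observed)
    trajectory; ``sigma2_cells`` is the matching per-cell noise variance.
    """

    def __init__(self, model: OdeModel, experiment: ExperimentSpec,
                 settings: SolverSettings = SolverSettings()):
        self.model = model
        self.experiment = experiment
        self.settings = settings
        s2_obs = experiment.sigma2_vector()
        self.sigma2_cells = np.tile(s2_obs, experiment.time_grid.size)
        self.dim_out = experiment.time_grid.size * experiment.n_observed

    def __call__(self, theta) -> np.ndarray:
        traj = integrate(self.model, theta, self.experiment, self.settings)
        return traj.values.ravel()


class FunctionSimulator:
    """Wrap a plain function theta -> output vector (for analytic benchmarks)."""

    def __init__(self, fn, sigma2_cells, dim_out=None, batch_fn=None):
        self.fn = fn
        self.sigma2_cells = np.atleast_1d(np.asarray(sigma2_cells, dtype=float))
        self.dim_out = dim_out if dim_out is not None else self.sigma2_cells.size
        self.batch_fn = batch_fn

    def __call__(self, theta):
        return np.atleast_1d(np.asarray(self.fn(np.asarray(theta, float)), dtype=float))

    def simulate_batch(self, thetas):
        if self.batch_fn is not None:
            return np.asarray(self.batch_fn(thetas), dtype=float)
        return np.stack([self(t) for t in thetas])


def _sample_and_simulate(sim, prior, n, rng):
    """Draw n prior samples and simulate each, rejecting integration failures.

    Returns (thetas, F, n_failed).  Gives up once failures exceed 10x n.
    """
    thetas = prior.sample(n, rng)
    if hasattr(sim, "simulate_batch") and not isinstance(sim, ExperimentSimulator):
        return thetas, sim.simulate_batch(thetas), 0
    F = np.empty((n, sim.dim_out))
    n_failed = 0
    for i in range(n):
        while True:
            try:
                F[i] = sim(thetas[i])
                break
            except IntegrationError:
                n_failed += 1
                if n_failed > 10 * n:
                    raise EstimationError(
                        "more than 10x the sample size failed to integrate; "
                        "check the prior support and solver settings")
                thetas[i] = prior.sample(1, rng)[0]
    return thetas, F, n_failed


def _pairwise_loglik(Y, F, sigma2_cells):
    """(N, M) matrix of log N(Y_i; F_j, diag(sigma2))."""
    scale = 1.0 / np.sqrt(sigma2_cells)
    const = -0.5 * np.sum(np.log(2.0 * np.pi * sigma2_cells))
    D = cdist(Y * scale, F * scale, metric="sqeuclidean")
    return -0.5 * D + const


def _self_loglik(Y, F, sigma2_cells):
    const = -0.5 * np.sum(np.log(2.0 * np.pi * sigma2_cells))
    return -0.5 * np.sum((Y - F) ** 2 / sigma2_cells, axis=1) + const


def _rep_rngs(seed, R):
    return [np.random.default_rng(np.random.SeedSequence([int(seed), r])) for r in range(R)]


def _finish(values, N, M, R, seed, K=None, n_failed=0):
    values = np.asarray(values, dtype=float)
    se = float(values.std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0
    return MIEstimate(float(values.mean()), se, N, M, R, int(seed), K=K,
                      n_failed_integrations=n_failed)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def estimate_mi_joint(model, experiment, prior, N=1000, M=1000, R=5, seed=0,
                      reuse_outer=False, settings=SolverSettings(),
                      simulator=None) -> MIEstimate:
    """Estimate I(Theta; Y_e) for one experiment.

    ``reuse_outer=True`` reuses the outer N-sample for the evidence average
    (the cheaper variant); the default draws an independent M-sample, which
    avoids the systematic downward bias of the reused estimator.
    ``simulator`` overrides the (model, experiment) adapter — used by
    analytic benchmark problems.
    """
    if N < 2 or M < 2:
        raise ValueError("N and M must both be >= 2")
    sim = simulator if simulator is not None else ExperimentSimulator(model, experiment, settings)
    if np.any(sim.sigma2_cells <= 0):
        raise ValueError("mutual-information estimation requires noise variance > 0")
    s2 = sim.sigma2_cells
    vals, failures = [], 0
    for rng in _rep_rngs(seed, R):
        _, F, nf1 = _sample_and_simulate(sim, prior, N, rng)
        y = F + rng.normal(size=F.shape) * np.sqrt(s2)
        ll_self = _self_loglik(y, F, s2)
        if reuse_outer:
            F_ev, nf2 = F, 0
        else:
            _, F_ev, nf2 = _sample_and_simulate(sim, prior, M, rng)
        ev = log_mean_exp(_pairwise_loglik(y, F_ev, s2), axis=1)
        vals.append(np.mean(ll_self - ev))
        failures += nf1 + nf2
    return _finish(vals, N, M if not reuse_outer else N, R, seed, n_failed=failures)


def estimate_mi_component(i, model, experiment, prior, N=1000, K=100, M=1000,
                          R=5, seed=0, settings=SolverSettings(),
                          simulator=None) -> MIEstimate:
    """Estimate I(Theta_i; Y_e) for parameter component *i* (index or name).

    The numerator p(y_n | theta_{n,i}) is an inner average over K draws with
    component i pinned at theta_{n,i} and the other components redrawn from
    the prior — only defined for priors with independent components.
    """
    if isinstance(i, str):
        i = prior.index_of(i)
    if not getattr(prior, "independent_components", False):
        # delegate the error to the prior so the message names the type
        prior.resample_others(i, np.zeros(getattr(prior, "dim", 1)), 1,
                              np.random.default_rng(0))
    if N < 2 or M < 2 or K < 1:
        raise ValueError("N, M >= 2 and K >= 1 required")
    sim = simulator if simulator is not None else ExperimentSimulator(model, experiment, settings)
    if np.any(sim.sigma2_cells <= 0):
        raise ValueError("mutual-information estimation requires noise variance > 0")
    s2 = sim.sigma2_cells
    vals, failures = [], 0
    for rng in _rep_rngs(seed, R):
        thetas, F, nf1 = _sample_and_simulate(sim, prior, N, rng)
        y = F + rng.normal(size=F.shape) * np.sqrt(s2)
        _, F_ev, nf2 = _sample_and_simulate(sim, prior, M, rng)
        ev = log_mean_exp(_pairwise_loglik(y, F_ev, s2), axis=1)
        failures += nf1 + nf2
        num = np.empty(N)
        for n in range(N):
            cond = _ConditionalPrior(prior, i, thetas[n])
            _, F_in, nf3 = _sample_and_simulate(sim, cond, K, rng)
            failures += nf3
            num[n] = log_mean_exp(_self_loglik(
                np.broadcast_to(y[n], F_in.shape), F_in, s2))
        vals.append(np.mean(num - ev))
    return _finish(vals, N, M, R, seed, K=K, n_failed=failures)


class _ConditionalPrior:
    """Prior restricted to theta_i = value; draws delegate to resample_others."""

    def __init__(self, prior, i, theta):
        self.prior, self.i, self.theta = prior, i, theta

    def sample(self, n, rng):
        return self.prior.resample_others(self.i, self.theta, n, rng)


def estimate_mi_predictive(experiment_e, experiment_target, model=None, prior=None,
                           N=1000, M=1000, R=5, seed=0, settings=SolverSettings(),
                           simulator_e=None, simulator_target=None,
                           model_target=None) -> MIEstimate:
    """Estimate I(Y_e; Y_e*): how informative experiment e's outcome is about
    the outcome of the target experiment e*.

    Both experiments must share the same parameter vector (their model
    variants may differ).  Uses the conditional independence of the two
    outputs given theta: joint, and both marginal, densities are evidence
    averages over one shared M-sample.
    """
    if N < 2 or M < 2:
        raise ValueError("N and M must both be >= 2")
    sim_e = simulator_e if simulator_e is not None else ExperimentSimulator(
        model, experiment_e, settings)
    sim_t = simulator_target if simulator_target is not None else ExperimentSimulator(
        model_target if model_target is not None else model, experiment_target, settings)
    for s in (sim_e, sim_t):
        if np.any(s.sigma2_cells <= 0):
            raise ValueError("mutual-information estimation requires noise variance > 0")
    s2e, s2t = sim_e.sigma2_cells, sim_t.sigma2_cells
    vals, failures = [], 0
    for rng in _rep_rngs(seed, R):
        thetas, Fe, nf1 = _sample_and_simulate(sim_e, prior, N, rng)
        Ft = np.stack([_simulate_retry(sim_t, t) for t in thetas])
        ye = Fe + rng.normal(size=Fe.shape) * np.sqrt(s2e)
        yt = Ft + rng.normal(size=Ft.shape) * np.sqrt(s2t)
        thetas_ev, Fe_ev, nf2 = _sample_and_simulate(sim_e, prior, M, rng)
        # the same shared evidence thetas drive the target simulations
        Ft_ev = np.stack([_simulate_retry(sim_t, t) for t in thetas_ev])
        A = _pairwise_loglik(ye, Fe_ev, s2e)
        B = _pairwise_loglik(yt, Ft_ev, s2t)
        vals.append(np.mean(log_mean_exp(A + B, axis=1)
                            - log_mean_exp(A, axis=1)
                            - log_mean_exp(B, axis=1)))
        failures += nf1 + nf2
    return _finish(vals, N, M, R, seed, n_failed=failures)


def _simulate_retry(sim, theta):
    """Simulate one theta for a second experiment; a failure here cannot be
    redrawn (the draw is shared), so it maps to the log-zero sentinel path by
    raising EstimationError only if truly unintegrable."""
    try:
        return sim(theta)
    except IntegrationError as exc:
        raise EstimationError(
            f"target experiment failed to integrate at a shared draw: {exc}") from exc
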