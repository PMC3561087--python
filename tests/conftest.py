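"""Shared fixtures: analytic benchmark problems and small synthetic datasets.

Linear-Gaussian problems have closed-form mutual information, so they serve
as exact oracles for the Monte-Carlo estimators.  The heavier case-study
fixtures (repressilator ABC fits) are session-scoped so several tests can
share one computation.
"""

import numpy as np
import pytest

import infodesign as idn
from infodesign.mi import FunctionSimulator
from infodesign.priors import IndependentGaussianPrior


def linear_gaussian_problem(tau2, sigma2, dim=1):
    """y = theta + eps benchmark: prior N(0, tau2 I), noise N(0, sigma2 I).

    Exact mutual information: dim/2 * ln(1 + tau2/sigma2).
    """
    prior = IndependentGaussianPrior(
        tuple(f"th{i}" for i in range(dim)),
        np.zeros(dim), np.full(dim, np.sqrt(tau2)))
    sim = FunctionSimulator(lambda th: th, np.full(dim, sigma2),
                            batch_fn=lambda T: np.asarray(T, float))
    exact = 0.5 * dim * np.log(1.0 + tau2 / sigma2)
    return prior, sim, exact


def sum_gaussian_problem(tau1, tau2, sigma2):
    """y = theta1 + theta2 + eps: closed-form single-component MI.

    I(theta1; Y) = 1/2 ln((tau1+tau2+sigma2)/(tau2+sigma2)).
    """
    prior = IndependentGaussianPrior(("a", "b"), [0.0, 0.0],
                                     [np.sqrt(tau1), np.sqrt(tau2)])
    sim = FunctionSimulator(lambda th: np.array([th[0] + th[1]]), [sigma2],
                            batch_fn=lambda T: T.sum(axis=1, keepdims=True))
    exact = 0.5 * np.log((tau1 + tau2 + sigma2) / (tau2 + sigma2))
    return prior, sim, exact


def replicate_problem(tau2, s1, s2):
    """Two replicate scalar experiments measuring the same theta.

    I(Y1; Y2) from the bivariate Gaussian covariance determinant.
    """
    prior = IndependentGaussianPrior(("th",), [0.0], [np.sqrt(tau2)])
    sim1 = FunctionSimulator(lambda th: th, [s1], batch_fn=lambda T: np.asarray(T, float))
    sim2 = FunctionSimulator(lambda th: th, [s2], batch_fn=lambda T: np.asarray(T, float))
    den = (tau2 + s1) * (tau2 + s2)
    exact = 0.5 * np.log(den / (den - tau2 ** 2))
    return prior, sim1, sim2, exact


@pytest.fixture(scope="session")
def repressilator_menu():
    return idn.build_repressilator_menu()


@pytest.fixture(scope="session")
def repressilator_prior():
    return idn.repressilator_prior()


@pytest.fixture(scope="session")
def repressilator_fixture_data(repressilator_menu):
    """Synthetic noisy datasets for all five variants at theta*."""
    out = {}
    for exp in repressilator_menu:
        _, ds = idn.generate_fixture(exp.model, exp, idn.REPRESSILATOR_THETA_STAR,
                                     seed=1234)
        out[exp.id] = ds
    return out
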