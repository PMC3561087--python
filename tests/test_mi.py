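"""Mutual-information estimators: closed-form oracles, invariants, plumbing.

The linear-Gaussian problems in conftest provide exact mutual-information
values; the estimators must converge to them.  The heavier full-grid oracle
suite lives in test_acceptance.py; here we cover the machinery at moderate
sample sizes plus the structural properties (nulls, symmetry, monotonicity,
log-mean-exp numerics).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infodesign.mi import (FunctionSimulator, MIEstimate, estimate_mi_component,
                           estimate_mi_joint, estimate_mi_predictive, log_mean_exp)
from infodesign.priors import (IndependentGaussianPrior, ParticlePopulation,
                               UniformPrior, UnsupportedPriorOperation)
from infodesign.simulate import LOG_ZERO

from conftest import linear_gaussian_problem, replicate_problem, sum_gaussian_problem


# ---------------------------------------------------------------------------
# log_mean_exp
# ---------------------------------------------------------------------------

def test_log_mean_exp_examples():
    assert log_mean_exp([-1000.0, -1000.0]) == pytest.approx(-1000.0)
    assert log_mean_exp([0.0, np.log(3.0)]) == pytest.approx(np.log(2.0))
    with pytest.raises(ValueError):
        log_mean_exp([])


def test_log_mean_exp_matches_high_precision():
    """Against extended-precision direct computation on wide-range inputs."""
    from decimal import Decimal, getcontext
    getcontext().prec = 60
    rng = np.random.default_rng(3)
    v = rng.uniform(-700.0, 0.0, size=1000)
    expected = float((sum(Decimal(float(x)).exp() for x in v) / 1000).ln())
    assert log_mean_exp(v) == pytest.approx(expected, abs=1e-10)


def test_log_mean_exp_sentinel_handling():
    assert log_mean_exp([LOG_ZERO, LOG_ZERO]) == LOG_ZERO
    # one real entry among sentinels: mean is value - ln(n)
    assert log_mean_exp([0.0, LOG_ZERO]) == pytest.approx(-np.log(2.0))
    row = log_mean_exp(np.array([[0.0, LOG_ZERO], [LOG_ZERO, LOG_ZERO]]), axis=1)
    assert row[0] == pytest.approx(-np.log(2.0))
    assert row[1] == LOG_ZERO


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(min_value=-500, max_value=500), min_size=1, max_size=40))
def test_log_mean_exp_bounds(vals):
    """lme lies between min and max of its inputs."""
    out = log_mean_exp(vals)
    assert min(vals) - 1e-9 <= out <= max(vals) + 1e-9


# ---------------------------------------------------------------------------
# Estimator correctness at moderate size
# ---------------------------------------------------------------------------

def test_joint_matches_linear_gaussian():
    prior, sim, exact = linear_gaussian_problem(1.0, 1.0)
    est = estimate_mi_joint(None, None, prior, N=1500, M=1500, R=6, seed=10,
                            simulator=sim)
    assert est.value == pytest.approx(exact, abs=3 * est.std_error)


def test_component_equals_joint_when_output_depends_on_one_parameter():
    """If the output ignores theta_2, I(theta_1; Y) = I(Theta; Y)."""
    prior = IndependentGaussianPrior(("a", "b"), [0.0, 0.0], [1.0, 1.0])
    sim = FunctionSimulator(lambda th: np.array([th[0]]), [1.0],
                            batch_fn=lambda T: T[:, :1])
    ej = estimate_mi_joint(None, None, prior, N=1200, M=1200, R=5, seed=3,
                           simulator=sim)
    ec = estimate_mi_component(0, None, None, prior, N=600, K=600, M=600, R=5,
                               seed=4, simulator=sim)
    combined = ej.std_error + ec.std_error
    assert abs(ej.value - ec.value) <= 3 * combined


def test_component_null_when_output_independent():
    prior = IndependentGaussianPrior(("a", "b"), [0.0, 0.0], [1.0, 1.0])
    sim = FunctionSimulator(lambda th: np.array([th[1]]), [1.0],
                            batch_fn=lambda T: T[:, 1:])
    est = estimate_mi_component(0, None, None, prior, N=500, K=300, M=300,
                                R=5, seed=6, simulator=sim)
    assert abs(est.value) <= max(3 * est.std_error, 0.01)


def test_component_closed_form_sum_model():
    prior, sim, exact = sum_gaussian_problem(1.0, 0.5, 1.0)
    est = estimate_mi_component(0, None, None, prior, N=1000, K=400, M=400,
                                R=6, seed=8, simulator=sim)
    assert est.value == pytest.approx(exact, abs=3 * est.std_error)


def test_predictive_closed_form_and_symmetry():
    prior, sim1, sim2, exact = replicate_problem(1.0, 1.0, 0.5)
    e12 = estimate_mi_predictive(None, None, prior=prior, N=1500, M=1500, R=6,
                                 seed=12, simulator_e=sim1, simulator_target=sim2)
    e21 = estimate_mi_predictive(None, None, prior=prior, N=1500, M=1500, R=6,
                                 seed=13, simulator_e=sim2, simulator_target=sim1)
    assert e12.value == pytest.approx(exact, abs=3 * e12.std_error)
    # mutual information is symmetric in its two arguments
    assert abs(e12.value - e21.value) <= 3 * (e12.std_error + e21.std_error)


def test_constant_output_gives_zero_mi():
    prior = IndependentGaussianPrior(("a",), [0.0], [1.0])
    sim = FunctionSimulator(lambda th: np.array([2.5]), [1.0],
                            batch_fn=lambda T: np.full((len(T), 1), 2.5))
    ej = estimate_mi_joint(None, None, prior, N=800, M=800, R=5, seed=2,
                           simulator=sim)
    assert abs(ej.value) <= max(3 * ej.std_error, 1e-3)


def test_two_atom_prior_recovers_ln2():
    """Two well-separated atoms with tiny noise: exactly one bit = ln 2 nats."""
    atoms = np.array([[0.0], [10.0]])
    prior = ParticlePopulation(atoms, np.array([0.5, 0.5]))
    sim = FunctionSimulator(lambda th: th, [1e-4],
                            batch_fn=lambda T: np.asarray(T, float))
    est = estimate_mi_joint(None, None, prior, N=1500, M=1500, R=5, seed=5,
                            simulator=sim)
    assert est.value == pytest.approx(np.log(2.0), abs=max(3 * est.std_error, 0.02))


def test_mi_decreases_with_noise_common_random_numbers():
    """Under matched seeds, the joint estimate strictly decreases along a
    five-point noise-variance grid."""
    vals = []
    for sigma2 in (0.25, 0.5, 1.0, 2.0, 4.0):
        prior, sim, _ = linear_gaussian_problem(1.0, sigma2)
        est = estimate_mi_joint(None, None, prior, N=1500, M=1500, R=4,
                                seed=77, simulator=sim)
        vals.append(est.value)
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_reuse_outer_variant_runs_and_biases_low():
    """The evidence sample reusing the outer draws is the cheap variant; its
    estimate must not exceed the independent-evidence one by a large margin."""
    prior, sim, exact = linear_gaussian_problem(1.0, 1.0)
    e_ind = estimate_mi_joint(None, None, prior, N=1200, M=1200, R=4, seed=1,
                              simulator=sim)
    e_reuse = estimate_mi_joint(None, None, prior, N=1200, M=1200, R=4, seed=1,
                                simulator=sim, reuse_outer=True)
    assert e_reuse.M == e_reuse.N
    assert e_reuse.value <= e_ind.value + 3 * (e_ind.std_error + e_reuse.std_error)


def test_estimator_determinism():
    prior, sim, _ = linear_gaussian_problem(1.0, 1.0)
    a = estimate_mi_joint(None, None, prior, N=300, M=300, R=3, seed=9, simulator=sim)
    b = estimate_mi_joint(None, None, prior, N=300, M=300, R=3, seed=9, simulator=sim)
    assert a.value == b.value and a.std_error == b.std_error


def test_component_rejects_particle_prior():
    pop = ParticlePopulation(np.zeros((5, 2)), np.full(5, 0.2))
    sim = FunctionSimulator(lambda th: th[:1], [1.0])
    with pytest.raises(UnsupportedPriorOperation):
        estimate_mi_component(0, None, None, pop, N=10, K=5, M=10, seed=0,
                              simulator=sim)


def test_mi_estimate_validation():
    with pytest.raises(ValueError):
        MIEstimate(0.1, -1.0, 10, 10, 2, 0)
    with pytest.raises(ValueError):
        MIEstimate(0.1, 0.0, 0, 10, 2, 0)


def test_sample_size_preconditions():
    prior, sim, _ = linear_gaussian_problem(1.0, 1.0)
    with pytest.raises(ValueError):
        estimate_mi_joint(None, None, prior, N=1, M=10, simulator=sim)
    with pytest.raises(ValueError, match="noise variance"):
        bad = FunctionSimulator(lambda th: th, [0.0], batch_fn=lambda T: T)
        estimate_mi_joint(None, None, prior, N=10, M=10, simulator=bad)
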