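"""ABC SMC: distance metric, prior recovery, conjugate-oracle accuracy."""

import numpy as np
import pytest
from scipy import stats

import infodesign as idn
from infodesign.abc_smc import AbcSettings, distance, fit
from infodesign.mi import FunctionSimulator
from infodesign.priors import UniformPrior


def test_distance_identity_and_nonnegativity():
    rng = np.random.default_rng(0)
    y = rng.normal(size=(8, 2))
    assert distance(y, y) == 0.0
    assert distance(y, y + rng.normal(size=y.shape)) > 0.0


def test_distance_triangle_inequality():
    rng = np.random.default_rng(1)
    scale = np.array([1.0, 2.0])
    for _ in range(25):
        a, b, c = rng.normal(size=(3, 6, 2))
        dab = distance(a, b, column_scale=scale)
        dbc = distance(b, c, column_scale=scale)
        dac = distance(a, c, column_scale=scale)
        assert dac <= dab + dbc + 1e-12


def test_distance_column_scale_invariance():
    """Scaling one observable column of both inputs leaves the default
    (SD-standardized) distance unchanged."""
    rng = np.random.default_rng(2)
    y = rng.normal(size=(10, 2))
    f = rng.normal(size=(10, 2))
    d0 = distance(y, f)
    y2, f2 = y.copy(), f.copy()
    y2[:, 1] *= 10.0
    f2[:, 1] *= 10.0
    assert distance(y2, f2) == pytest.approx(d0)


def test_distance_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        distance(np.zeros((3, 2)), np.zeros((4, 2)))


class _ToyExperiment:
    """A 1-D linear model wrapped as model/experiment for the ABC driver."""

    def __init__(self, n_obs=5, sigma=0.2):
        self.n_obs = n_obs
        self.sigma = sigma
        grid = np.linspace(1.0, 2.0, n_obs)
        self.model = idn.OdeModel(
            name="toy-linear", state_names=("x",), parameter_names=("theta",),
            rhs=lambda x, t, th, u=0.0: np.array([th[0]]),  # dx/dt = theta
            initial_state=np.zeros(1), observables={"x": np.array([1.0])},
        )
        self.experiment = idn.ExperimentSpec(
            id="toy", model=self.model, observed=("x",), time_grid=grid,
            noise_variance={"x": sigma ** 2})


def test_fixed_infinite_tolerance_recovers_prior():
    """One generation at eps = +inf keeps everything: the population is a
    prior sample (two-sample KS agreement with fresh prior draws)."""
    toy = _ToyExperiment()
    prior = UniformPrior(("theta",), np.array([-2.0]), np.array([2.0]))
    theta_star = np.array([0.7])
    tr = idn.integrate(toy.model, theta_star, toy.experiment)
    ds = idn.observe(tr, toy.sigma ** 2, seed=5)
    pop = fit(toy.model, toy.experiment, ds, prior,
              settings=AbcSettings(n_particles=1000, max_generations=0), seed=0)
    assert pop.generation == 0
    assert pop.acceptance_rates[0] == 1.0
    assert pop.weights.sum() == pytest.approx(1.0, abs=1e-12)
    fresh = prior.sample(1000, np.random.default_rng(123))[:, 0]
    assert stats.ks_2samp(pop.particles[:, 0], fresh).pvalue > 0.01


def test_conjugate_posterior_mean_recovered():
    """Linear observation of theta with uniform prior wide enough to act
    locally flat: ABC posterior mean approaches the least-squares estimate
    (the posterior mean of the flat-prior conjugate analysis)."""
    toy = _ToyExperiment(n_obs=5, sigma=0.3)
    prior = UniformPrior(("theta",), np.array([-5.0]), np.array([5.0]))
    theta_star = np.array([1.2])
    tr = idn.integrate(toy.model, theta_star, toy.experiment)
    ds = idn.observe(tr, toy.sigma ** 2, seed=7)
    # flat-prior posterior: theta | y ~ N(theta_hat, sigma^2 / sum(t_i^2))
    t = toy.experiment.time_grid
    theta_hat = float((ds.values[:, 0] @ t) / (t @ t))
    post_sd = toy.sigma / np.sqrt(t @ t)
    pop = fit(toy.model, toy.experiment, ds, prior,
              settings=AbcSettings(n_particles=300, max_generations=10,
                                   quantile=0.3), seed=1)
    assert abs(pop.mean()[0] - theta_hat) < max(0.1 * post_sd, 0.05)


def test_epsilon_strictly_decreasing_and_distances_shrink():
    toy = _ToyExperiment()
    prior = UniformPrior(("theta",), np.array([-2.0]), np.array([2.0]))
    tr = idn.integrate(toy.model, np.array([0.5]), toy.experiment)
    ds = idn.observe(tr, toy.sigma ** 2, seed=9)
    pop = fit(toy.model, toy.experiment, ds, prior,
              settings=AbcSettings(n_particles=150, max_generations=6), seed=2)
    eps = np.array(pop.epsilon_schedule)
    assert np.all(np.diff(eps) < 0)
    # posterior contraction: final variance below the prior's
    assert pop.var()[0] < prior.variances()[0]


def test_reproducibility_per_seed():
    toy = _ToyExperiment()
    prior = UniformPrior(("theta",), np.array([-2.0]), np.array([2.0]))
    tr = idn.integrate(toy.model, np.array([0.5]), toy.experiment)
    ds = idn.observe(tr, toy.sigma ** 2, seed=9)
    s = AbcSettings(n_particles=120, max_generations=3)
    p1 = fit(toy.model, toy.experiment, ds, prior, settings=s, seed=4)
    p2 = fit(toy.model, toy.experiment, ds, prior, settings=s, seed=4)
    np.testing.assert_array_equal(p1.particles, p2.particles)
    np.testing.assert_array_equal(p1.weights, p2.weights)


def test_particle_count_precondition():
    toy = _ToyExperiment()
    prior = UniformPrior(("theta",), np.array([-2.0]), np.array([2.0]))
    tr = idn.integrate(toy.model, np.array([0.5]), toy.experiment)
    ds = idn.observe(tr, toy.sigma ** 2, seed=9)
    with pytest.raises(ValueError, match="n_particles"):
        fit(toy.model, toy.experiment, ds, prior,
            settings=AbcSettings(n_particles=50))
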