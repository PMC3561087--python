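"""Choose the most informative repressilator perturbation experiment.

Ranks the wild type (E1) and four parameter-decreasing interventions
(E2..E5) by the estimated mutual information between the noisy trajectories
and the four model parameters, then validates the winner by fitting the
posterior to synthetic data and computing the prior-to-posterior entropy
gain.  Sample sizes are kept small so the script runs in about two minutes.
"""

import numpy as np

import infodesign as idn
from infodesign.abc_smc import AbcSettings, fit
from infodesign.design import DesignTarget, EstimatorSettings, rank_experiments
from infodesign.entropy import information_gain

menu = idn.build_repressilator_menu()
prior = idn.repressilator_prior()

report = rank_experiments(menu, DesignTarget.inference(), prior,
                          settings=EstimatorSettings(N=300, M=300, R=3), seed=0)
print("Mutual information I(Theta; Y_e) per candidate (nats):")
for eid, est in report.entries:
    print(f"  {eid}: {est.value:10.1f} +/- {est.std_error:.1f}")
top = max(report.entries, key=lambda kv: kv[1].value)[0]
print(f"highest estimate: {top}  (wild type is E1)\n")

# validate with an ABC fit to synthetic data from the top candidate
exp = next(e for e in menu if e.id == top)
_, ds = idn.generate_fixture(exp.model, exp, idn.REPRESSILATOR_THETA_STAR, seed=1234)
post = fit(exp.model, exp, ds, prior,
           settings=AbcSettings(n_particles=100, max_generations=4, quantile=0.3),
           seed=0)
rng = np.random.default_rng(0)
bounds = np.stack([prior.lower, prior.upper], axis=1)
gain = information_gain(prior.sample(5000, rng), post, 10, bounds, rng=rng)
print(f"entropy gain of the {top} fit: {gain.gain:.2f} nats "
      f"(prior {gain.entropy_prior:.2f} -> posterior {gain.entropy_posterior:.2f})")
print("\nThe MI column says how much, on average, each intervention would"
      "\nteach us about (alpha0, alpha, beta, n); the entropy gain is the"
      "\nrealized uncertainty reduction for one simulated dataset.")
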