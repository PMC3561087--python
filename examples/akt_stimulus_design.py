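"""Stimulus design for predicting an unrealizable EGF input pattern.

Workflow: fit the EGF->AKT->S6 cascade to synthetic baseline data (a 60 s
EGF impulse), then rank 12 realizable stimuli (impulses, steps, ramps at
several intensities) by the mutual information between their outcomes and
the outcome of the target condition — a noisy 5-pulse EGF train that would
be very hard to deliver experimentally.  The posterior from the baseline
fit serves as the prior for the predictive ranking (posterior-as-prior).

Runs in roughly five minutes at these reduced sample sizes.
"""

import numpy as np

import infodesign as idn
from infodesign.abc_smc import AbcSettings, fit
from infodesign.design import DesignTarget, EstimatorSettings, rank_experiments

model, candidates, target = idn.build_akt()
prior = idn.akt_prior()

baseline = next(c for c in candidates if c.id == "impulse_10")
_, data = idn.generate_fixture(model, baseline, idn.AKT_THETA_STAR, seed=777)
posterior = fit(model, baseline, data, prior,
                settings=AbcSettings(n_particles=100, max_generations=5,
                                     quantile=0.3), seed=21)
print(f"baseline ABC fit: {posterior.generation} generations, "
      f"final tolerance {posterior.epsilon_schedule[-1]:.3g}")

report = rank_experiments(
    candidates, DesignTarget.prediction(target),
    posterior.resampled(2000, np.random.default_rng(3)),
    settings=EstimatorSettings(N=100, M=100, R=2), seed=31)

print("\npredictive MI against the 5-pulse target (nats):")
for eid, est in report.entries:
    print(f"  {eid:12s} {est.value:8.2f} +/- {est.std_error:.2f}")
best = max(report.entries, key=lambda kv: kv[1].value)[0]
print(f"\nmost informative realizable stimulus: {best}")
print("A sustained input explores receptor turnover and the slow S6 layer,"
      "\nwhich is why step-like stimuli dominate short impulses here.")
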