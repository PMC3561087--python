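# Methods

`infodesign` selects, from a finite menu of candidate experiments on an ODE
model, the experiment whose (simulated) outcome is expected to be most
informative — about the full parameter vector, about a single parameter, or
about the outcome of a target condition that cannot be measured directly.
This note records the models, the estimators, the numerical choices, and the
limits of what the test suite demonstrates.

## Observation model

Every experiment `e` observes a deterministic trajectory through Gaussian
noise:

    y = f(θ, e) + ε,   ε ~ N(0, σ²_o I)  per observable o, i.i.d. across
                       time points and readouts.

`f(θ, e)` is the solution of the model ODE under the experiment's parameter
overrides and stimulus, mapped through named linear observables and sampled
on the experiment's time grid.  Noise is homoscedastic per readout; per-time
variances are deliberately out of scope.  All densities, entropies and
mutual informations are natural-log (nats).

## Mutual-information estimators

Let `p(y|θ,e)` be the Gaussian likelihood above and `π` the prior (any
sampleable distribution — analytic or a weighted particle set).

**Joint.** `I(Θ; Y_e)` is estimated by an outer sample `θ_1..θ_N ~ π` with
`y_i ~ p(·|θ_i)`, and an evidence estimate from an independent M-sample:

    Î = (1/N) Σ_i [ log p(y_i|θ_i) − log (1/M) Σ_j p(y_i|θ'_j) ].

The evidence average runs through a max-subtracted log-mean-exp.  Reusing
the outer sample for the evidence (`reuse_outer=True`) is cheaper but biased
further downward; the default draws the M-sample independently.

**Single component.** `I(Θ_i; Y_e)` additionally needs
`p(y | θ_i) = E[p(y | θ_i, Θ_-i)]`, estimated from K conditional draws that
pin component i and redraw the rest from the prior.  This conditional step
is only defined for priors with independent components; particle priors are
rejected with an explicit error rather than silently approximated.

**Predictive.** `I(Y_e; Y_e*)` uses the conditional independence of the two
outputs given θ: with one shared M-sample, the joint density
`p(y, y*) ≈ (1/M) Σ_j p(y|θ_j,e) p(y*|θ_j,e*)` and both marginals are
evidence-style averages, and Î is their log-ratio averaged over the outer
sample.

**Error bars and bias.** Each estimate is repeated R times on independent
substreams; the reported `std_error` is the SD over repetitions divided by
√R.  Nested Monte-Carlo estimators are *biased* at finite inner sample size:
the joint estimator is biased upward (the evidence is underestimated), the
component estimator's numerator adds a downward bias that grows as the
conditional likelihood concentrates.  Two practical consequences, both
visible in the test suite:

* for oracle comparisons the inner size K must scale with the concentration
  of the conditional likelihood (the closed-form suite uses K = 400);
* when the numerator and denominator use very different sample sizes
  (K ≪ M), the bias difference can dominate the signal and even produce
  negative values; analyses that difference two estimates (the Hes1 readout
  comparison) therefore use K = M so the two log-mean-exp biases largely
  cancel.

In wide-output, low-noise regimes (240 observed cells for the
repressilator) the absolute estimates at the sample sizes used here
(N = M = 500) are saturated — dominated by the nearest evidence draw — and
should be read as a *diversity ranking* of experiments, not as calibrated
nats.  Rankings at matched seeds are what the package's claims rest on; the
paper-scale estimates would require orders of magnitude more simulations.

**Failures.** Parameter draws whose integration fails are rejected and
redrawn (counted on the estimate).  An estimate aborts only if failures
exceed 10× the sample size.

## Built-in systems and their defaults

Constants below are package defaults chosen once to put each system in its
characteristic regime; all are config-exposed.

**Repressilator** (time unit min).  Standard three-gene cyclic-repression
form: for gene i with repressor protein of the previous gene,

    dm_i/dt = −m_i + α/(1 + p_prev^n) + α₀,
    dp_i/dt = −β (p_i − m_i).

Inferable θ = (α₀, α, β, n); uniform priors α₀ ∈ [0,5], α ∈ [500,2500],
β ∈ [1,10], n ∈ [1,4]; reference θ* = (1, 1000, 5, 2) (oscillatory).
Candidates: E1 wild type; E2 β×0.1 in all genes (regime change); E3 α₀×0.1,
E4 α×0.1, E5 β×0.1 in gene 1 only (symmetry breaking — the affected term is
duplicated with a fixed scale factor, so θ stays 4-dimensional).  Grid: 40
points over [1, 40] min; all six species observed; σ² = 25 per species
(≈7 % of the θ* mRNA amplitude).  Initial state (0,2,0,1,0,3) breaks phase
symmetry so trajectories are anchored.
`repressilator_oscillation_interval` brackets the β-window where the
symmetric fixed point is unstable (eigenvalue crossing of the
finite-difference Jacobian), used by the regime-sensitivity analysis.

**Hes1** (time unit min).  Three components: mRNA m, cytosolic protein p1,
nuclear protein p2; nuclear protein represses transcription:

    dm/dt  = −k_deg m + 1/(1 + (p2/P0)^h),
    dp1/dt = −k_deg p1 + ν m − k1 p1,
    dp2/dt = −k_deg p2 + k1 p1.

k_deg is fixed at 0.03 min⁻¹ (experimentally determined); θ = (P0, h, k1, ν)
with priors P0 ∈ [0.5,5], h ∈ [2,10], k1, ν ∈ [0.005,0.1]; reference
θ* = (2.4, 6.9, 0.035, 0.025); initial state (2, 5, 3).  Grid: 15 points
over [30, 450] min; σ² = 0.25 for *both* readouts — a deliberate
simplification (real qPCR and Western-blot errors differ).  Two experiments
share the dynamics and differ in readout: mRNA, or total protein p1 + p2.

A caution about the readout comparison: under this equal-noise assumption
the two readouts are close in information content, and the per-parameter
ordering is *not* uniformly in favour of mRNA.  An average-sensitivity
(low-noise Fisher) analysis over prior draws finds the protein readout at
least as informative for P0, h and k1 and mRNA clearly ahead only for the
translation rate ν, and the matched-seed MI gaps fluctuate in sign across
master seeds at single-CPU sample sizes.  The corresponding acceptance
check of the strict "mRNA wins everywhere" ordering is accordingly expected
to fail under these defaults; an instrument-asymmetric noise model (blots
noisier than qPCR) would favour mRNA but is not the package default.

**EGF → AKT → S6 cascade** (time unit s).  Eleven species (EGF, EGFR,
pEGFR, pEGFR-AKT, AKT, pAKT, S6, pAKT-S6, pS6, pro-EGFR, EGF-EGFR),
mass-action: EGF binds EGFR; the complex converts to phosphorylated
receptor; pro-EGFR replenishes receptor (turnover); pEGFR is removed;
pEGFR and pAKT drive the two phosphorylation cycles through explicit
complexes.  Total AKT and total S6 are conserved.  Extracellular EGF tracks
the applied stimulus with a fast relaxation (0.1 s⁻¹) rather than being
clamped, so the input enters the ODE smoothly within stimulus segments.
θ = 10 rate constants plus the initial receptor concentration EGFR0
(nominal values in `AKT_THETA_STAR`, tuned so an impulse gives the
characteristic ordering pEGFR peak ≈ 4 min, pAKT ≈ 6 min, pS6 ≈ 20 min and
slow decay); prior: uniform within [nominal/2, nominal×2].  Observables
(pEGFR, pAKT, pS6) on a 13-point grid over one hour with σ² of roughly
(5 % of each readout's range)².  Menu: impulses (60 s) at 1/3/10/20/30
ng/ml, steps (60 min) at 1/5/10/30, ramps (60 min) to 5/15/30; target: five
60 s pulses of 20 ng/ml spaced 300 s with |N(0, 1)| background noise
redrawn every 30 s.

## Stimuli and integration

Inputs are deterministic once seeded.  The pulse-train background is
piecewise-constant on a fixed grid (`noise_grid_dt`) rather than idealized
white noise, so the right-hand side is finitely parameterized and
reproducible; the "impulse" is a finite-width step.  Integration uses LSODA
(rtol 1e−6, atol 1e−8 defaults) piecewise between stimulus breakpoints —
pulse edges and noise-grid switches — because adaptive solvers assume a
smooth right-hand side.  Right-hand sides are numba-compiled when numba is
present; the NumPy fallbacks are the reference implementations.

## ABC SMC

The posterior validation uses ABC SMC with: scale-balanced Euclidean
distance (each readout column standardized by the data column SD); noisy
simulations (`y_sim = f(θ) + ε`, matching the generative model — without
this the accepted set collapses onto the best-fitting point as ε → 0 and
the posterior spread is understated); tolerance schedule ε_{t+1} =
q-quantile of accepted distances (default q = 0.5, the case studies use
0.3); full-covariance Gaussian kernel with twice the weighted covariance of
the previous population (a component-wise kernel is available but wastes
nearly all proposals on the correlated ridges typical of ODE posteriors,
and in high-dimensional uniform priors steps outside the box almost
surely); importance weights with the uniform-prior constant numerator;
stopping when the acceptance rate per simulation (out-of-prior proposals
are free and not counted) falls below 1 % or at `max_generations`.  A
generation with zero acceptances rolls the tolerance back once, then fails
with diagnostics.  Weighted populations are resampled to equal weights
before entropy estimation or reuse as a design prior.

## Entropy validation

Information gain is the difference of plug-in histogram entropies of prior
and posterior samples under one shared discretization (default 10 bins per
dimension on the prior box; marginals for high-dimensional models).  The
plug-in estimator is biased and discretization changes the entropy scale,
so the package compares *gains across experiments at fixed settings* and
never compares entropy gains with mutual-information magnitudes; the
`information_gain` contract enforces equal sample sizes on both sides.

## What the synthetic data does and does not show

Fixtures are draws from the package's own observation model at a reference
θ*.  Passing tests therefore demonstrate internal consistency — estimators
converge to closed forms where those exist, rankings agree between MI and
entropy-gain routes, posteriors recover generating parameters — under
exactly the modelled noise (Gaussian, homoscedastic, uncorrelated).  Real
time-course data (Western blots, qPCR) bring normalization, correlated and
non-Gaussian errors, and model misspecification, none of which are
emulated; a real application should revisit σ² per readout and the distance
choice.

## Problem sizes in the test suite

The acceptance tests run, on one CPU, with: closed-form oracle suite
N = M = 2000, R = 8 (K = 400 for the component form); repressilator ranking
N = M = 500, R = 5; Hes1 readout comparison N = 60, K = M = 150, R = 2 at
matched seeds; AKT predictive ranking N = M = 80, R = 2 from a 128-particle
posterior-as-prior; ABC fits with 128 particles, ≤ 9 generations, q = 0.3.
These sizes are the package's scaled-down defaults for a single-CPU run.
The repressilator selection (a symmetry-breaking variant on top, wild type
never) and the AKT selection (a step stimulus on top) are stable across
master seeds at these sizes; which of the two best repressilator variants
(E3, E5) lands first is a genuine statistical tie, and the Hes1
per-parameter readout ordering is within Monte-Carlo noise (see the Hes1
section above).

## Known limitations

* Absolute MI values in wide-output regimes are saturated (see above).
* The component estimator requires independent priors.
* ABC settings are not claimed to match any particular external toolbox
  run; only qualitative findings (rankings, identifiability patterns) are
  asserted.
* Stochastic kinetics (SDE/CME), delay equations, correlated or
  multiplicative noise, SBML import, continuous design spaces, and batch
  (parallel) selection are out of scope.
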