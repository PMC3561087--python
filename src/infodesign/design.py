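"""Experiment ranking and the iterative design loop.

Design proceeds by computing, for every candidate experiment, the mutual
information between its (simulated) outcome and the design target — the full
parameter vector, one parameter component, or the outcome of a target
experiment — and selecting the candidate with the highest estimate.  The full
ranked report is returned rather than just the argmax, since near-ties within
Monte-Carlo error are common and the judgment of what is a *substantial* gap
is left to the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .abc_smc import AbcSettings, fit_multi
from .mi import (EstimationError, MIEstimate, SolverSettings,
                 estimate_mi_component, estimate_mi_joint, estimate_mi_predictive)
from .models import ExperimentSpec
from .priors import ParticlePopulation

logger = logging.getLogger("infodesign")

__all__ = ["DesignTarget", "EstimatorSettings", "DesignReport",
           "rank_experiments", "iterate_design"]


@dataclass(frozen=True)
class DesignTarget:
    """What the chosen experiment should be informative about.

    kind: ``inference`` (full parameter vector), ``component`` (one named
    parameter), or ``prediction`` (the outcome of a target experiment).
    """

    kind: str
    parameter: Optional[str] = None
    experiment: Optional[ExperimentSpec] = None

    def __post_init__(self):
        if self.kind not in ("inference", "component", "prediction"):
            raise ValueError(f"unknown design target kind {self.kind!r}")
        if self.kind == "component" and not self.parameter:
            raise ValueError("component target needs a parameter name")
        if self.kind == "prediction" and self.experiment is None:
            raise ValueError("prediction target needs a target experiment")

    @classmethod
    def inference(cls):
        return cls("inference")

    @classmethod
    def component(cls, parameter: str):
        return cls("component", parameter=parameter)

    @classmethod
    def prediction(cls, experiment: ExperimentSpec):
        return cls("prediction", experiment=experiment)

    def label(self) -> str:
        if self.kind == "inference":
            return "joint"
        if self.kind == "component":
            return f"component:{self.parameter}"
        return f"predictive:{self.experiment.id}"


@dataclass(frozen=True)
class EstimatorSettings:
    N: int = 1000
    M: int = 1000
    K: int = 100
    R: int = 5
    reuse_outer: bool = False
    solver: SolverSettings = SolverSettings()


@dataclass
class DesignReport:
    """Ranked candidate experiments for one design target."""

    target: str
    entries: list                      # [(experiment_id, MIEstimate)], sorted desc
    selected: str
    failed: dict = field(default_factory=dict)   # experiment_id -> error message
    tie_warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "selected": self.selected,
            "entries": [dict(experiment_id=eid, **est.to_dict())
                        for eid, est in self.entries],
            "failed": self.failed,
            "tie_warnings": self.tie_warnings,
        }

    def estimate_for(self, experiment_id: str) -> MIEstimate:
        for eid, est in self.entries:
            if eid == experiment_id:
                return est
        raise KeyError(experiment_id)


def _order_with_ties(results):
    """Sort descending by MI; lexicographic id within groups that overlap
    within one combined standard error of the group leader."""
    ordered = sorted(results, key=lambda kv: (-kv[1].value, kv[0]))
    groups, warnings = [], []
    for eid, est in ordered:
        if groups:
            lead_id, lead = groups[-1][0]
            combined = lead.std_error + est.std_error
            if lead.value - est.value <= combined:
                groups[-1].append((eid, est))
                continue
        groups.append([(eid, est)])
    out = []
    for g in groups:
        if len(g) > 1:
            g = sorted(g, key=lambda kv: kv[0])
            ids = [eid for eid, _ in g]
            warnings.append(
                f"experiments {ids} overlap within 1 combined std_error; "
                "tie broken lexicographically")
            logger.warning(warnings[-1])
        out.extend(g)
    return out, warnings


def rank_experiments(candidates, target: DesignTarget, prior,
                     settings: EstimatorSettings = EstimatorSettings(),
                     seed: int = 0) -> DesignReport:
    """Estimate the target mutual information for every candidate and rank.

    Each candidate runs on its own substream derived from *seed*, so the
    report is deterministic given the seed.  An estimator failure on one
    candidate flags that candidate in ``report.failed`` instead of dropping
    it silently.
    """
    if not candidates:
        raise ValueError("rank_experiments requires at least one candidate")
    results, failed = [], {}
    for j, exp in enumerate(candidates):
        sub_seed = int(np.random.SeedSequence([int(seed), j]).generate_state(1)[0] % (2 ** 31))
        try:
            if target.kind == "inference":
                est = estimate_mi_joint(
                    exp.model, exp, prior, N=settings.N, M=settings.M,
                    R=settings.R, seed=sub_seed, reuse_outer=settings.reuse_outer,
                    settings=settings.solver)
            elif target.kind == "component":
                est = estimate_mi_component(
                    target.parameter, exp.model, exp, prior, N=settings.N,
                    K=settings.K, M=settings.M, R=settings.R, seed=sub_seed,
                    settings=settings.solver)
            else:
                est = estimate_mi_predictive(
                    exp, target.experiment, model=exp.model, prior=prior,
                    N=settings.N, M=settings.M, R=settings.R, seed=sub_seed,
                    settings=settings.solver,
                    model_target=target.experiment.model)
        except EstimationError as exc:
            logger.warning("candidate %s failed: %s", exp.id, exc)
            failed[exp.id] = str(exc)
            continue
        logger.info("candidate %s: %.4f +/- %.4f nats", exp.id, est.value, est.std_error)
        results.append((exp.id, est))
    if not results:
        raise EstimationError("every candidate experiment failed to estimate")
    entries, warnings = _order_with_ties(results)
    return DesignReport(target=target.label(), entries=entries,
                        selected=entries[0][0], failed=failed,
                        tie_warnings=warnings)


def iterate_design(prior, candidates, target: DesignTarget,
                   data_source: Callable[[ExperimentSpec], object],
                   estimator_settings: EstimatorSettings = EstimatorSettings(),
                   abc_settings: AbcSettings = AbcSettings(),
                   abc_prior=None, seed: int = 0):
    """One round of the sequential design loop.

    Ranks the candidates, selects the top experiment, acquires its data via
    ``data_source`` (a real file loader or a synthetic generator), fits the
    posterior by ABC SMC, and returns ``(report, posterior)``.  The returned
    :class:`ParticlePopulation` is the natural prior for the next round:
    today's posterior is tomorrow's prior.

    ``abc_prior`` lets the ABC fit run from an analytic prior when ``prior``
    itself is already a particle population.
    """
    report = rank_experiments(candidates, target, prior,
                              settings=estimator_settings, seed=seed)
    chosen = next(e for e in candidates if e.id == report.selected)
    dataset = data_source(chosen)
    fit_prior = abc_prior if abc_prior is not None else prior
    if isinstance(fit_prior, ParticlePopulation):
        raise ValueError(
            "ABC SMC needs an analytic prior with known support; pass "
            "abc_prior= explicitly when designing from a particle population")
    posterior = fit_multi(chosen.model, [(chosen, dataset)], fit_prior,
                          settings=abc_settings, seed=seed)
    return report, posterior
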