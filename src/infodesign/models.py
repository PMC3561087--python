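"""Built-in ODE systems and candidate-experiment menus.

Three systems are provided:

* the **repressilator** — three genes in a cyclic repression loop (states
  ``m1..m3, p1..p3``), with four inferable parameters ``alpha0`` (basal
  transcription), ``alpha`` (repressible transcription), ``beta``
  (protein/mRNA decay ratio) and ``n`` (Hill coefficient), plus five candidate
  experiments E1..E5 (wild type and four parameter-decreasing interventions,
  three of which act on a single gene and break the rotational symmetry);
* the **Hes1 oscillator** — a three-component negative-feedback model (mRNA,
  cytosolic protein, nuclear protein) whose nuclear protein represses
  transcription; the two candidate experiments share the dynamics and differ
  only in the readout: mRNA (real-time PCR) versus total protein (Western
  blot);
* the **EGF→AKT→S6 cascade** — an 11-species mass-action model of receptor
  activation and downstream phosphorylation, driven by an extracellular EGF
  input; the design menu is 12 simple stimuli (impulse/step/ramp at several
  intensities) and the target is a noisy 5-pulse train that is hard to realize
  experimentally.

Numeric constants (nominal parameter values, prior bounds, noise variances,
stimulus intensities and time grids) are package defaults chosen to put each
system in its characteristic dynamical regime; they are documented in
``docs/methods.md`` and logged as assumptions by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from . import _kernels
from .priors import UniformPrior
from .stimulus import StimulusSpec

__all__ = [
    "OdeModel",
    "ExperimentSpec",
    "build_repressilator",
    "build_hes1",
    "build_akt",
    "repressilator_prior",
    "hes1_prior",
    "akt_prior",
    "REPRESSILATOR_THETA_STAR",
    "HES1_THETA_STAR",
    "AKT_THETA_STAR",
    "repressilator_oscillation_interval",
]


class ConfigurationError(ValueError):
    """Bad model/experiment configuration."""


@dataclass(frozen=True)
class OdeModel:
    """A parametric ODE system dx/dt = g(x, theta, u(t)).

    ``rhs`` has signature ``rhs(x, t, theta, u)`` with ``u`` the scalar input
    value at time ``t`` (0 for unstimulated models).  ``observables`` are
    named linear maps from the state vector to a scalar readout.
    ``initial_state`` may be a vector or a callable of theta (used when an
    initial concentration is itself an inferable parameter).
    """

    name: str
    state_names: tuple
    parameter_names: tuple
    rhs: Callable
    initial_state: object
    observables: dict
    time_unit: str = "min"
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.state_names)
        if k < 1 or len(self.parameter_names) < 1:
            raise ConfigurationError("model needs at least one state and one parameter")
        for name, w in self.observables.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (k,):
                raise ConfigurationError(
                    f"observable {name!r} must be a weight vector of length {k}")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def x0(self, theta) -> np.ndarray:
        if callable(self.initial_state):
            return np.asarray(self.initial_state(np.asarray(theta, float)), dtype=float)
        return np.asarray(self.initial_state, dtype=float)

    def observable_matrix(self, observed) -> np.ndarray:
        try:
            return np.stack([np.asarray(self.observables[o], float) for o in observed])
        except KeyError as exc:
            raise ConfigurationError(
                f"unknown observable {exc.args[0]!r}; have {list(self.observables)}")


@dataclass(frozen=True)
class ExperimentSpec:
    """One candidate experiment: model variant + stimulus + readouts + grid."""

    id: str
    model: OdeModel
    observed: tuple
    time_grid: np.ndarray
    noise_variance: dict
    parameter_overrides: dict = field(default_factory=dict)
    stimulus: Optional[StimulusSpec] = None
    stimulus_seed: Optional[int] = None

    def __post_init__(self):
        tg = np.asarray(self.time_grid, dtype=float)
        object.__setattr__(self, "time_grid", tg)
        object.__setattr__(self, "observed", tuple(self.observed))
        if tg.size < 2 or np.any(np.diff(tg) <= 0):
            raise ConfigurationError("time_grid must be strictly increasing with >= 2 points")
        if not self.observed:
            raise ConfigurationError("at least one observable must be observed")
        for o in self.observed:
            if o not in self.model.observables:
                raise ConfigurationError(f"observable {o!r} not defined by model {self.model.name}")
            if self.noise_variance.get(o, 0.0) < 0:
                raise ConfigurationError("noise variances must be >= 0")
        for p in self.parameter_overrides:
            if p not in self.model.parameter_names:
                raise ConfigurationError(
                    f"override targets unknown parameter {p!r} of model {self.model.name}")

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    def sigma2_vector(self) -> np.ndarray:
        """Per-observable variance in `observed` order."""
        return np.array([float(self.noise_variance[o]) for o in self.observed])

    def apply_overrides(self, theta: np.ndarray) -> np.ndarray:
        """Apply global parameter overrides (fixed value or scale factor)."""
        th = np.array(theta, dtype=float)
        for name, (op, value) in self.parameter_overrides.items():
            j = self.model.parameter_names.index(name)
            if op == "scale":
                th[j] *= value
            elif op == "set":
                th[j] = value
            else:
                raise ConfigurationError(f"unknown override op {op!r}")
        return th

    def with_id(self, new_id: str) -> "ExperimentSpec":
        return replace(self, id=new_id)


# ---------------------------------------------------------------------------
# Repressilator
# ---------------------------------------------------------------------------

#: Reference parameter (alpha0, alpha, beta, n) used to generate synthetic data.
REPRESSILATOR_THETA_STAR = np.array([1.0, 1000.0, 5.0, 2.0])

_REPRESSILATOR_VARIANTS = {
    # variant: (description, global overrides, per-gene scale matrix rows
    # (alpha0, alpha, beta) for genes 1..3)
    "E1": ("wild type", {}, None),
    "E2": ("beta decreased 10x in all genes (regime change)",
           {"beta": ("scale", 0.1)}, None),
    "E3": ("alpha0 decreased 10x in gene 1 only (symmetry breaking)",
           {}, np.array([[0.1, 1.0, 1.0], [1, 1, 1], [1, 1, 1]], float)),
    "E4": ("alpha decreased 10x in gene 1 only (symmetry breaking)",
           {}, np.array([[1.0, 0.1, 1.0], [1, 1, 1], [1, 1, 1]], float)),
    "E5": ("beta decreased 10x in gene 1 only (symmetry breaking)",
           {}, np.array([[1.0, 1.0, 0.1], [1, 1, 1], [1, 1, 1]], float)),
}


def _repressilator_rhs_factory(gene_scales):
    if gene_scales is None:
        gene_scales = np.ones((3, 3))
    s = np.ascontiguousarray(gene_scales, dtype=float)

    def rhs(x, t, theta, u=0.0):
        return _kernels.repressilator_core(x, t, theta, u, s)

    return rhs


def repressilator_prior() -> UniformPrior:
    """Default uniform prior over (alpha0, alpha, beta, n)."""
    return UniformPrior.from_dict({
        "alpha0": (0.0, 5.0),
        "alpha": (500.0, 2500.0),
        "beta": (1.0, 10.0),
        "n": (1.0, 4.0),
    })


def _default_repressilator_grid() -> np.ndarray:
    # 40 equally spaced samples over one characteristic oscillation window
    return np.linspace(1.0, 40.0, 40)


def build_repressilator(variant: str = "E1", *, noise_variance: float = 25.0,
                        time_grid=None):
    """Build one repressilator experiment variant.

    E1 is the wild type; E2 decreases ``beta`` globally; E3–E5 decrease one
    gene's basal transcription, repressible transcription or protein decay
    respectively, breaking the three-fold symmetry while keeping exactly the
    same four inferable parameters.  All six species are observed.
    """
    if variant not in _REPRESSILATOR_VARIANTS:
        raise ConfigurationError(
            f"unknown repressilator variant {variant!r}; "
            f"valid ids: {sorted(_REPRESSILATOR_VARIANTS)}")
    desc, overrides, gene_scales = _REPRESSILATOR_VARIANTS[variant]
    states = ("m1", "m2", "m3", "p1", "p2", "p3")
    eye = np.eye(6)
    model = OdeModel(
        name=f"repressilator:{variant}",
        state_names=states,
        parameter_names=("alpha0", "alpha", "beta", "n"),
        rhs=_repressilator_rhs_factory(gene_scales),
        initial_state=np.array([0.0, 2.0, 0.0, 1.0, 0.0, 3.0]),
        observables={name: eye[i] for i, name in enumerate(states)},
        time_unit="min",
        fixed={"variant": variant, "description": desc,
               "gene_scales": None if gene_scales is None else gene_scales},
    )
    grid = _default_repressilator_grid() if time_grid is None else np.asarray(time_grid, float)
    exp = ExperimentSpec(
        id=variant, model=model, observed=states, time_grid=grid,
        noise_variance={s: noise_variance for s in states},
        parameter_overrides=overrides,
    )
    return model, exp


def build_repressilator_menu(**kwargs):
    """The five-experiment design menu E1..E5."""
    return [build_repressilator(v, **kwargs)[1] for v in sorted(_REPRESSILATOR_VARIANTS)]


def repressilator_oscillation_interval(alpha0: float, alpha: float, n: float,
                                       beta_range=(0.05, 50.0), n_grid: int = 400):
    """Numerically bracket the beta-interval where the symmetric fixed point
    is unstable (sustained oscillations).

    The symmetric fixed point loses stability through a Hopf bifurcation as
    ``beta`` crosses the interval endpoints.  Used by the regime-sensitivity
    analysis to place priors inside versus straddling a bifurcation.
    """
    from scipy.optimize import brentq

    # symmetric fixed point: m = p and p = alpha0 + alpha / (1 + p^n)
    def fp(p):
        return alpha0 + alpha / (1.0 + p ** n) - p

    p_star = brentq(fp, 1e-9, alpha0 + alpha + 1.0)
    x_slope = alpha * n * p_star ** (n - 1) / (1.0 + p_star ** n) ** 2  # -d f / d p

    def max_real_eig(beta):
        model, _ = build_repressilator("E1")
        theta = np.array([alpha0, alpha, beta, n])
        x = np.array([p_star] * 6)
        # finite-difference Jacobian of the 6-D system at the fixed point
        f0 = model.rhs(x, 0.0, theta)
        J = np.zeros((6, 6))
        h = 1e-6 * max(1.0, p_star)
        for j in range(6):
            xp = x.copy()
            xp[j] += h
            J[:, j] = (model.rhs(xp, 0.0, theta) - f0) / h
        return float(np.max(np.linalg.eigvals(J).real))

    betas = np.geomspace(beta_range[0], beta_range[1], n_grid)
    signs = np.array([max_real_eig(b) for b in betas])
    unstable = signs > 0
    if not unstable.any():
        return None
    idx = np.where(unstable)[0]
    lo_i, hi_i = idx[0], idx[-1]
    lo = betas[lo_i] if lo_i == 0 else brentq(max_real_eig, betas[lo_i - 1], betas[lo_i])
    hi = betas[hi_i] if hi_i == n_grid - 1 else brentq(max_real_eig, betas[hi_i], betas[hi_i + 1])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Hes1
# ---------------------------------------------------------------------------

#: Reference parameter (P0, h, k1, nu) for synthetic Hes1 data.
HES1_THETA_STAR = np.array([2.4, 6.9, 0.035, 0.025])

#: mRNA/protein degradation rate, experimentally determined (min^-1).
HES1_KDEG = 0.03


def _hes1_rhs(x, t, theta, u=0.0, kdeg=HES1_KDEG):
    return _kernels.hes1_core(x, t, theta, u, kdeg)


def hes1_prior() -> UniformPrior:
    return UniformPrior.from_dict({
        "P0": (0.5, 5.0),
        "h": (2.0, 10.0),
        "k1": (0.005, 0.1),
        "nu": (0.005, 0.1),
    })


def build_hes1(*, noise_variance: float = 0.25, time_grid=None):
    """Build the Hes1 model and its two candidate readout experiments.

    The model has a transcriptional negative feedback: nuclear protein ``p2``
    represses mRNA production through a Hill function with threshold ``P0``
    and coefficient ``h``; mRNA is translated into cytosolic protein ``p1``
    (rate ``nu``) which is transported into the nucleus (rate ``k1``).  The
    common degradation rate is fixed at 0.03 min^-1.  The two experiments
    observe mRNA or the summed (cytosolic + nuclear) protein.
    """
    model = OdeModel(
        name="hes1",
        state_names=("m", "p1", "p2"),
        parameter_names=("P0", "h", "k1", "nu"),
        rhs=_hes1_rhs,
        initial_state=np.array([2.0, 5.0, 3.0]),
        observables={
            "mRNA": np.array([1.0, 0.0, 0.0]),
            "total_protein": np.array([0.0, 1.0, 1.0]),
        },
        time_unit="min",
        fixed={"kdeg": HES1_KDEG},
    )
    grid = np.linspace(30.0, 450.0, 15) if time_grid is None else np.asarray(time_grid, float)
    exps = [
        ExperimentSpec(id="hes1_mrna", model=model, observed=("mRNA",),
                       time_grid=grid, noise_variance={"mRNA": noise_variance}),
        ExperimentSpec(id="hes1_protein", model=model, observed=("total_protein",),
                       time_grid=grid,
                       noise_variance={"total_protein": noise_variance}),
    ]
    return model, exps


# ---------------------------------------------------------------------------
# EGF -> AKT -> S6 cascade
# ---------------------------------------------------------------------------

_AKT_STATES = ("EGF", "EGFR", "pEGFR", "pEGFR_AKT", "AKT", "pAKT",
               "S6", "pAKT_S6", "pS6", "proEGFR", "EGF_EGFR")

_AKT_PARAMS = ("k_bind", "k_phos", "k_turnover", "k_degrade",
               "k_akt_on", "k_akt_cat", "k_akt_off",
               "k_s6_on", "k_s6_cat", "k_s6_off", "EGFR0")

#: Nominal rate constants (per second / per (ng/ml) per second) + EGFR0.
AKT_THETA_STAR = np.array([
    0.003,    # k_bind: EGF + EGFR -> EGF-EGFR
    0.02,     # k_phos: EGF-EGFR -> pEGFR
    0.0005,   # k_turnover: pro-EGFR -> EGFR
    0.005,    # k_degrade: pEGFR -> (removed)
    0.05,     # k_akt_on: pEGFR + AKT -> pEGFR-AKT
    0.02,     # k_akt_cat: pEGFR-AKT -> pEGFR + pAKT
    0.008,    # k_akt_off: pAKT -> AKT
    0.01,     # k_s6_on: pAKT + S6 -> pAKT-S6
    0.005,    # k_s6_cat: pAKT-S6 -> pAKT + pS6
    0.0005,   # k_s6_off: pS6 -> S6
    1.0,      # EGFR0: initial receptor concentration
])

_AKT_EGF_TRACK = 0.1  # 1/s, rate at which extracellular EGF tracks the input


def _akt_rhs(x, t, theta, u=0.0):
    return _kernels.akt_core(x, t, theta, u, _AKT_EGF_TRACK)


def _akt_x0(theta):
    x0 = np.zeros(11)
    x0[_AKT_STATES.index("EGFR")] = theta[-1]   # EGFR0 is a parameter
    x0[_AKT_STATES.index("AKT")] = 1.0
    x0[_AKT_STATES.index("S6")] = 1.0
    x0[_AKT_STATES.index("proEGFR")] = 1.0
    return x0


def akt_prior(width: float = 2.0) -> UniformPrior:
    """Uniform prior: each rate within [nominal/width, nominal*width]."""
    return UniformPrior(
        _AKT_PARAMS, AKT_THETA_STAR / width, AKT_THETA_STAR * width)


#: Design menu: 5 impulse intensities, 4 step intensities, 3 ramp final
#: intensities (ng/ml).  Impulses last 60 s; steps and ramps 60 min.
AKT_IMPULSE_INTENSITIES = (1.0, 3.0, 10.0, 20.0, 30.0)
AKT_STEP_INTENSITIES = (1.0, 5.0, 10.0, 30.0)
AKT_RAMP_INTENSITIES = (5.0, 15.0, 30.0)


def build_akt(*, time_grid=None, noise_variance=None, target_noise_seed: int = 20130131):
    """Build the AKT cascade, its 12-stimulus design menu, and the target.

    Returns ``(model, candidates, target)`` where ``candidates`` are the 12
    realizable stimuli (5 impulse, 4 step, 3 ramp intensities) and ``target``
    is the noisy 5-pulse-train experiment whose outcome we want to predict.
    All experiments observe (pEGFR, pAKT, pS6).
    """
    eye = np.eye(11)
    model = OdeModel(
        name="akt",
        state_names=_AKT_STATES,
        parameter_names=_AKT_PARAMS,
        rhs=_akt_rhs,
        initial_state=_akt_x0,
        observables={s: eye[i] for i, s in enumerate(_AKT_STATES)},
        time_unit="s",
    )
    grid = np.linspace(0.0, 3600.0, 13) if time_grid is None else np.asarray(time_grid, float)
    if noise_variance is None:
        # ~5% of each readout's typical dynamic range at the nominal parameter
        noise_variance = {"pEGFR": 4e-4, "pAKT": 1e-3, "pS6": 1e-3}
    observed = ("pEGFR", "pAKT", "pS6")

    def make(exp_id, stim):
        return ExperimentSpec(id=exp_id, model=model, observed=observed,
                              time_grid=grid, noise_variance=dict(noise_variance),
                              stimulus=stim)

    candidates = []
    for a in AKT_IMPULSE_INTENSITIES:
        candidates.append(make(f"impulse_{a:g}", StimulusSpec(
            shape="impulse", amplitude=a, duration=60.0, onset=60.0)))
    for a in AKT_STEP_INTENSITIES:
        candidates.append(make(f"step_{a:g}", StimulusSpec(
            shape="step", amplitude=a, duration=3600.0, onset=60.0)))
    for a in AKT_RAMP_INTENSITIES:
        candidates.append(make(f"ramp_{a:g}", StimulusSpec(
            shape="ramp", amplitude=a, duration=3600.0, onset=60.0)))

    target = ExperimentSpec(
        id="pulse_train_target", model=model, observed=observed,
        time_grid=grid, noise_variance=dict(noise_variance),
        stimulus=StimulusSpec(shape="pulse_train", amplitude=20.0, duration=60.0,
                              onset=60.0, n_pulses=5, spacing=300.0,
                              background_noise_variance=1.0, noise_grid_dt=30.0),
        stimulus_seed=target_noise_seed,
    )
    return model, candidates, target
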