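"""Extracellular stimulus (input signal) library.

Inputs are deterministic functions of time once a seed is fixed, so the ODE
right-hand side stays well-defined for adaptive solvers.  Four shapes are
supported:

``impulse``
    a short finite-width rectangle (amplitude for ``duration`` seconds);
``step``
    a long rectangle — same functional form as the impulse, longer duration;
``ramp``
    linear rise from 0 to ``amplitude`` over ``duration``, then held;
``pulse_train``
    ``n_pulses`` rectangles spaced ``spacing`` apart, plus a background term
    equal to the absolute value of a zero-mean Gaussian with variance
    ``background_noise_variance``, redrawn every ``noise_grid_dt`` seconds and
    held piecewise-constant in between.

The piecewise-constant background replaces idealized white noise: a solver
needs a finitely-parameterized, reproducible input path.  The noise path is
drawn once per (seed) from a dedicated generator, so re-evaluating a stimulus
at the same ``(t, seed)`` is bit-identical — a requirement for deterministic
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["StimulusSpec", "evaluate_stimulus", "StimulusPath"]

_SHAPES = ("none", "impulse", "step", "ramp", "pulse_train")


@dataclass(frozen=True)
class StimulusSpec:
    """Descriptor of one input signal (concentrations in ng/ml, times in s)."""

    shape: str = "none"
    amplitude: float = 0.0
    duration: float = 0.0
    onset: float = 0.0
    n_pulses: int = 1
    spacing: float = 0.0
    background_noise_variance: float = 0.0
    noise_grid_dt: float = 1.0

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown stimulus shape {self.shape!r}; expected one of {_SHAPES}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape != "none" and self.duration <= 0:
            raise ValueError("duration must be > 0 for non-trivial stimuli")
        if self.shape == "pulse_train":
            if self.n_pulses < 1:
                raise ValueError("pulse_train needs n_pulses >= 1")
            if self.background_noise_variance < 0:
                raise ValueError("background_noise_variance must be >= 0")
            if self.noise_grid_dt <= 0:
                raise ValueError("noise_grid_dt must be > 0")

    def to_dict(self) -> dict:
        return {
            "shape": self.shape, "amplitude": self.amplitude,
            "duration": self.duration, "onset": self.onset,
            "n_pulses": self.n_pulses, "spacing": self.spacing,
            "background_noise_variance": self.background_noise_variance,
            "noise_grid_dt": self.noise_grid_dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)


class StimulusPath:
    """A concrete, fully-determined input path u(t) on [0, t_max].

    Precomputes the pulse-train background noise so scalar evaluation inside
    an ODE right-hand side is cheap, and exposes the discontinuity points so
    the integrator can split at them.
    """

    def __init__(self, spec: StimulusSpec, t_max: float, seed: Optional[int] = None):
        self.spec = spec
        self.t_max = float(t_max)
        self.seed = seed
        self._noise = None
        if spec.shape == "pulse_train" and spec.background_noise_variance > 0:
            if seed is None:
                raise ValueError("pulse_train with background noise requires a seed")
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
            n = int(np.ceil(self.t_max / spec.noise_grid_dt)) + 1
            self._noise = np.abs(rng.normal(0.0, np.sqrt(spec.background_noise_variance), n))

    # -- pulse bookkeeping -------------------------------------------------
    def _pulse_edges(self):
        s = self.spec
        edges = []
        if s.shape in ("impulse", "step", "ramp"):
            edges = [s.onset, s.onset + s.duration]
        elif s.shape == "pulse_train":
            for k in range(s.n_pulses):
                start = s.onset + k * s.spacing
                edges += [start, start + s.duration]
        return edges

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Times in (t0, t1) where u(t) is non-smooth."""
        pts = set(self._pulse_edges())
        s = self.spec
        if self._noise is not None:
            k0 = int(np.floor(t0 / s.noise_grid_dt)) + 1
            k1 = int(np.ceil(t1 / s.noise_grid_dt))
            pts.update(k * s.noise_grid_dt for k in range(k0, k1 + 1))
        return np.array(sorted(p for p in pts if t0 < p < t1))

    def _base(self, t: float) -> float:
        s = self.spec
        if s.shape == "none":
            return 0.0
        if s.shape in ("impulse", "step"):
            return s.amplitude if s.onset <= t < s.onset + s.duration else 0.0
        if s.shape == "ramp":
            if t < s.onset:
                return 0.0
            frac = (t - s.onset) / s.duration
            return s.amplitude * min(frac, 1.0)
        # pulse_train
        if t >= s.onset:
            k = int((t - s.onset) // s.spacing) if s.spacing > 0 else 0
            if k < s.n_pulses:
                within = (t - s.onset) - k * s.spacing
                if 0 <= within < s.duration:
                    return s.amplitude
        return 0.0

    def __call__(self, t: float) -> float:
        v = self._base(t)
        if self._noise is not None:
            k = min(int(t // self.spec.noise_grid_dt), self._noise.size - 1)
            v += self._noise[k]
        return v

    def values(self, ts) -> np.ndarray:
        return np.array([self(float(t)) for t in np.atleast_1d(ts)])


def evaluate_stimulus(spec: StimulusSpec, t: float, seed: Optional[int] = None) -> float:
    """Evaluate the input signal at time *t* (seconds).

    For ``pulse_train`` with background noise a *seed* is mandatory so the
    noise path is reproducible and shared by every evaluation within one
    trajectory.
    """
    if t < 0:
        raise ValueError("stimulus time must be non-negative")
    path = StimulusPath(spec, t_max=max(t, 1.0), seed=seed)
    return path(float(t))
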