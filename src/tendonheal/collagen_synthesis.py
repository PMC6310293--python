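"""Strain-dependent collagen synthesis.

Maps the mean cellular strain over one gait cycle to a per-cell collagen
synthesis rate through a sigmoidal response curve fitted to in vitro stretch
experiments:

    rate(eps_m) = floor + amplitude / (1 + exp(-steepness * (g(eps_m) - inflection)))

with floor 0.6 and amplitude 1.3 (arbitrary collagen units per cell per hour),
steepness 150 and inflection 0.02 on the transformed strain ``g(eps_m)``.  The
default transform is the identity; ``g(eps) = eps/2`` is available as a config
alternative.  Output is bounded in [0.6, 1.9]; only ratios and orderings of
this rate are meaningful because the underlying in vitro data report relative
changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics_strain import StrainProfile

__all__ = ["SynthesisCurve", "mean_strain", "synthesis_rate"]

_TRANSFORMS = {
    "identity": lambda e: e,
    "half": lambda e: e / 2.0,
}


@dataclass(frozen=True)
class SynthesisCurve:
    """Sigmoidal mean-strain -> collagen synthesis response curve."""

    amplitude: float = 1.3
    steepness: float = 150.0
    inflection: float = 0.02
    floor: float = 0.6
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}; "
                             f"choose from {sorted(_TRANSFORMS)}")
        if self.amplitude < 0 or self.steepness <= 0:
            raise ValueError("amplitude must be >= 0 and steepness > 0")

    @property
    def upper(self) -> float:
        return self.floor + self.amplitude

    def __call__(self, eps_m: float) -> float:
        return synthesis_rate(eps_m, self)


def mean_strain(profile: StrainProfile) -> float:
    """Time-average of a cell-level strain profile over one period.

    Integrates the trace with the trapezoidal rule over the profile's period
    (for a constant profile this is just the constant).  The profile must
    cover at least one full period.
    """
    t = np.asarray(profile.times, dtype=float)
    e = np.asarray(profile.strain, dtype=float)
    if t.size == 0:
        raise ValueError("empty strain profile")
    if t.size == 1:
        return float(e[0])
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("profile times must be strictly increasing")
    if profile.period is not None and span < profile.period * (1 - 1e-9):
        raise ValueError(
            f"profile covers {span:g} s which is less than one period "
            f"({profile.period:g} s)")
    # restrict to exactly one period from the start when the trace is longer
    if profile.period is not None and span > profile.period:
        mask = t <= t[0] + profile.period + 1e-12
        t, e = t[mask], e[mask]
    return float(np.trapezoid(e, t) / (t[-1] - t[0]))


def synthesis_rate(eps_m: float, curve: SynthesisCurve | None = None) -> float:
    """Collagen synthesis rate (arbitrary units per cell per hour) at mean strain eps_m."""
    if curve is None:
        curve = SynthesisCurve()
    if not math.isfinite(eps_m):
        raise ValueError("mean strain must be finite")
    g = _TRANSFORMS[curve.transform](eps_m)
    x = -curve.steepness * (g - curve.inflection)
    # exp overflow guard: the sigmoid saturates to floor / floor+amplitude
    if x > 700.0:
        return curve.floor
    return curve.floor + curve.amplitude / (1.0 + math.exp(x))
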