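"""Downstream (tracheal) pressure drivers and the quasi-steadiness diagnostic.

Three canonical inspiratory-effort ramps drive the simulations, all
reaching the most-negative outlet pressure (default −600 Pa) at the end of
the ramp:

* linear:       p(t) = amplitude · t/T
* sinusoidal:   p(t) = amplitude · sin(π t / 2T)
* exponential:  p(t) = amplitude · e^{k(1 − t/T)},  k = ln(1/|amplitude|)

so that the exponential ramp starts at −1 Pa.  Profiles are
scale-invariant in duration: a slow experimental ramp (~16 s) and a fast
simulated one (1 s) trace the same curve re-parameterized, which is what
makes the pressure-flow curve profile-independent in a quasi-steady model.

The Strouhal number St = f·L/V (frequency x length / velocity) diagnoses
whether unsteady effects matter; St << 1 justifies the quasi-steady
treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_KINDS = ("linear", "sinusoidal", "exponential")


@dataclass(frozen=True)
class BreathingProfile:
    """Inspiratory outlet-pressure ramp.

    Parameters
    ----------
    kind : {"linear", "sinusoidal", "exponential"}
    amplitude : float
        Most-negative outlet pressure, Pa (must be < 0; default −600).
    duration : float
        Ramp time, s (must be > 0; default 1).
    """

    kind: str = "linear"
    amplitude: float = -600.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.amplitude < 0:
            raise ValueError("amplitude must be negative (inspiratory suction)")
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    @property
    def k(self) -> float:
        """Exponential rate ln(1/|amplitude|), so that p(0) = −1 Pa."""
        return math.log(1.0 / abs(self.amplitude))

    def to_config(self) -> dict:
        return {"kind": self.kind, "amplitude_pa": self.amplitude,
                "duration_s": self.duration}

    @classmethod
    def from_config(cls, cfg: dict) -> "BreathingProfile":
        return cls(kind=cfg.get("kind", "linear"),
                   amplitude=cfg.get("amplitude_pa", -600.0),
                   duration=cfg.get("duration_s", 1.0))


def outlet_pressure(profile: BreathingProfile, t):
    """Outlet (tracheal) pressure, Pa, at time t ∈ [0, duration].

    Vectorized over ``t``.  Raises ``ValueError`` outside the ramp domain.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > profile.duration):
        raise ValueError(
            f"t must lie in [0, {profile.duration}] s"
        )
    s = t_arr / profile.duration
    if profile.kind == "linear":
        p = profile.amplitude * s
    elif profile.kind == "sinusoidal":
        p = profile.amplitude * np.sin(math.pi * s / 2.0)
    else:  # exponential
        p = profile.amplitude * np.exp(profile.k * (1.0 - s))
    return p if p.ndim else float(p)


def strouhal(f: float, L: float, V: float) -> float:
    """Strouhal number St = f·L/V.

    Parameters
    ----------
    f : float
        Characteristic frequency, Hz.
    L : float
        Characteristic length, m.
    V : float
        Characteristic velocity, m/s (must be > 0).
    """
    if not V > 0:
        raise ValueError("characteristic velocity must be positive")
    return f * L / V
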