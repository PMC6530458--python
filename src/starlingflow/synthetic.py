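"""Synthetic inputs: the default parameter grid, noisy tube-law samples,
and experiment-style traces with run-to-run valve variability.

Everything the analysis pipeline consumes can be generated here, so every
stage is testable without external data.  The default grid spans the
study conditions used throughout the documentation and tests:
wall thickness h ∈ {2, 4, 6, 8} mm at E = 2 kPa, modulus
E ∈ {2, 15, 24, 30} kPa at h = 2 mm, rest area A0 = 1.18 cm², segment
length 20 mm, and nasal-resistance presets 0.07e6 and 0.12e6 Pa·s/m³
(both nostrils open vs one blocked).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .breathing import BreathingProfile
from .material import ElasticMaterial
from .solver import AirwayModel, simulate_breathing
from .tubelaw import TubeGeometry, TubeLawModel, make_tube_law
from .units import lmin_to_m3s

#: Nasal-resistance presets, Pa·s/m³ (0.07 and 0.12 Pa·s/mL).
R_UP_OPEN = 0.07e6
R_UP_BLOCKED = 0.12e6

#: Default rest area and collapsible-segment length.
DEFAULT_A0 = 1.18e-4
DEFAULT_LENGTH = 0.020


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor/realization noise for synthetic data.

    sigma_area is relative (fraction of local area); sigma_flow and
    sigma_pressure are absolute (m³/s, Pa).  Identical seeds give
    identical output.
    """

    sigma_area: float = 0.01
    sigma_flow: float = lmin_to_m3s(0.5)
    sigma_pressure: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_area, self.sigma_flow, self.sigma_pressure) < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class SweepConfig:
    """One mechanical configuration of the sweep (SI units)."""

    h: float
    E: float
    R_up: float
    A0: float = DEFAULT_A0
    length: float = DEFAULT_LENGTH

    @property
    def label(self) -> str:
        return (
            f"h{self.h * 1e3:g}mm_E{self.E / 1e3:g}kPa_"
            f"R{self.R_up / 1e6:g}"
        )


@dataclass(frozen=True)
class SweepSpec:
    """A list of sweep configurations plus shared settings."""

    configs: tuple[SweepConfig, ...]
    nu: float = 0.48
    profile: BreathingProfile = field(default_factory=BreathingProfile)

    def __post_init__(self) -> None:
        if not self.configs:
            raise ValueError("sweep spec must contain at least one configuration")

    def models(self, **model_kwargs) -> list[tuple[SweepConfig, AirwayModel]]:
        """Build an AirwayModel for each configuration."""
        out = []
        for cfg in self.configs:
            geom = TubeGeometry(A0=cfg.A0, h=cfg.h, length=cfg.length)
            mat = ElasticMaterial(E=cfg.E, nu=self.nu)
            law = make_tube_law(geom, mat)
            out.append((cfg, AirwayModel(law=law, R_up=cfg.R_up, **model_kwargs)))
        return out


def default_parameter_grid(
    resistances: tuple[float, ...] = (R_UP_OPEN, R_UP_BLOCKED),
) -> SweepSpec:
    """The default study grid: 7 mechanical configurations × resistance presets.

    Thickness series h ∈ {2,4,6,8} mm at E = 2 kPa and elasticity series
    E ∈ {2,15,24,30} kPa at h = 2 mm (the shared h=2 mm, E=2 kPa corner
    appears once), each paired with every nasal-resistance preset.
    """
    mech: list[tuple[float, float]] = []
    for h_mm in (2.0, 4.0, 6.0, 8.0):
        mech.append((h_mm * 1e-3, 2e3))
    for E_kpa in (15.0, 24.0, 30.0):
        mech.append((2e-3, E_kpa * 1e3))
    configs = tuple(
        SweepConfig(h=h, E=E, R_up=r) for r in resistances for (h, E) in mech
    )
    return SweepSpec(configs=configs)


def synth_tube_law_samples(
    law: TubeLawModel,
    n: int,
    noise: NoiseSpec = NoiseSpec(),
    p_max: float = 50.0,
) -> pd.DataFrame:
    """Noisy (pressure, area) samples of a tube law.

    Pressures are sampled uniformly between the pressure at which the law
    reaches its area floor and ``p_max`` (default +50 Pa of distension);
    areas are perturbed multiplicatively with relative noise sigma_area.

    Returns a DataFrame with columns pressure_pa, area_m2.
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(noise.seed)
    p_floor = float(law.pressure(law.A_floor))
    P = np.sort(rng.uniform(p_floor, p_max, size=n))[::-1]
    A = np.asarray(law.area(P), dtype=float)
    A = A * (1.0 + rng.normal(0.0, noise.sigma_area, size=n))
    return pd.DataFrame({"pressure_pa": P, "area_m2": A})


def _time_warp(duration: float, jitter: float, rng: np.random.Generator):
    """Random monotone re-parameterization of [0, duration].

    Monotone cubic (PCHIP) through knots whose interior spacing is
    jittered by a relative ``jitter``; emulates run-to-run variability in
    how fast a vacuum valve is opened while preserving the endpoints.
    """
    n_knots = 7
    t_knots = np.linspace(0.0, duration, n_knots)
    if jitter <= 0:
        return lambda t: np.asarray(t, dtype=float)
    gaps = np.diff(t_knots)
    gaps = gaps * np.exp(rng.normal(0.0, jitter, size=gaps.size))
    tau = np.concatenate(([0.0], np.cumsum(gaps)))
    tau *= duration / tau[-1]
    warp = PchipInterpolator(t_knots, tau)

    def f(t):
        return np.clip(warp(np.asarray(t, dtype=float)), 0.0, duration)

    return f


def synth_experiment_trace(
    model: AirwayModel,
    profile: BreathingProfile,
    noise: NoiseSpec = NoiseSpec(),
    valve_jitter: float = 0.2,
    fs: float = 100.0,
    sim_dt: Optional[float] = None,
) -> pd.DataFrame:
    """Experiment-style (t, pressure, flow) trace with sensor noise and
    valve-opening variability.

    Simulates the model once, time-warps the outlet-pressure ramp by a
    random monotone re-parameterization of strength ``valve_jitter``, and
    adds Gaussian sensor noise to pressure and flow.  Sampling at ``fs``
    Hz (default 100).  With zero jitter and zero noise the table matches
    the noiseless simulation sampled at 1/fs.

    Returns a DataFrame with columns t_s, p_out_pa, q_m3s.
    """
    rng = np.random.default_rng(noise.seed)
    dt = sim_dt if sim_dt is not None else 1.0 / fs
    trace = simulate_breathing(model, profile, dt=dt)
    # quasi-steady: flow is a function of outlet pressure only
    p_asc = trace.p_out[::-1]
    q_asc = trace.flows[::-1]
    warp = _time_warp(profile.duration, valve_jitter, rng)
    ts = np.arange(0.0, profile.duration + 0.5 / fs, 1.0 / fs)
    ts = ts[ts <= profile.duration]
    from .breathing import outlet_pressure  # local import avoids cycle at init

    p_true = np.asarray(outlet_pressure(profile, warp(ts)), dtype=float)
    p_true = np.clip(p_true, trace.p_out.min(), trace.p_out.max())
    q_true = np.interp(p_true, p_asc, q_asc)
    p_meas = p_true + rng.normal(0.0, noise.sigma_pressure, size=ts.size)
    q_meas = q_true + rng.normal(0.0, noise.sigma_flow, size=ts.size)
    return pd.DataFrame({"t_s": ts, "p_out_pa": p_meas, "q_m3s": q_meas})
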