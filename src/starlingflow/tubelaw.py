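"""Area–pressure closure (tube law) of the collapsible pharyngeal segment.

The collapsible segment is described by a monotone area–transmural-pressure
relationship A(P_tm) with three regimes:

* **Hoop (pre-buckling) branch**, P_tm > P_b + δ: the wall resists by
  circumferential stretching, A = A0·(1 + P_tm/K_lin) with areal stiffness
  K_lin = E·h / ((1−ν²)·R0), R0 = sqrt(A0/π).
* **Buckling knee**, |P_tm − P_b| ≤ δ: a circular cross-section loses
  stability near the ring-buckling pressure
  P_b = −k_b·E/(4(1−ν²))·(h/R0)³ (mode-2 ring buckling for k_b = 3) and the
  effective compliance rises from the stiff hoop value C_pre = A0/K_lin to
  the soft bending value C_knee = A_b/(n·K_p), K_p = E·h³/(12(1−ν²)·R0³).
  Compliance is ramped linearly in pressure across the knee so the law is
  C¹ everywhere.
* **Similarity (post-buckling) collapse branch**, P_tm < P_b − δ: the
  buckled cross-section follows the similarity form
  P_tm = P2 − K_eff·((A/A2)^(−n) − 1) with exponent n (default 1.5) and
  K_eff anchored so compliance is continuous at the knee exit.

Two regularizations keep the closure valid for thick walls: the buckling
pressure is clamped so the hoop branch still has positive area at buckling
(A_b ≥ buckle_area_ratio_min·A0), and areas are clipped at a floor A_floor
representing a residual slit when opposite walls approach contact
(default: ellipse of major axis 2·R0 and minor axis 0.5 mm).

The wave speed c = sqrt(A/(ρ·C)) and the wave-speed flow limit
VImax = A·c = A^{3/2}·(ρ·dA/dP)^{−1/2} are provided as free functions of
an (area, compliance) pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares


class EstimationError(ValueError):
    """Raised when a quantity cannot be estimated from the given samples."""


class UndefinedComplianceError(ValueError):
    """Raised when compliance is requested at or below the clipped area floor."""


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry of the collapsible segment.

    Parameters
    ----------
    A0 : float
        Rest (zero transmural pressure) luminal cross-sectional area, m².
    h : float
        Uniform wall thickness, m.
    length : float
        Axial length of the collapsible segment, m.
    """

    A0: float
    h: float
    length: float = 0.020

    def __post_init__(self) -> None:
        for name in ("A0", "h", "length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.h >= 10.0 * self.R0:
            warnings.warn(
                "wall thickness exceeds 10x the effective lumen radius; "
                "the shell-scale stiffness formulas are outside their "
                "validity range",
                stacklevel=2,
            )

    @property
    def R0(self) -> float:
        """Effective rest radius sqrt(A0/π), m."""
        return math.sqrt(self.A0 / math.pi)


@dataclass(frozen=True)
class FluidProperties:
    """Air properties: density rho (kg/m³) and dynamic viscosity (Pa·s)."""

    rho: float = 1.2
    mu_air: float = 1.81e-5

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("air density must be positive")
        if self.mu_air < 0:
            raise ValueError("dynamic viscosity must be >= 0")


#: Air at the density used in the wave-speed formula.
AIR = FluidProperties(rho=1.2, mu_air=1.81e-5)

#: Standard-air preset used by CFD solvers.
AIR_FSI = FluidProperties(rho=1.225, mu_air=1.79e-5)


@dataclass(frozen=True)
class TubeLawModel:
    """A C¹, monotone area–pressure closure for a collapsible segment.

    Constructed by :func:`make_tube_law` (from geometry + material) or by
    :func:`fit_tube_law` (calibrated to sampled (P, A) data).  All fields
    are SI.  ``K_lin`` is the pre-buckling areal stiffness (Pa per unit
    fractional area change), ``P_b`` the (clamped) buckling transmural
    pressure, ``n_collapse`` the post-buckling similarity exponent and
    ``A_floor`` the minimum resolvable area at which the solver clips.
    """

    A0: float
    K_lin: float
    P_b: float
    n_collapse: float
    A_floor: float
    # knee construction (derived, see make_tube_law)
    delta: float
    C_knee: float
    geometry: Optional[TubeGeometry] = None
    material: Optional["ElasticMaterial"] = field(default=None, repr=False)

    # -- derived anchors ---------------------------------------------------
    @property
    def C_pre(self) -> float:
        """Pre-buckling (hoop branch) compliance A0/K_lin, m²/Pa."""
        return self.A0 / self.K_lin

    @property
    def P1(self) -> float:
        """Transmural pressure at the stiff end of the buckling knee."""
        return self.P_b + self.delta

    @property
    def P2(self) -> float:
        """Transmural pressure at the soft end of the buckling knee."""
        return self.P_b - self.delta

    @property
    def A_b(self) -> float:
        """Area at the buckling pressure on the hoop branch."""
        return self.A0 * (1.0 + self.P_b / self.K_lin)

    @property
    def A1(self) -> float:
        """Area at the knee entry P1."""
        return self.A0 * (1.0 + self.P1 / self.K_lin)

    @property
    def A2(self) -> float:
        """Area at the knee exit P2."""
        return self.A1 - self.delta * (self.C_pre + self.C_knee)

    @property
    def K_eff(self) -> float:
        """Similarity-branch stiffness anchored for compliance continuity."""
        return self.A2 / (self.n_collapse * self.C_knee)

    # -- evaluation --------------------------------------------------------
    def area(self, P_tm):
        """Unclipped area at transmural pressure (vectorized)."""
        P = np.asarray(P_tm, dtype=float)
        x = self.P1 - P  # knee coordinate, >= 0 inside/below the knee
        beta = (self.C_knee - self.C_pre) / (4.0 * self.delta)
        a_lin = self.A0 * (1.0 + P / self.K_lin)
        a_knee = self.A1 - x * (self.C_pre + beta * x)
        with np.errstate(invalid="ignore"):
            a_sim = self.A2 * np.power(
                1.0 + (self.P2 - P) / self.K_eff, -1.0 / self.n_collapse
            )
        out = np.where(P >= self.P1, a_lin, np.where(P >= self.P2, a_knee, a_sim))
        return out if out.ndim else float(out)

    def compliance(self, P_tm):
        """Analytic dA/dP at transmural pressure (vectorized, unclipped)."""
        P = np.asarray(P_tm, dtype=float)
        c_knee_ramp = self.C_pre + (self.C_knee - self.C_pre) * (
            (self.P1 - P) / (2.0 * self.delta)
        )
        with np.errstate(invalid="ignore"):
            a_sim = self.area(np.where(P < self.P2, P, self.P2))
            c_sim = self.C_knee * np.power(a_sim / self.A2, self.n_collapse + 1.0)
        out = np.where(
            P >= self.P1, self.C_pre, np.where(P >= self.P2, c_knee_ramp, c_sim)
        )
        return out if out.ndim else float(out)

    def pressure(self, A):
        """Inverse law: transmural pressure at (unclipped) area, vectorized."""
        a = np.asarray(A, dtype=float)
        if np.any(a <= 0):
            raise ValueError("area must be strictly positive")
        beta = (self.C_knee - self.C_pre) / (4.0 * self.delta)
        p_lin = self.K_lin * (a / self.A0 - 1.0)
        if beta > 0:
            disc = np.maximum(self.C_pre**2 + 4.0 * beta * (self.A1 - a), 0.0)
            x = (-self.C_pre + np.sqrt(disc)) / (2.0 * beta)
        else:  # degenerate knee (C_knee == C_pre)
            x = (self.A1 - a) / self.C_pre
        p_knee = self.P1 - x
        with np.errstate(invalid="ignore", divide="ignore"):
            p_sim = self.P2 - self.K_eff * (
                np.power(a / self.A2, -self.n_collapse) - 1.0
            )
        out = np.where(a >= self.A1, p_lin, np.where(a >= self.A2, p_knee, p_sim))
        return out if out.ndim else float(out)

    def clipped_at(self, P_tm) -> bool:
        """True where the law would fall at or below the area floor."""
        return bool(np.all(np.asarray(self.area(P_tm)) <= self.A_floor))


def default_area_floor(geometry: TubeGeometry, gap: float = 0.5e-3) -> float:
    """Residual-slit area floor: ellipse with major axis 2·R0 and minor ``gap``.

    Mirrors a wall-contact stop rule at a 0.5 mm residual gap between
    opposite walls, scaled to the rest-area aspect of the segment.
    """
    return math.pi / 4.0 * (2.0 * geometry.R0) * gap


def make_tube_law(
    geometry: TubeGeometry,
    material: "ElasticMaterial",
    *,
    k_b: float = 3.0,
    n_collapse: float = 1.5,
    knee_frac: float = 0.1,
    buckle_area_ratio_min: float = 0.5,
    A_floor: Optional[float] = None,
    contact_gap: float = 0.5e-3,
) -> TubeLawModel:
    """Construct the tube law from geometry and wall material.

    Parameters
    ----------
    k_b : float
        Buckling coefficient; 3 gives the classical mode-2 ring-buckling
        pressure E·h³/(4(1−ν²)·R0³)·(n²−1)/... scale.
    n_collapse : float
        Similarity exponent of the post-buckling branch.
    knee_frac : float
        Half-width of the C¹ buckling knee as a fraction of |P_b|.
    buckle_area_ratio_min : float
        Thick-wall regularization: |P_b| is clamped so that the hoop branch
        area at buckling satisfies A_b ≥ this fraction of A0.
    A_floor : float, optional
        Minimum resolvable area; computed from ``contact_gap`` when omitted.

    Raises
    ------
    ValueError
        If the requested options produce a non-monotone or degenerate law.
    """
    E, nu = material.E, material.nu
    A0, h, R0 = geometry.A0, geometry.h, geometry.R0

    K_lin = E * h / ((1.0 - nu**2) * R0)
    P_b_raw = -k_b * E / (4.0 * (1.0 - nu**2)) * (h / R0) ** 3
    # clamp so the hoop branch still has area >= buckle_area_ratio_min*A0
    P_b = max(P_b_raw, -(1.0 - buckle_area_ratio_min) * K_lin)
    A_b = A0 * (1.0 + P_b / K_lin)

    K_p = E * h**3 / (12.0 * (1.0 - nu**2) * R0**3)
    C_knee = A_b / (n_collapse * K_p)
    C_pre = A0 / K_lin
    if C_knee < C_pre:
        # extremely thick wall: bending stiffer than hoop; degenerate knee
        C_knee = C_pre

    delta = max(knee_frac * abs(P_b), 1.0)
    if A_floor is None:
        A_floor = default_area_floor(geometry, gap=contact_gap)
    # thin-wall guard: the knee cannot swallow more area than the lumen
    # has above the floor; narrow it in pressure if it would
    A1 = A0 * (1.0 + (P_b + delta) / K_lin)
    knee_area_budget = A1 - max(2.0 * A_floor, 0.05 * A1)
    if delta * (C_pre + C_knee) > knee_area_budget:
        delta = knee_area_budget / (C_pre + C_knee)
        if delta <= 0:
            raise ValueError(
                "closure options leave no area budget for the buckling knee"
            )

    law = TubeLawModel(
        A0=A0,
        K_lin=K_lin,
        P_b=P_b,
        n_collapse=n_collapse,
        A_floor=A_floor,
        delta=delta,
        C_knee=C_knee,
        geometry=geometry,
        material=material,
    )
    _validate_law(law)
    return law


def _validate_law(law: TubeLawModel) -> None:
    if law.A2 <= law.A_floor:
        raise ValueError(
            "closure options produce a buckling knee that collapses below the "
            f"area floor (A2={law.A2:.3e} <= A_floor={law.A_floor:.3e})"
        )
    if law.C_knee < law.C_pre:
        raise ValueError("knee compliance below hoop compliance: non-monotone setup")
    # dense numeric monotonicity check over the working range
    p = np.linspace(law.pressure(law.A_floor), 5.0 * abs(law.P_b) + 100.0, 512)
    a = law.area(p)
    if np.any(np.diff(a) < -1e-15):
        raise ValueError("closure options produce a non-monotone tube law")


def area_at_pressure(law: TubeLawModel, P_tm: float) -> float:
    """Area (m²) at transmural pressure, clipped at the law's area floor.

    Clipping is silent; use ``law.clipped_at(P_tm)`` to detect it.
    """
    return max(float(law.area(P_tm)), law.A_floor)


def pressure_at_area(law: TubeLawModel, A: float) -> float:
    """Transmural pressure (Pa) at a given area; inverse of the closure."""
    return float(law.pressure(A))


def compliance_at(law: TubeLawModel, P_tm: float) -> float:
    """Analytic compliance dA/dP (m²/Pa) at transmural pressure.

    Raises
    ------
    UndefinedComplianceError
        If the law is clipped at the area floor at this pressure.
    """
    if law.area(P_tm) <= law.A_floor:
        raise UndefinedComplianceError(
            f"compliance undefined at P_tm={P_tm:.1f} Pa: area clipped at floor"
        )
    return float(law.compliance(P_tm))


def wave_speed(A: float, C: float, fluid: FluidProperties = AIR) -> float:
    """Elastic-tube wave speed c = sqrt(A/(rho*C)), m/s.

    ``A`` is the local area (m²) and ``C = dA/dP`` the local compliance
    (m²/Pa).  Flow chokes when the mean velocity Q/A reaches c.
    """
    if not (A > 0 and C > 0):
        raise ValueError("wave speed requires A > 0 and C > 0")
    return math.sqrt(A / (fluid.rho * C))


def wsfl_vimax(A: float, C: float, fluid: FluidProperties = AIR) -> float:
    """Wave-speed flow limit A^{3/2}·(rho·C)^{−1/2} = A·c, m³/s."""
    return A * wave_speed(A, C, fluid)


def fit_compliance(
    P: Sequence[float],
    A: Sequence[float],
    at_P: float,
    window: float,
) -> float:
    """Local least-squares slope dA/dP of sampled (P, A) pairs near ``at_P``.

    Uses all samples with |P − at_P| <= window; requires at least three
    distinct pressures inside the window.
    """
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    if P.shape != A.shape:
        raise ValueError("P and A must have the same shape")
    sel = np.abs(P - at_P) <= window
    if sel.sum() < 3 or np.unique(P[sel]).size < 3:
        raise EstimationError(
            f"need >= 3 samples with distinct pressures within "
            f"{window:g} Pa of {at_P:g} Pa, found {int(sel.sum())}"
        )
    slope = np.polyfit(P[sel], A[sel], 1)[0]
    return float(slope)


def fit_tube_law(
    P: Sequence[float],
    A: Sequence[float],
    *,
    n_collapse: float = 1.5,
    A_floor: Optional[float] = None,
    initial: Optional[TubeLawModel] = None,
) -> TubeLawModel:
    """Calibrate a tube law (K_lin, P_b, C_knee) to sampled (P, A) data.

    Least-squares fit of the closure's relative area prediction; the rest
    area A0 is taken as the fitted area at zero pressure.  Useful when the
    (P, A) relation comes from measurements or a 3D simulation rather than
    from shell-scale formulas.
    """
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    if P.size < 5:
        raise EstimationError("tube-law calibration needs at least 5 samples")
    order = np.argsort(P)
    P, A = P[order], A[order]

    A0_guess = float(np.interp(0.0, P, A)) if P.min() < 0 < P.max() else float(A.max())
    if initial is not None:
        x0 = [initial.K_lin, -initial.P_b, initial.C_knee]
    else:
        x0 = [A0_guess / max(fit_compliance(P, A, P.max(), np.ptp(P)), 1e-12) / 4,
              max(abs(P.min()) / 3.0, 10.0),
              (A.max() - A.min()) / max(np.ptp(P), 1.0)]

    floor = A_floor if A_floor is not None else max(A.min() * 0.1, 1e-8)

    def build(x):
        K_lin, negPb, C_knee = x
        return TubeLawModel(
            A0=A0_guess, K_lin=K_lin, P_b=-negPb, n_collapse=n_collapse,
            A_floor=floor, delta=max(0.1 * negPb, 1.0), C_knee=C_knee,
        )

    def resid(x):
        law = build(np.abs(x))
        if law.A2 <= 0:
            return np.full(P.size, 1e3)
        return (law.area(P) - A) / A0_guess

    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    law = build(np.abs(sol.x))
    _validate_law(law)
    return law


# imported late to avoid a cycle in type checking
from .material import ElasticMaterial  # noqa: E402  (re-export for annotations)
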