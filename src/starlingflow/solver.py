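"""Quasi-1D, quasi-steady Starling-resistor flow solver.

The airway is a series circuit: a rigid upstream (nasal) segment with
linear resistance R_up (optionally a quadratic loss k2_up), a short
collapsible segment obeying a tube law, and a rigid downstream (tracheal)
segment with linear resistance R_down.  In the collapsible segment the
flow is frictionless and the energy (Bernoulli) equation holds at every
axial station i:

    P_i = P_N − R_up·Q − k2_up·Q² − ½·rho·(Q/A_i)²,
    A_i = A(P_i − P_tissue)           (tube law)

For a given flow Q this fixes a station state; sweeping Q traces the
station pressure-flow relation, which folds back at a maximal flow.  At
the fold the local velocity Q/A equals the tube wave speed
c = sqrt(A/(rho·dA/dP)) exactly (the saddle-node of the implicit solution
IS the wave-speed choking criterion), so states on the fold are
flow-limited: demanding a lower outlet pressure than the fold can deliver
leaves the flow and every upstream pressure unchanged (waterfall
behavior).

Because the model is quasi-steady (no inertial terms; justified by the
tiny Strouhal number of breathing), the pressure-flow curve produced by a
time-varying outlet-pressure ramp is independent of the ramp shape by
construction — each instant simply samples the steady curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .breathing import BreathingProfile, outlet_pressure
from .tubelaw import AIR, FluidProperties, TubeLawModel
from .units import m3s_to_lmin

logger = logging.getLogger(__name__)

#: Tolerance on flow at the limitation fold, m³/s.
Q_TOL = 1e-9


class SolverError(RuntimeError):
    """Raised when the steady solver fails to converge."""


@dataclass(frozen=True)
class AirwayModel:
    """Upstream resistance + collapsible segment + tissue pressure + fluid.

    Parameters
    ----------
    law : TubeLawModel
        Area-pressure closure of the collapsible segment.
    fluid : FluidProperties
        Air density/viscosity.
    R_up : float
        Linear upstream (nasal) resistance, Pa·s/m³.
    k2_up : float
        Quadratic upstream loss coefficient, Pa·s²/m⁶ (default 0).
    R_down : float
        Linear downstream (tracheal) resistance, Pa·s/m³ (default small).
    P_tissue : float
        External/tissue pressure on the collapsible wall, Pa gauge.
    P_N : float
        Nostril pressure, Pa gauge (atmosphere = 0; CPAP raises it).
    n_stations : int
        Number of axial stations in the collapsible segment (>= 3).
    viscous_loss : bool
        Include a per-station Poiseuille loss inside the segment
        (default off; the Bernoulli term dominates at choke for a 20 mm
        segment).
    """

    law: TubeLawModel
    fluid: FluidProperties = AIR
    R_up: float = 0.07e6
    k2_up: float = 0.0
    R_down: float = 1e4
    P_tissue: float = 0.0
    P_N: float = 0.0
    n_stations: int = 21
    viscous_loss: bool = False

    def __post_init__(self) -> None:
        if self.R_up < 0 or self.R_down < 0 or self.k2_up < 0:
            raise ValueError("resistances and loss coefficients must be >= 0")
        if self.n_stations < 3:
            raise ValueError("n_stations must be >= 3")


@dataclass(frozen=True)
class FlowState:
    """A steady flow solution.

    ``limited`` marks states on the flow-limitation fold, where
    Q/A_choke equals the wave speed at the choke station.
    """

    Q: float
    P_stations: np.ndarray
    A_stations: np.ndarray
    limited: bool
    choke_index: Optional[int]
    A_choke: float
    C_choke: float
    clipped: bool = False

    @property
    def A_min(self) -> float:
        return float(np.min(self.A_stations))


@dataclass
class SimulationTrace:
    """Time series of a simulated inspiratory ramp."""

    times: np.ndarray
    p_out: np.ndarray
    flows: np.ndarray
    a_min: np.ndarray
    limited: np.ndarray
    station_pressures: np.ndarray  # (n_times, n_stations)
    choke_index: np.ndarray
    stop_reason: str  # "completed" | "wall_contact"
    model: Optional[AirwayModel] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("p_out", "flows", "a_min", "limited", "choke_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace series {name!r} length mismatch")
        if self.station_pressures.shape[0] != n:
            raise ValueError("station pressure table length mismatch")

    def to_frame(self) -> pd.DataFrame:
        """Tidy trace table: t_s, p_out_pa, q_m3s, q_lmin, a_min_m2, limited."""
        return pd.DataFrame(
            {
                "t_s": self.times,
                "p_out_pa": self.p_out,
                "q_m3s": self.flows,
                "q_lmin": [m3s_to_lmin(q) for q in self.flows],
                "a_min_m2": self.a_min,
                "limited": self.limited.astype(bool),
            }
        )

    def station_frame(self) -> pd.DataFrame:
        """Wide station-pressure table: t_s, p_st_00 ... p_st_NN (Pa)."""
        cols = {
            f"p_st_{i:02d}": self.station_pressures[:, i]
            for i in range(self.station_pressures.shape[1])
        }
        return pd.DataFrame({"t_s": self.times, **cols})


# ---------------------------------------------------------------------------
# per-model workspace: the station pressure-flow curve Q_req(A)
# ---------------------------------------------------------------------------

_N_GRID = 4096


@dataclass(frozen=True)
class _Workspace:
    A_grid: np.ndarray
    Q_grid: np.ndarray
    A_hi: float
    A_peak: float
    Q_peak: float
    # monotone (subcritical) branch arrays, ascending in A
    A_branch: np.ndarray
    Q_branch: np.ndarray
    phi_branch: np.ndarray  # achievable outlet pressure on the branch


def _q_required(model: AirwayModel, A) -> np.ndarray:
    """Flow that puts a station at area A (station energy balance).

    Solves (½rho/A² + k2)·Q² + R_up·Q = P_N − P_lum(A) for Q >= 0, where
    P_lum(A) = P_tissue + P_tm(A).
    """
    A = np.asarray(A, dtype=float)
    law = model.law
    P_lum = model.P_tissue + law.pressure(A)
    drive = np.maximum(model.P_N - P_lum, 0.0)
    a2 = 0.5 * model.fluid.rho / A**2 + model.k2_up
    disc = model.R_up**2 + 4.0 * a2 * drive
    return (-model.R_up + np.sqrt(disc)) / (2.0 * a2)


@lru_cache(maxsize=64)
def _workspace(model: AirwayModel) -> _Workspace:
    law = model.law
    A_hi = float(law.area(model.P_N - model.P_tissue))
    if A_hi <= law.A_floor:
        raise SolverError(
            "airway closed at rest: tissue pressure collapses the segment "
            "below the area floor before any flow is demanded"
        )
    A_grid = np.linspace(law.A_floor, A_hi, _N_GRID)
    Q_grid = _q_required(model, A_grid)
    i_star = int(np.argmax(Q_grid))
    lo = A_grid[max(i_star - 1, 0)]
    hi = A_grid[min(i_star + 1, _N_GRID - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda a: -float(_q_required(model, a)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-14},
        )
        A_peak, Q_peak = float(res.x), float(-res.fun)
    else:  # peak at a grid boundary
        A_peak, Q_peak = float(A_grid[i_star]), float(Q_grid[i_star])
    if Q_grid[-1] > Q_peak:  # monotone curve (e.g. rigid limit): no fold
        A_peak, Q_peak = A_hi, float(Q_grid[-1])

    branch = A_grid >= A_peak
    A_branch = np.concatenate(([A_peak], A_grid[branch]))
    Q_branch = np.concatenate(([Q_peak], Q_grid[branch]))
    # enforce strict monotonicity for interpolation (dedupe)
    keep = np.concatenate(([True], np.diff(A_branch) > 0))
    A_branch, Q_branch = A_branch[keep], Q_branch[keep]
    P_lum_branch = model.P_tissue + law.pressure(A_branch)
    phi_branch = P_lum_branch - model.R_down * Q_branch
    return _Workspace(
        A_grid=A_grid, Q_grid=Q_grid, A_hi=A_hi,
        A_peak=A_peak, Q_peak=Q_peak,
        A_branch=A_branch, Q_branch=Q_branch, phi_branch=phi_branch,
    )


def _state_at_area(model: AirwayModel, A: float, limited: bool) -> FlowState:
    law = model.law
    Q = float(_q_required(model, A))
    P_tm = float(law.pressure(A))
    P_lum = model.P_tissue + P_tm
    n = model.n_stations
    clipped = A <= law.A_floor * (1.0 + 1e-6)
    C = float(law.compliance(P_tm))
    return FlowState(
        Q=Q,
        P_stations=np.full(n, P_lum),
        A_stations=np.full(n, A),
        limited=limited,
        choke_index=n - 1,
        A_choke=A,
        C_choke=C,
        clipped=clipped,
    )


def solve_steady(model: AirwayModel, P_out: float) -> FlowState:
    """Steady flow state for a demanded outlet (tracheal) pressure.

    Returns the consistent (Q, station pressures/areas) solution.  When no
    solution reaches the demanded P_out — the airway is flow-limited — the
    maximal-flow (fold) state is returned with ``limited=True``; the flow
    is then independent of further P_out decreases.

    Raises
    ------
    ValueError
        If P_out > P_N (expiratory demand is outside this model's scope).
    SolverError
        If the solver cannot converge.
    """
    if P_out > model.P_N:
        raise ValueError("solve_steady requires P_out <= P_N (inspiration)")
    if model.viscous_loss:
        return _solve_steady_viscous(model, P_out)
    ws = _workspace(model)
    phi_peak = ws.phi_branch[0]
    if P_out <= phi_peak:
        return _state_at_area(model, ws.A_peak, limited=True)
    # invert the monotone branch: phi increasing in A
    A0_guess = float(np.interp(P_out, ws.phi_branch, ws.A_branch))

    def g(a: float) -> float:
        return (
            model.P_tissue
            + float(model.law.pressure(a))
            - model.R_down * float(_q_required(model, a))
            - P_out
        )

    dA = (ws.A_hi - ws.A_peak) / _N_GRID
    lo = max(A0_guess - 2 * dA, ws.A_peak)
    hi = min(A0_guess + 2 * dA, ws.A_hi)
    try:
        if g(lo) * g(hi) <= 0:
            A_sol = brentq(g, lo, hi, xtol=1e-16)
        else:
            A_sol = brentq(g, ws.A_peak, ws.A_hi, xtol=1e-16)
    except ValueError as exc:  # pragma: no cover - diagnostics path
        raise SolverError(
            f"station solve failed to bracket at P_out={P_out:.1f} Pa"
        ) from exc
    limited = abs(A_sol - ws.A_peak) < 1e-12
    return _state_at_area(model, float(A_sol), limited=limited)


def max_flow(model: AirwayModel) -> tuple[float, FlowState]:
    """Peak inspiratory flow VImax and the limited (choked) state.

    VImax is the supremum of :func:`solve_steady` flow over all outlet
    pressures; the returned state sits on the limitation fold, where the
    local velocity equals the tube wave speed (to within ``Q_TOL``).
    """
    if model.viscous_loss:
        return _max_flow_viscous(model)
    ws = _workspace(model)
    state = _state_at_area(model, ws.A_peak, limited=True)
    return state.Q, state


def simulate_breathing(
    model: AirwayModel,
    profile: BreathingProfile,
    dt: float = 1e-3,
) -> SimulationTrace:
    """Quasi-steady time-marching of an inspiratory ramp.

    Each time step solves the steady problem at the instantaneous outlet
    pressure; the (P_out, Q) pairs define the pressure-flow curve.  The
    march stops early with ``stop_reason="wall_contact"`` if the minimum
    area reaches the tube-law floor (opposite walls at the residual gap).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    ts = np.arange(0.0, profile.duration + dt / 2.0, dt)
    ts[-1] = min(ts[-1], profile.duration)
    rows, p_outs, flows, a_mins, limiteds, chokes = [], [], [], [], [], []
    stop_reason = "completed"
    floor = model.law.A_floor
    for t in ts:
        p = float(outlet_pressure(profile, t))
        p = min(p, model.P_N)
        st = solve_steady(model, p)
        p_outs.append(p)
        flows.append(st.Q)
        a_mins.append(st.A_min)
        limiteds.append(st.limited)
        chokes.append(st.choke_index)
        rows.append(st.P_stations)
        if st.A_min <= floor * (1.0 + 1e-6):
            stop_reason = "wall_contact"
            break
    n = len(p_outs)
    if stop_reason == "wall_contact":
        logger.info("wall contact at t=%.3f s (A_min at floor)", ts[n - 1])
    if any(limiteds):
        onset = ts[int(np.argmax(limiteds))]
        logger.info(
            "flow limitation from t=%.3f s, choke station %d, stop=%s",
            onset, chokes[-1], stop_reason,
        )
    return SimulationTrace(
        times=ts[:n],
        p_out=np.asarray(p_outs),
        flows=np.asarray(flows),
        a_min=np.asarray(a_mins),
        limited=np.asarray(limiteds, dtype=bool),
        station_pressures=np.vstack(rows),
        choke_index=np.asarray(chokes),
        stop_reason=stop_reason,
        model=model,
    )


def classical_starling_vimax(P_N: float, P_tissue: float, R: float) -> float:
    """Classical Starling-resistor peak flow (P_N − P_tissue)/R, floored at 0.

    The textbook model: during flow limitation the peak flow depends only
    on the nostril-to-tissue pressure gradient and the upstream resistance.
    """
    if not R > 0:
        raise ValueError("upstream resistance must be positive")
    return max((P_N - P_tissue) / R, 0.0)


def rigid_reference_curve(model: AirwayModel, p_outs) -> np.ndarray:
    """Flows of the rigid-walled twin (area pinned at A0) at given outlet pressures.

    Closed form: (½rho/A0² + k2)·Q² + (R_up + R_down)·Q = P_N − P_out.
    """
    p = np.asarray(p_outs, dtype=float)
    A0 = model.law.A0
    a2 = 0.5 * model.fluid.rho / A0**2 + model.k2_up
    b = model.R_up + model.R_down
    drive = np.maximum(model.P_N - p, 0.0)
    return (-b + np.sqrt(b**2 + 4.0 * a2 * drive)) / (2.0 * a2)


# ---------------------------------------------------------------------------
# slow path: per-station march with Poiseuille losses (viscous_loss=True)
# ---------------------------------------------------------------------------

def _march(model: AirwayModel, Q: float):
    """March the stations downstream at flow Q; None when infeasible."""
    law = model.law
    dx = (law.geometry.length if law.geometry is not None else 0.02) / (
        model.n_stations - 1
    )
    mu = model.fluid.mu_air
    rho = model.fluid.rho
    P0 = model.P_N - model.R_up * Q - model.k2_up * Q**2
    visc = 0.0
    A_hi = float(law.area(model.P_N - model.P_tissue))
    A_grid = np.linspace(law.A_floor, A_hi, 1024)
    P_lum_grid = model.P_tissue + law.pressure(A_grid)
    A_st, P_st = [], []
    for _ in range(model.n_stations):
        rhs = P0 - visc
        f = P_lum_grid - rhs + 0.5 * rho * Q**2 / A_grid**2

        def fs(a: float) -> float:
            return (
                model.P_tissue + float(law.pressure(a)) - rhs
                + 0.5 * rho * Q**2 / a**2
            )

        idx = np.nonzero((f[:-1] <= 0) & (f[1:] >= 0))[0]
        if idx.size == 0:
            # near the fold f may dip below zero between grid nodes
            j = int(np.argmin(f))
            lo = A_grid[max(j - 1, 0)]
            hi = A_grid[min(j + 1, A_grid.size - 1)]
            res = minimize_scalar(fs, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-15})
            if res.fun > 0:
                return None
            a_lo, a_hi = float(res.x), hi
        else:
            j = idx[-1]
            a_lo, a_hi = A_grid[j], A_grid[j + 1]
        a_sol = brentq(fs, a_lo, a_hi, xtol=1e-16)
        A_st.append(a_sol)
        P_st.append(model.P_tissue + float(law.pressure(a_sol)))
        visc += 8.0 * math.pi * mu * dx * Q / a_sol**2
    return np.asarray(A_st), np.asarray(P_st)


def _max_flow_viscous(model: AirwayModel) -> tuple[float, FlowState]:
    lo, hi = 0.0, 1e-4
    while _march(model, hi) is not None:
        lo, hi = hi, hi * 2.0
        if hi > 1.0:  # pragma: no cover
            raise SolverError("no flow limitation found below 1 m³/s")
    while hi - lo > Q_TOL:
        mid = 0.5 * (lo + hi)
        if _march(model, mid) is not None:
            lo = mid
        else:
            hi = mid
    res = _march(model, lo)
    assert res is not None
    A_st, P_st = res
    i = int(np.flatnonzero(A_st == A_st.min())[-1])
    P_tm = P_st[i] - model.P_tissue
    return lo, FlowState(
        Q=lo, P_stations=P_st, A_stations=A_st, limited=True,
        choke_index=i, A_choke=float(A_st[i]),
        C_choke=float(model.law.compliance(P_tm)),
        clipped=bool(A_st.min() <= model.law.A_floor * (1 + 1e-9)),
    )


def _solve_steady_viscous(model: AirwayModel, P_out: float) -> FlowState:
    q_lim, lim_state = _max_flow_viscous(model)

    def g(q: float) -> float:
        res = _march(model, q)
        assert res is not None
        _, P_st = res
        return P_st[-1] - model.R_down * q - P_out

    if g(q_lim) > 0:
        return lim_state
    q = brentq(g, 0.0, q_lim, xtol=Q_TOL)
    res = _march(model, q)
    assert res is not None
    A_st, P_st = res
    i = int(np.flatnonzero(A_st == A_st.min())[-1])
    P_tm = P_st[i] - model.P_tissue
    return FlowState(
        Q=q, P_stations=P_st, A_stations=A_st,
        limited=abs(q - q_lim) <= 2 * Q_TOL, choke_index=i,
        A_choke=float(A_st[i]), C_choke=float(model.law.compliance(P_tm)),
    )
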