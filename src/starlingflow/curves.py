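"""Metrics defined on pressure-flow data.

A pressure-flow curve records inspiratory flow Q against downstream
(outlet) pressure P_out as effort increases.  The clinically meaningful
features extracted here:

* ``vimax_of`` — peak inspiratory flow VImax and the pressure at which it
  occurs (the plateau value once the airway is flow-limited);
* ``nasal_resistance`` — the initial slope of the curve, quantified as
  ΔP/Q at a reference transnasal drop (default 15 Pa);
* ``onset_pressure`` — P₁, the least-negative pressure at which the curve
  starts to deviate from its rigid-walled twin;
* ``ned_index`` — negative effort dependence, the fractional fall of flow
  below VImax at the most negative sampled pressure;
* ``waterfall_metric`` — how much the upstream station pressures move
  after flow limitation (wave-speed theory predicts: not at all);
* ``wsfl_agreement`` — percent difference between the simulated peak flow
  and the wave-speed formula A^{3/2}(rho·dA/dP)^{-1/2} at the choke state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .solver import AirwayModel, SimulationTrace, max_flow
from .tubelaw import wsfl_vimax


@dataclass
class PressureFlowCurve:
    """Ordered (P_out, Q) pairs, sorted by decreasing P_out.

    ``provenance`` tags the origin: "simulated", "measured" or "synthetic".
    """

    p_out: np.ndarray
    q: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        p = np.asarray(self.p_out, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if p.shape != q.shape or p.ndim != 1 or p.size < 1:
            raise ValueError("curve needs matching 1-D pressure and flow arrays")
        if np.unique(p).size != p.size:
            raise ValueError("P_out values must be distinct")
        if np.any(q < 0):
            raise ValueError("flows must be >= 0 (inspiratory positive)")
        order = np.argsort(-p)  # decreasing pressure (increasing effort)
        object.__setattr__(self, "p_out", p[order])
        object.__setattr__(self, "q", q[order])

    @classmethod
    def from_trace(cls, trace: SimulationTrace) -> "PressureFlowCurve":
        """Collapse a time trace onto its (P_out, Q) curve."""
        p, idx = np.unique(trace.p_out, return_index=True)
        return cls(p_out=p, q=trace.flows[idx], provenance="simulated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p_out_pa": self.p_out, "q_m3s": self.q})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "measured"):
        for col in ("p_out_pa", "q_m3s"):
            if col not in df.columns:
                raise ValueError(f"curve table missing required column {col!r}")
        return cls(
            p_out=df["p_out_pa"].to_numpy(),
            q=df["q_m3s"].to_numpy(),
            provenance=provenance,
        )

    def interp_q(self, p) -> np.ndarray:
        """Flow at given pressures by monotone linear interpolation."""
        p_asc = self.p_out[::-1]
        q_asc = self.q[::-1]
        return np.interp(np.asarray(p, dtype=float), p_asc, q_asc)


@dataclass
class CurveMetrics:
    """Derived scalar metrics of a pressure-flow curve (SI units)."""

    vimax: float
    p_at_vimax: float
    r_nasal: Optional[float] = None
    p1_onset: Optional[float] = None
    ned: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "vimax_m3s": self.vimax,
            "p_at_vimax_pa": self.p_at_vimax,
            "r_nasal_pa_s_m3": self.r_nasal,
            "p1_onset_pa": self.p1_onset,
            "ned": self.ned,
        }
        d.update(self.extras)
        return json.dumps(d, indent=2, sort_keys=True)


def vimax_of(curve: PressureFlowCurve) -> tuple[float, float]:
    """Peak flow and the outlet pressure at which it occurs.

    Ties resolve to the least-negative pressure (earliest attainment).
    The result is invariant to the input point order (curves sort
    internally by decreasing pressure).
    """
    if curve.q.size < 2:
        raise ValueError("vimax needs a curve with at least 2 points")
    i = int(np.argmax(curve.q))  # first occurrence = least-negative P_out
    return float(curve.q[i]), float(curve.p_out[i])


def nasal_resistance(curve: PressureFlowCurve, dP_ref: float = -15.0) -> float:
    """Upstream resistance ΔP/Q (Pa·s/m³) at a reference transnasal drop.

    Interpolates the flow at pharyngeal/outlet pressure ``dP_ref`` (default
    −15 Pa, i.e. a 15 Pa drop from atmospheric nostrils) and returns the
    secant resistance |dP_ref|/Q.  Early in inspiration the collapsible
    segment is effectively rigid, so this is the initial slope of the
    pressure-flow curve.
    """
    if dP_ref < curve.p_out.min() or dP_ref > curve.p_out.max():
        raise ValueError(
            f"reference drop {dP_ref} Pa outside curve span "
            f"[{curve.p_out.min():.1f}, {curve.p_out.max():.1f}] Pa"
        )
    q_ref = float(curve.interp_q(dP_ref))
    if q_ref <= 0:
        raise ValueError("zero flow at the reference drop; resistance undefined")
    return abs(dP_ref) / q_ref


def onset_pressure(
    curve: PressureFlowCurve,
    rigid_curve: PressureFlowCurve,
    rel_tol: float = 0.05,
) -> Optional[float]:
    """Deviation-onset pressure P₁.

    The least-negative outlet pressure at which the flow falls below the
    rigid-walled reference by more than ``rel_tol`` (relative deficit).
    Returns None when the curves never deviate.  Both curves are resampled
    onto their shared pressure range by monotone linear interpolation.
    """
    lo = max(curve.p_out.min(), rigid_curve.p_out.min())
    hi = min(curve.p_out.max(), rigid_curve.p_out.max())
    if hi <= lo:
        raise ValueError("curves share no pressure range")
    grid = np.linspace(hi, lo, 512)
    q = curve.interp_q(grid)
    q_r = rigid_curve.interp_q(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        deficit = np.where(q_r > 0, (q_r - q) / q_r, 0.0)
    dev = np.nonzero(deficit > rel_tol)[0]
    if dev.size == 0:
        return None
    return float(grid[dev[0]])


def ned_index(curve: PressureFlowCurve) -> float:
    """Negative effort dependence (VImax − Q_end)/VImax, floored at 0.

    Q_end is the flow at the most negative sampled pressure.  Zero for a
    plateau curve; positive when flow falls with increasing effort.
    """
    vimax, _ = vimax_of(curve)
    if vimax <= 0:
        raise ValueError("NED undefined for an all-zero curve")
    q_end = float(curve.q[-1])  # most negative pressure after sorting
    return max((vimax - q_end) / vimax, 0.0)


def waterfall_metric(
    trace: SimulationTrace, onset_time: Optional[float] = None
) -> float:
    """Maximum relative change of upstream-of-choke station pressures
    after flow limitation.

    Wave-speed theory predicts the upstream pressure profile freezes once
    flow is limited; this metric is that statement's residual (0 = frozen).
    ``onset_time`` defaults to the first limited instant in the trace.
    """
    lim = np.asarray(trace.limited, dtype=bool)
    if not lim.any():
        raise ValueError("trace contains no limited states")
    if onset_time is None:
        i0 = int(np.argmax(lim))
    else:
        i0 = int(np.searchsorted(trace.times, onset_time))
        if i0 >= len(trace.times) or not lim[i0:].any():
            raise ValueError("no limited states at or after onset_time")
        i0 += int(np.argmax(lim[i0:]))
    choke = int(trace.choke_index[i0])
    if choke == 0:
        return 0.0  # no stations upstream of the choke
    ref = trace.station_pressures[i0, :choke]
    later = trace.station_pressures[i0 + 1 :, :choke]
    if later.size == 0:
        return 0.0
    denom = np.maximum(np.abs(ref), 1e-12)
    return float(np.max(np.abs(later - ref[None, :]) / denom[None, :]))


def wsfl_agreement(model: AirwayModel) -> float:
    """Percent difference between simulated VImax and the wave-speed limit.

    Runs :func:`max_flow`, evaluates A^{3/2}(rho·dA/dP)^{-1/2} at the choke
    area and compliance of the limited state, and returns
    100·|VImax − predicted| / VImax.
    """
    vimax, state = max_flow(model)
    predicted = wsfl_vimax(state.A_choke, state.C_choke, model.fluid)
    return 100.0 * abs(vimax - predicted) / vimax


def curve_metrics(
    curve: PressureFlowCurve,
    rigid_curve: Optional[PressureFlowCurve] = None,
    dP_ref: float = -15.0,
) -> CurveMetrics:
    """Bundle the scalar metrics of a curve into one record."""
    vimax, p_at = vimax_of(curve)
    try:
        r_nasal = nasal_resistance(curve, dP_ref)
    except ValueError:
        r_nasal = None
    p1 = (
        onset_pressure(curve, rigid_curve) if rigid_curve is not None else None
    )
    return CurveMetrics(
        vimax=vimax, p_at_vimax=p_at, r_nasal=r_nasal,
        p1_onset=p1, ned=ned_index(curve),
    )
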