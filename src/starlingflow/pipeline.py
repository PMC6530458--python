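"""Configuration, I/O and orchestration.

``RunConfig`` is the validated JSON-facing configuration (unknown keys are
rejected).  ``run_simulate`` produces trace/curve/metrics files for a
single model, ``run_sweep`` tabulates peak-flow and choke-state metrics
over a parameter sweep, and ``run_analyze`` recomputes curve metrics from
files on disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .breathing import BreathingProfile
from .curves import (
    PressureFlowCurve,
    curve_metrics,
    nasal_resistance,
    waterfall_metric,
    wsfl_agreement,
)
from .material import ElasticMaterial
from .solver import (
    AirwayModel,
    SimulationTrace,
    max_flow,
    simulate_breathing,
    solve_steady,
)
from .synthetic import SweepSpec
from .tubelaw import FluidProperties, TubeGeometry, make_tube_law, wsfl_vimax
from .units import CMH2O_PA, compliance_si_to_cm2cmh2o, m3s_to_lmin

logger = logging.getLogger(__name__)


class MaterialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    E_pa: float = 15e3
    nu: float = 0.48
    density_kg_m3: float = 1080.0


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    A0_m2: float = 1.18e-4
    h_m: float = 2e-3
    length_m: float = 0.020


class FluidConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rho_kg_m3: float = 1.2
    mu_pa_s: float = 1.81e-5


class ProfileConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "linear"
    amplitude_pa: float = -600.0
    duration_s: float = 1.0


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt_s: float = Field(default=1e-3, gt=0)
    n_stations: int = Field(default=21, ge=3)
    viscous_loss: bool = False


class TubeLawConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_b: float = 3.0
    n_collapse: float = 1.5
    knee_frac: float = 0.1
    contact_gap_m: float = 0.5e-3


class RunConfig(BaseModel):
    """Validated configuration of a single simulation run."""

    model_config = ConfigDict(extra="forbid")

    material: MaterialConfig = Field(default_factory=MaterialConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    profile: ProfileConfig = Field(default_factory=ProfileConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    tube_law: TubeLawConfig = Field(default_factory=TubeLawConfig)
    R_up_pa_s_m3: float = 0.07e6
    k2_up_pa_s2_m6: float = 0.0
    R_down_pa_s_m3: float = 1e4
    P_tissue_pa: float = 0.0
    P_N_pa: float = 0.0
    seed: int = 0

    def build_model(self) -> AirwayModel:
        geom = TubeGeometry(
            A0=self.geometry.A0_m2, h=self.geometry.h_m,
            length=self.geometry.length_m,
        )
        mat = ElasticMaterial(
            E=self.material.E_pa, nu=self.material.nu,
            density=self.material.density_kg_m3,
        )
        law = make_tube_law(
            geom, mat,
            k_b=self.tube_law.k_b,
            n_collapse=self.tube_law.n_collapse,
            knee_frac=self.tube_law.knee_frac,
            contact_gap=self.tube_law.contact_gap_m,
        )
        return AirwayModel(
            law=law,
            fluid=FluidProperties(rho=self.fluid.rho_kg_m3,
                                  mu_air=self.fluid.mu_pa_s),
            R_up=self.R_up_pa_s_m3,
            k2_up=self.k2_up_pa_s2_m6,
            R_down=self.R_down_pa_s_m3,
            P_tissue=self.P_tissue_pa,
            P_N=self.P_N_pa,
            n_stations=self.solver.n_stations,
            viscous_loss=self.solver.viscous_loss,
        )

    def build_profile(self) -> BreathingProfile:
        return BreathingProfile(
            kind=self.profile.kind,
            amplitude=self.profile.amplitude_pa,
            duration=self.profile.duration_s,
        )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON config file."""
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)


def run_simulate(config: RunConfig, out_dir: str | Path) -> SimulationTrace:
    """Simulate one inspiratory ramp and write trace/curve/metrics files.

    Writes ``trace.csv``, ``stations.csv``, ``curve.csv``, ``metrics.json``
    and a ``config.json`` sidecar into ``out_dir``.  The model and profile
    are validated (and the outputs dir untouched) before anything runs.
    """
    model = config.build_model()
    profile = config.build_profile()
    trace = simulate_breathing(model, profile, dt=config.solver.dt_s)
    curve = PressureFlowCurve.from_trace(trace)
    metrics = curve_metrics(curve)
    if trace.limited.any():
        metrics.extras["waterfall_metric"] = waterfall_metric(trace)
    metrics.extras["stop_reason"] = trace.stop_reason
    metrics.extras["limited"] = bool(trace.limited.any())

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(out / "trace.csv", index=False)
    trace.station_frame().to_csv(out / "stations.csv", index=False)
    curve.to_frame().to_csv(out / "curve.csv", index=False)
    (out / "metrics.json").write_text(metrics.to_json())
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    logger.info(
        "run complete: stop=%s limited=%s vimax=%.1f L/min",
        trace.stop_reason, bool(trace.limited.any()),
        m3s_to_lmin(metrics.vimax),
    )
    return trace


#: Exact sweep-table column names (units in headers).
SWEEP_COLUMNS = (
    "config",
    "VImax (L/min)",
    "C_choke (cm²/cmH₂O)",
    "A_choke (cm²)",
    "wsfl_vimax (L/min)",
    "agreement (%)",
    "R_nasal (Pa·s/mL)",
)


def run_sweep(
    spec: SweepSpec,
    out_path: Optional[str | Path] = None,
    **model_kwargs,
) -> pd.DataFrame:
    """Peak-flow/choke-state table over a parameter sweep (tidy long format).

    One row per configuration; per-row failures are recorded in an
    ``error`` column and the sweep continues.
    """
    rows = []
    for cfg, model in spec.models(**model_kwargs):
        row: dict = {"config": cfg.label, "error": ""}
        try:
            vimax, state = max_flow(model)
            predicted = wsfl_vimax(state.A_choke, state.C_choke, model.fluid)
            # nasal resistance at a 15 Pa nostril-to-pharynx drop, with
            # pharyngeal pressure taken at the choke plane
            p_grid = np.linspace(0.0, -30.0, 31)
            states = [solve_steady(model, p) for p in p_grid]
            p_phar = np.array([s.P_stations[s.choke_index] for s in states])
            q_grid = np.array([s.Q for s in states])
            curve = PressureFlowCurve(p_out=p_phar, q=q_grid)
            r_nasal = nasal_resistance(curve, dP_ref=-15.0)
            row.update(
                {
                    "VImax (L/min)": m3s_to_lmin(vimax),
                    "C_choke (cm²/cmH₂O)": compliance_si_to_cm2cmh2o(
                        state.C_choke
                    ),
                    "A_choke (cm²)": state.A_choke * 1e4,
                    "wsfl_vimax (L/min)": m3s_to_lmin(predicted),
                    "agreement (%)": 100.0 * abs(vimax - predicted) / vimax,
                    "R_nasal (Pa·s/mL)": r_nasal / 1e6,
                }
            )
        except Exception as exc:  # per-row failure: record and continue
            row["error"] = str(exc)
            logger.warning("sweep row %s failed: %s", cfg.label, exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in SWEEP_COLUMNS if c in df.columns] + ["error"]
    df = df[cols]
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


def read_curve(path: str | Path, units: str = "si") -> PressureFlowCurve:
    """Read a pressure-flow curve CSV.

    ``units="si"`` expects columns p_out_pa, q_m3s; ``units="clinical"``
    expects p_out_cmh2o, q_lmin.
    """
    df = pd.read_csv(path)
    if units == "si":
        need = ("p_out_pa", "q_m3s")
    elif units == "clinical":
        need = ("p_out_cmh2o", "q_lmin")
    else:
        raise ValueError("units must be 'si' or 'clinical'")
    for col in need:
        if col not in df.columns:
            raise ValueError(
                f"curve file {path} missing required column {col!r} "
                f"for units={units!r}"
            )
    if units == "clinical":
        df = pd.DataFrame(
            {
                "p_out_pa": df["p_out_cmh2o"] * CMH2O_PA,
                "q_m3s": df["q_lmin"] / 60000.0,
            }
        )
    return PressureFlowCurve.from_frame(df)


def run_analyze(
    curve_path: str | Path,
    stations_path: Optional[str | Path] = None,
    trace_path: Optional[str | Path] = None,
    units: str = "si",
    out_path: Optional[str | Path] = None,
) -> dict:
    """Recompute curve metrics (and the waterfall metric when a station
    table plus trace are available) from files on disk."""
    curve = read_curve(curve_path, units=units)
    metrics = curve_metrics(curve)
    result = json.loads(metrics.to_json())
    if stations_path is not None and trace_path is not None:
        tdf = pd.read_csv(trace_path)
        sdf = pd.read_csv(stations_path)
        for col in ("t_s", "p_out_pa", "q_m3s", "a_min_m2", "limited"):
            if col not in tdf.columns:
                raise ValueError(f"trace file missing required column {col!r}")
        st_cols = [c for c in sdf.columns if c.startswith("p_st_")]
        if not st_cols:
            raise ValueError("stations file has no p_st_* columns")
        trace = SimulationTrace(
            times=tdf["t_s"].to_numpy(),
            p_out=tdf["p_out_pa"].to_numpy(),
            flows=tdf["q_m3s"].to_numpy(),
            a_min=tdf["a_min_m2"].to_numpy(),
            limited=tdf["limited"].to_numpy(dtype=bool),
            station_pressures=sdf[st_cols].to_numpy(),
            choke_index=np.full(len(tdf), len(st_cols) - 1),
            stop_reason="completed",
        )
        if trace.limited.any():
            result["waterfall_metric"] = waterfall_metric(trace)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, indent=2, sort_keys=True))
    return result
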