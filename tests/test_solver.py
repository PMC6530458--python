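"""Steady Starling-resistor solver: folds, choking, waterfall, limits."""

import numpy as np
import pytest

from starlingflow import (
    AirwayModel,
    BreathingProfile,
    ElasticMaterial,
    PressureFlowCurve,
    TubeGeometry,
    classical_starling_vimax,
    make_tube_law,
    max_flow,
    rigid_reference_curve,
    simulate_breathing,
    solve_steady,
    wave_speed,
)

from conftest import grid_law, grid_models


def brute_force_max_flow(model, n_q=400, q_hi=None, damping=0.5):
    """Independent oracle: dense Q scan with damped fixed-point station
    iteration; returns (sup feasible Q, grid step)."""
    law = model.law
    if q_hi is None:
        q_hi = 2.0 * max_flow(model)[0]
    feasible = 0.0
    for Q in np.linspace(0.0, q_hi, n_q):
        P0 = model.P_N - model.R_up * Q - model.k2_up * Q**2
        P = P0
        for _ in range(500):
            A = max(float(law.area(P - model.P_tissue)), law.A_floor)
            P_new = P0 - 0.5 * model.fluid.rho * (Q / A) ** 2
            P_new = damping * P + (1 - damping) * P_new
            if abs(P_new - P) < 1e-10:
                P = P_new
                break
            P = P_new
        A = max(float(law.area(P - model.P_tissue)), law.A_floor)
        if A <= law.A_floor * 1.0001:
            break
        c = wave_speed(A, float(law.compliance(P - model.P_tissue)), model.fluid)
        if Q / A > c:
            break
        feasible = Q
    return feasible, q_hi / (n_q - 1)


class TestClassicalEquation:
    def test_arithmetic(self):
        assert classical_starling_vimax(500.0, 200.0, 1e5) == pytest.approx(3e-3)

    def test_zero_gradient(self):
        assert classical_starling_vimax(200.0, 200.0, 1e5) == 0.0

    def test_negative_gradient_floored(self):
        assert classical_starling_vimax(100.0, 200.0, 1e5) == 0.0

    def test_linearity(self):
        v1 = classical_starling_vimax(400.0, 100.0, 2e5)
        v2 = classical_starling_vimax(700.0, 100.0, 2e5)
        assert v2 == pytest.approx(2 * v1)

    @pytest.mark.parametrize("R", [0.0, -1e5])
    def test_resistance_domain(self, R):
        with pytest.raises(ValueError):
            classical_starling_vimax(500.0, 0.0, R)


class TestSteadySolve:
    def test_rigid_limit_is_series_resistor(self):
        """With a near-rigid, wide tube the solver reduces to the linear
        resistor chain Q = (P_N − P_out)/(R_up + R_down)."""
        law = make_tube_law(TubeGeometry(A0=1e-2, h=2e-3), ElasticMaterial(E=1e9))
        m = AirwayModel(law=law, R_up=1e5, R_down=1e4)
        st = solve_steady(m, -300.0)
        assert not st.limited
        assert st.Q == pytest.approx(300.0 / 1.1e5, rel=1e-3)

    def test_precondition(self, default_model):
        with pytest.raises(ValueError):
            solve_steady(default_model, default_model.P_N + 10.0)

    def test_flow_conserved_across_stations(self, default_model):
        st = solve_steady(default_model, -100.0)
        assert st.A_stations.shape == (default_model.n_stations,)
        assert st.P_stations.shape == (default_model.n_stations,)
        # single-Q formulation: every station carries the same flow by
        # construction; the state arrays must be mutually consistent
        assert np.all(st.A_stations > 0)
        assert np.all(np.diff(st.P_stations) <= 1e-12)

    def test_limited_flag_and_plateau(self, default_model):
        vimax, lim = max_flow(default_model)
        p_lim = lim.P_stations[0] - default_model.R_down * vimax
        st1 = solve_steady(default_model, p_lim - 50.0)
        st2 = solve_steady(default_model, p_lim - 300.0)
        assert st1.limited and st2.limited
        assert st1.Q == pytest.approx(st2.Q, abs=1e-9)
        assert st1.Q == pytest.approx(vimax, rel=1e-9)

    def test_waterfall_upstream_pressures_frozen(self, default_model):
        vimax, lim = max_flow(default_model)
        p_lim = lim.P_stations[0] - default_model.R_down * vimax
        st1 = solve_steady(default_model, p_lim - 10.0)
        st2 = solve_steady(default_model, p_lim - 400.0)
        up = slice(0, st1.choke_index)
        rel = np.abs(st2.P_stations[up] - st1.P_stations[up]) / np.abs(
            st1.P_stations[up]
        )
        assert np.max(rel) < 0.01

    @pytest.mark.parametrize("model", grid_models(), ids=lambda m: f"E{m.law.material.E:.0f}_h{m.law.geometry.h * 1e3:.0f}")
    def test_limited_states_choke_at_wave_speed(self, model):
        """At the flow-limitation fold the local velocity equals the
        elastic-tube wave speed (saddle-node <=> wave-speed criterion)."""
        vimax, st = max_flow(model)
        u = vimax / st.A_choke
        c = wave_speed(st.A_choke, st.C_choke, model.fluid)
        assert u == pytest.approx(c, rel=0.02)

    def test_oracle_equivalence_on_random_models(self):
        """Solver max_flow agrees with a brute-force Q-grid scan (damped
        fixed-point per station) within one grid step on 20 seeded models."""
        rng = np.random.default_rng(1234)
        for _ in range(20):
            law = grid_law(
                h=rng.uniform(2e-3, 8e-3), E=rng.uniform(2e3, 30e3)
            )
            model = AirwayModel(
                law=law, R_up=float(rng.choice([0.07e6, 0.12e6]))
            )
            vimax, _ = max_flow(model)
            oracle, step = brute_force_max_flow(model)
            assert abs(vimax - oracle) <= step


class TestDirections:
    def test_vimax_increases_with_modulus(self, geometry):
        v15 = max_flow(AirwayModel(law=make_tube_law(geometry, ElasticMaterial(E=15e3))))[0]
        v30 = max_flow(AirwayModel(law=make_tube_law(geometry, ElasticMaterial(E=30e3))))[0]
        assert v30 > v15

    def test_vimax_decreases_with_nasal_resistance(self, stiff_law):
        v_open = max_flow(AirwayModel(law=stiff_law, R_up=0.07e6))[0]
        v_blocked = max_flow(AirwayModel(law=stiff_law, R_up=0.12e6))[0]
        assert v_blocked < v_open

    def test_viscous_losses_reduce_peak_flow(self, soft_law):
        v0 = max_flow(AirwayModel(law=soft_law))[0]
        vv, st = max_flow(AirwayModel(law=soft_law, viscous_loss=True))
        assert vv < v0
        # with friction on, pressure falls strictly station to station
        assert np.all(np.diff(st.P_stations) < 0)


class TestClassicalRecovery:
    def test_vimax_linear_in_nasal_pressure(self, soft_law):
        """In the classical regime (upstream resistance dominating the
        tube's Bernoulli impedance) VImax rises linearly with nasal
        pressure with slope 1/R_up."""
        R_up = 4e6
        p_ns = np.linspace(1500.0, 4000.0, 6)
        vs = []
        for p_n in p_ns:
            m = AirwayModel(
                law=soft_law, R_up=R_up, P_tissue=300.0, P_N=p_n
            )
            vs.append(max_flow(m)[0])
        slope, _ = np.polyfit(p_ns, vs, 1)
        assert slope == pytest.approx(1.0 / R_up, rel=0.05)
        # linearity: residuals of the linear fit are small
        fit = np.polyval(np.polyfit(p_ns, vs, 1), p_ns)
        assert np.max(np.abs(fit - vs)) / np.max(vs) < 0.01


class TestBreathingSimulation:
    def test_profile_independence(self):
        """Linear, sinusoidal and exponential drivers give the same
        pressure-flow curve to within 0.1% flow at matched pressures."""
        model = AirwayModel(law=grid_law(8e-3, 2e3))
        curves = {}
        for kind in ("linear", "sinusoidal", "exponential"):
            tr = simulate_breathing(
                model, BreathingProfile(kind=kind), dt=2e-3
            )
            curves[kind] = PressureFlowCurve.from_trace(tr)
        grid = np.linspace(-20.0, -580.0, 100)
        q_lin = curves["linear"].interp_q(grid)
        for kind in ("sinusoidal", "exponential"):
            q = curves[kind].interp_q(grid)
            assert np.max(np.abs(q - q_lin) / q_lin) < 1e-3

    def test_dt_refinement_invariance(self, default_model):
        tr1 = simulate_breathing(default_model, BreathingProfile(), dt=4e-3)
        tr2 = simulate_breathing(default_model, BreathingProfile(), dt=2e-3)
        grid = np.linspace(-20.0, -580.0, 80)
        q1 = PressureFlowCurve.from_trace(tr1).interp_q(grid)
        q2 = PressureFlowCurve.from_trace(tr2).interp_q(grid)
        assert np.max(np.abs(q1 - q2) / q1) < 1e-3

    def test_limitation_within_default_ramp(self, default_model):
        tr = simulate_breathing(default_model, BreathingProfile(), dt=2e-3)
        assert tr.stop_reason == "completed"
        assert tr.limited.any()
        # after limitation the flow plateaus
        qs = tr.flows[tr.limited]
        assert np.ptp(qs) <= 1e-9

    def test_wall_contact_stop(self, soft_law):
        """A highly resistive nose starves the segment: the area collapses
        to the contact floor and the march stops early."""
        m = AirwayModel(law=soft_law, R_up=3e6)
        tr = simulate_breathing(m, BreathingProfile(amplitude=-2000.0), dt=2e-3)
        assert tr.stop_reason == "wall_contact"
        assert tr.a_min[-1] <= soft_law.A_floor * (1 + 1e-6)
        assert tr.times[-1] < 2.0

    def test_trace_determinism(self, default_model):
        tr1 = simulate_breathing(default_model, BreathingProfile(), dt=5e-3)
        tr2 = simulate_breathing(default_model, BreathingProfile(), dt=5e-3)
        assert np.array_equal(tr1.flows, tr2.flows)
        assert np.array_equal(tr1.station_pressures, tr2.station_pressures)

    def test_invalid_dt(self, default_model):
        with pytest.raises(ValueError):
            simulate_breathing(default_model, BreathingProfile(), dt=0.0)


class TestRigidReference:
    def test_compliant_curve_tracks_then_falls_below_rigid(self, default_model):
        tr = simulate_breathing(default_model, BreathingProfile(), dt=2e-3)
        curve = PressureFlowCurve.from_trace(tr)
        grid = np.linspace(-10.0, -580.0, 120)
        q_c = curve.interp_q(grid)
        q_r = rigid_reference_curve(default_model, grid)
        early = np.abs(grid) < 50.0
        late = np.abs(grid) > 520.0
        assert np.max(np.abs(q_c[early] - q_r[early]) / q_r[early]) < 0.02
        assert np.all(q_c[late] < q_r[late])
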