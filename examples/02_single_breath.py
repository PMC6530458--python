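"""Simulate one inspiratory effort and extract the pressure-flow metrics.

Drives a collapsible pharynx (h = 2 mm, E = 15 kPa) with the default
linear outlet-pressure ramp (0 to −600 Pa in 1 s) behind an open-nostril
nasal resistance, then reports peak flow, nasal resistance, the
deviation-onset pressure P1 and the negative-effort-dependence index.
"""

import numpy as np

from starlingflow import (
    AirwayModel,
    BreathingProfile,
    ElasticMaterial,
    PressureFlowCurve,
    TubeGeometry,
    make_tube_law,
    ned_index,
    nasal_resistance,
    onset_pressure,
    rigid_reference_curve,
    simulate_breathing,
    vimax_of,
)
from starlingflow.units import m3s_to_lmin

law = make_tube_law(TubeGeometry(A0=1.18e-4, h=2e-3), ElasticMaterial(E=15e3))
model = AirwayModel(law=law, R_up=0.07e6)

trace = simulate_breathing(model, BreathingProfile(kind="linear"), dt=1e-3)
curve = PressureFlowCurve.from_trace(trace)
rigid = PressureFlowCurve(
    p_out=curve.p_out, q=rigid_reference_curve(model, curve.p_out)
)

vimax, p_at = vimax_of(curve)
onset = trace.times[np.argmax(trace.limited)]
print(f"flow limited from t = {onset:.3f} s (outlet {trace.p_out[np.argmax(trace.limited)]:.0f} Pa)")
print(f"VImax          = {m3s_to_lmin(vimax):.1f} L/min at P_out = {p_at:.0f} Pa")
print(f"R_nasal(−15Pa) = {nasal_resistance(curve) / 1e6:.3f} Pa·s/mL")
print(f"P1 onset       = {onset_pressure(curve, rigid):.0f} Pa")
print(f"NED index      = {ned_index(curve):.2f}")
# VImax is the plateau flow; NED = 0 means the plateau is flat (no
# negative effort dependence in a quasi-steady Starling resistor).
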