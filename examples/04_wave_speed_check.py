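"""Verify the wave-speed flow-limitation criterion on a single model.

At the flow-limitation fold the local air speed Q/A equals the
elastic-tube wave speed sqrt(A/(rho*dA/dP)), so the simulated peak flow
matches the closed-form prediction A^{3/2}(rho*dA/dP)^{-1/2}.
"""

from starlingflow import (
    AirwayModel,
    ElasticMaterial,
    TubeGeometry,
    make_tube_law,
    max_flow,
    wave_speed,
    wsfl_vimax,
)
from starlingflow.units import m3s_to_lmin

law = make_tube_law(TubeGeometry(A0=1.18e-4, h=4e-3), ElasticMaterial(E=2e3))
model = AirwayModel(law=law, R_up=0.07e6)

vimax, state = max_flow(model)
u = vimax / state.A_choke
c = wave_speed(state.A_choke, state.C_choke, model.fluid)
predicted = wsfl_vimax(state.A_choke, state.C_choke, model.fluid)

print(f"VImax (simulated)        = {m3s_to_lmin(vimax):.2f} L/min")
print(f"VImax (wave-speed form)  = {m3s_to_lmin(predicted):.2f} L/min")
print(f"choke area               = {state.A_choke * 1e4:.3f} cm²")
print(f"local speed u = {u:.2f} m/s,  wave speed c = {c:.2f} m/s")
print(f"percent difference       = {100 * abs(vimax - predicted) / vimax:.4f} %")
# u = c at the choke: flow limitation IS wave-speed choking here.
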