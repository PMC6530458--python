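"""Build a pharyngeal tube law and inspect its compliance and wave speed.

The tube law A(P_tm) links transmural pressure to luminal area.  Its
slope (compliance) sets the elastic-tube wave speed c = sqrt(A/(rho*C)),
the quantity that caps the flow a collapsible segment can carry.
"""

from starlingflow import (
    ElasticMaterial,
    TubeGeometry,
    area_at_pressure,
    compliance_at,
    make_tube_law,
    wave_speed,
)
from starlingflow.units import compliance_si_to_cm2cmh2o

geometry = TubeGeometry(A0=1.18e-4, h=2e-3, length=0.020)
law = make_tube_law(geometry, ElasticMaterial(E=15e3, nu=0.48))

print(f"buckling pressure P_b = {law.P_b:.0f} Pa")
print(f"{'P_tm (Pa)':>10} {'A (cm²)':>9} {'C (cm²/cmH₂O)':>14} {'c (m/s)':>8}")
for p in (0.0, -200.0, law.P_b, law.P2 - 30.0, law.P2 - 100.0):
    a = area_at_pressure(law, p)
    c = compliance_at(law, p)
    print(
        f"{p:10.0f} {a * 1e4:9.3f} {compliance_si_to_cm2cmh2o(c):14.4f}"
        f" {wave_speed(a, c):8.2f}"
    )
# Above the buckling pressure the wall is stiff (hoop stretching) and the
# wave speed is high; past buckling the compliance jumps and the wave
# speed collapses — that is where inspiratory flow chokes.
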