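# starlingflow

A quasi-one-dimensional, quasi-steady **Starling-resistor simulator of
pharyngeal airflow limitation**, for researchers in respiratory
biomechanics and sleep medicine who want a desk-scale, fully scriptable
model of how the upper airway chokes during inspiration.

The pharynx in obstructive sleep apnea behaves like a collapsible tube
mounted between a rigid upstream segment (the nasal cavity, resistance
R_up) and a rigid downstream segment (the trachea).  `starlingflow`
couples three ingredients:

1. **A tube law** A(P_tm): a C¹, monotone area–transmural-pressure
   closure with a stiff hoop (pre-buckling) branch
   A = A₀(1 + P_tm/K_lin), K_lin = E·h/((1−ν²)R₀), a buckling knee near
   the ring-buckling pressure P_b ∝ −E(h/R₀)³, and a Shapiro-type
   similarity collapse branch P_tm ∝ −(A/A_b)^(−n).
2. **Station energy balance** (frictionless Bernoulli) at every axial
   station of the collapsible segment:
   P = P_N − R_up·Q − ½ρ(Q/A)², with A = A(P − P_tissue).
3. **Wave-speed choking**: solutions fold back at a maximal flow; at the
   fold the local velocity Q/A equals the elastic-tube wave speed
   c = √(A/(ρ·dA/dP)), so the peak inspiratory flow obeys

   **V̇Imax = A^{3/2} (ρ·dA/dP)^{−1/2}**

   evaluated at the choke point.  Beyond the fold, flow and all upstream
   pressures are independent of the downstream pressure (the "waterfall"
   of classical Starling-resistor physiology).

The package also ships the surrounding analysis pipeline: breathing
profile drivers (linear/sinusoidal/exponential ramps to −600 Pa),
pressure-flow curve metrics (V̇Imax, nasal resistance at a 15 Pa drop,
deviation-onset pressure P₁, negative-effort-dependence index), a
parameter-sweep driver, and synthetic-data generators (noisy tube-law
samples, experiment-style traces with valve-opening jitter).

## Worked example

```python
from starlingflow import (AirwayModel, ElasticMaterial, TubeGeometry,
                          make_tube_law, max_flow, wave_speed, wsfl_vimax)
from starlingflow.units import m3s_to_lmin

law = make_tube_law(TubeGeometry(A0=1.18e-4, h=4e-3), ElasticMaterial(E=2e3))
model = AirwayModel(law=law, R_up=0.07e6)   # open-nostril nasal resistance

vimax, state = max_flow(model)
print(m3s_to_lmin(vimax))                         # 121.39  (L/min)
print(state.A_choke * 1e4)                        # 0.835   (cm²)
print(vimax / state.A_choke)                      # 24.24   (m/s, local speed)
print(wave_speed(state.A_choke, state.C_choke))   # 24.24   (m/s, wave speed)
print(m3s_to_lmin(wsfl_vimax(state.A_choke, state.C_choke)))  # 121.39
```

A 4 mm-thick wall with a 2 kPa modulus behind an open nose carries at
most 121 L/min: the flow-limited (choked) state, where the air speed at
the collapse site has reached the tube's wave speed, so the simulated
peak flow and the wave-speed formula coincide.  Driving the model with
any of the three breathing profiles (`simulate_breathing`) traces the
same pressure-flow curve and plateaus at this V̇Imax.

The `examples/` directory holds one short narrative script per
capability (tube law, single breath, stiffness/thickness sweep,
wave-speed check, synthetic bench experiment); each prints the numbers
it computes and says what they mean.  A thin CLI mirrors the pipeline:

```bash
starlingflow simulate --out run/            # trace.csv, curve.csv, metrics.json
starlingflow sweep --out sweep.csv          # the default parameter grid
starlingflow analyze run/curve.csv          # metrics from files
starlingflow synth --kind tubelaw --out samples.csv --seed 7
```

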