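# Methods

## Model overview

`starlingflow` treats the upper airway as a series circuit: a rigid
upstream (nasal) segment with linear resistance `R_up` and optional
quadratic loss `k2_up`, a short collapsible pharyngeal segment described
by a tube law, and a rigid downstream (tracheal) segment with a small
linear resistance `R_down`.  All pressures are gauge (atmosphere = 0)
and inspiratory flow is positive.  The flow is **quasi-steady**: the
Strouhal number of breathing (St = fL/V ≈ 0.25 Hz × 1 cm / 2.5 m/s
= 10⁻³) is far below unity, so inertial/unsteady terms are dropped and
every instant of a breath is a steady state.  Two consequences follow
*by construction* and are verified by the test suite rather than
assumed silently: the pressure-flow curve is independent of the
breathing profile (any ramp merely samples the same steady curve), and
the time step of `simulate_breathing` only controls sampling density.

In the collapsible segment the energy (Bernoulli) equation holds at
each axial station i:

    P_i = P_N − R_up·Q − k2_up·Q² − ½ρ(Q/A_i)²,   A_i = A(P_i − P_tissue)

with a uniform rest area A₀ along the segment (the one-dimensional
surrogate for an anatomical segment).  An optional per-station
Poiseuille loss (`viscous_loss=True`) is available for sensitivity
studies; it is off by default because the Bernoulli term dominates over
a 20 mm segment at choking velocities.

## Tube law

The closure has three regimes, joined C¹:

* **Hoop branch** (P_tm > P_b + δ): A = A₀(1 + P_tm/K_lin) with areal
  stiffness K_lin = E·h/((1−ν²)·R₀), R₀ = √(A₀/π).  Compliance is the
  constant C_pre = A₀/K_lin.
* **Buckling knee** (|P_tm − P_b| ≤ δ): a circular section loses
  stability near the mode-2 ring-buckling pressure
  P_b = −k_b·E/(4(1−ν²))·(h/R₀)³ (k_b = 3 by default).  Across the
  knee the compliance ramps **linearly in pressure** from C_pre to the
  bending-scale value C_knee = A_b/(n·K_p), K_p = E·h³/(12(1−ν²)R₀³),
  so the law is C¹ even though the two asymptotic branches differ in
  stiffness by roughly R₀²/h².  The half-width is δ = 0.1·|P_b|
  (floored at 1 Pa).
* **Similarity collapse branch** (P_tm < P_b − δ): the buckled section
  follows P_tm = P₂ − K_eff·((A/A₂)^(−n) − 1) with exponent n = 1.5 and
  K_eff = A₂/(n·C_knee) anchored so compliance is continuous at the
  knee exit (A₂, P₂).

Two regularizations keep the closure valid over the whole parameter
range:

* **Thick-wall clamp.** For h ≳ R₀ the ring-buckling pressure exceeds
  the hoop branch's zero-area pressure; |P_b| is clamped so the area at
  buckling satisfies A_b ≥ 0.5·A₀.
* **Thin-wall knee budget.** For very thin/soft walls the nominal knee
  would swallow more area than the lumen holds; δ is narrowed so the
  knee exit stays above max(2·A_floor, 0.05·A₁).

Areas are clipped at a floor A_floor representing the residual slit
when opposite walls approach contact: an ellipse with major axis 2R₀
and minor axis 0.5 mm (the wall-contact stop criterion), configurable.
`fit_tube_law` offers a calibration mode that fits (K_lin, P_b, C_knee)
to sampled (P, A) data when the area-pressure relation comes from
measurements or 3-D simulation instead of shell-scale formulas — the
shell-derived post-buckling stiffness is a thin-wall idealization and
over-responds to thickness relative to thick-walled anatomy.

Wave speed and the wave-speed flow limit are free functions of the
local (area, compliance) pair: c = √(A/(ρC)), V̇Imax = A·c.  Air
density defaults to ρ = 1.2 kg/m³; a `AIR_FSI` preset with
ρ = 1.225 kg/m³ (standard CFD air) is provided because both conventions
are common.

## Solver

For a uniform segment the station balance collapses to a single scalar
relation: for every station area A there is exactly one flow

    Q(A) = [−R_up + √(R_up² + 4(½ρ/A² + k2_up)(P_N − P_lum(A)))] / (2(½ρ/A² + k2_up))

with P_lum(A) = P_tissue + P_tm(A).  The curve Q(A) rises as the
segment narrows, peaks, and falls: the peak is the flow-limitation
fold, and differentiating shows dQ/dA = 0 exactly where Q/A equals the
wave speed — the saddle-node of the implicit solution *is* the
wave-speed criterion.  `max_flow` locates the peak by a dense area grid
(4096 points) plus bounded scalar refinement (xatol 10⁻¹⁴ m²);
`solve_steady` inverts the monotone subcritical branch (area above the
peak) by interpolation plus Brent polish to meet a demanded outlet
pressure.  When the demanded outlet pressure is below what the fold can
deliver, the returned state is the maximal-flow state with
`limited=True`; flow and upstream pressures are then independent of
further outlet-pressure decreases, which makes the waterfall metric of
a limited trace vanish identically.  Flow at the fold is resolved to
better than the 10⁻⁹ m³/s tie-break tolerance.  With `viscous_loss=True`
the stations differ and a downstream marching solver with bracketed
root-finding per station is used instead, with outer bisection on Q for
the fold.

The test suite checks the production solver against an independent
brute-force oracle (dense Q grid, damped fixed-point iteration per
station, feasibility scan) on seeded random models.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| A₀ | 1.18 cm² | rest area of the collapsible segment |
| length | 20 mm | collapsible segment length |
| h | 2–8 mm | wall thickness (grid) |
| E | 2–30 kPa | wall modulus (grid); silicone-like ν = 0.48, ρ = 1080 kg/m³ |
| R_up | 0.07×10⁶ / 0.12×10⁶ Pa·s/m³ | nasal resistance presets (both nostrils open / one blocked) |
| R_down | 10⁴ Pa·s/m³ | small tracheal resistance |
| ramp | 0 → −600 Pa in 1 s | default breathing profiles (linear/sinusoidal/exponential) |
| dt | 1 ms | trace sampling step |
| n_stations | 21 | axial stations in the segment |

The exponential ramp uses k = ln(1/|amplitude|) so it starts at −1 Pa
(the steady initialization pressure) for any amplitude.  Profiles are
duration-scale-invariant, so a 16 s bench ramp and a 1 s simulated ramp
trace the same curve.

## Synthetic data

`synth_tube_law_samples` draws pressures uniformly between the law's
floor pressure and +50 Pa and perturbs areas multiplicatively
(relative σ, default 1%).  `synth_experiment_trace` emulates bench
runs: the outlet-pressure ramp is re-parameterized by a random monotone
time warp (PCHIP through knots with log-normally jittered spacing —
run-to-run variability in how fast a vacuum valve opens), sampled at
100 Hz, with additive Gaussian sensor noise (defaults: 2 Pa pressure,
0.5 L/min flow; sensor noise magnitudes are design placeholders and
configurable).  All generators are deterministic under a fixed seed.

What the generators do **not** emulate: three-dimensional anatomy and
its asymmetric collapse, wall flutter/snoring oscillations, negative
effort dependence (the quasi-steady model plateaus by construction —
`ned_index` will detect NED in measured curves but the simulator never
produces it), and contact mechanics beyond the area-floor stop rule.
Passing tests therefore demonstrate internal consistency of the 1-D
model and its analysis pipeline at realistic parameter values, not
agreement with any particular anatomical airway; absolute peak flows of
a real 3-D airway depend on anatomy and are outside this model's claim.
What the model *does* claim, and the tests verify, are the structural
properties: wave-speed choking (simulated V̇Imax within a fraction of a
percent of A^{3/2}(ρ·dA/dP)^{−1/2} at the choke state across the
default grid), the waterfall freeze of upstream pressures, breathing
profile independence, V̇Imax ∝ C^(−1/2) across a stiffness sweep
(log-log slope −0.5 ± 0.1 with the open-nostril resistance), and
monotone effects of E, h and R_up.

## Design notes and numerical choices

* **Classical-equation recovery.** The textbook Starling relation
  V̇Imax = (P_N − P_tissue)/R_up emerges only when the upstream
  resistance dominates the tube's Bernoulli impedance: by the envelope
  theorem, dV̇Imax/dP_N = 1/(R_up + ρQ/A²) at the fold.  The recovery
  test therefore uses a high-resistance configuration
  (R_up = 4×10⁶ Pa·s/m³, P_tissue = +300 Pa, CPAP-like P_N sweep
  1.5–4 kPa), where the slope matches 1/R_up within a few percent; at
  the default nasal resistance the Bernoulli term contributes
  materially and the classical equation is only an approximation.
* **Choke station.** With a uniform segment all stations share one
  state; the choke index is reported as the most downstream station
  (ties in minimum area resolve downstream), which is where choking
  localizes in a physical segment.
* **Compliance estimation from samples** (`fit_compliance`) is a local
  least-squares slope.  It is well-posed where the law is close to
  linear over the window; on the post-buckling branch compliance varies
  on a pressure scale of K_eff, so windows there must be narrow and
  dense sampling is needed.  The recovery test uses the long hoop
  branch of the h = 6 mm, E = 2 kPa law for this reason.
* **Sweep table units** are clinical (L/min, cm²/cmH₂O, Pa·s/mL) with
  the conversion constants 1 cmH₂O = 98.0665 Pa and
  1 L/min = 1/60000 m³/s; the library core is SI throughout.
* **Neo-Hookean bookkeeping.** `neo_hookean_coeffs` stores C₁ = μ/2 and
  D₁ = λ/2.  The λ/2 volumetric convention is kept as-is for record
  keeping; finite-element packages often use 2/K (K the bulk modulus)
  instead.  Nothing in the solver consumes these coefficients.
* **Problem sizes.** The default grid (7 mechanical configurations × 2
  nasal-resistance presets), 20 random models for the oracle
  cross-check, 8-point stiffness sweeps, and millisecond-sampled 1 s
  ramps keep a full test run under a minute on one core while resolving
  every quantity far inside its tolerance.

## Known limitations

* The quasi-1D model cannot reproduce the absolute peak flows of an
  anatomical 3-D airway; its validation is structural (scalings,
  bounds, monotonicities), not pointwise.
* The shell-scale branch stiffnesses (K_lin, K_p ∝ h, h³) are thin-wall
  results; for h approaching R₀ they are regularized heuristically
  (clamp above) and should be replaced by calibrated laws
  (`fit_tube_law`) when sampled area-pressure data exist.
* Post-fold behavior is frozen at the maximal-flow state; dynamic
  collapse beyond wall contact, flutter and NED are out of scope.
* The upstream segment is a lumped resistance; no nasal geometry is
  modelled beyond (R_up, k2_up).
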