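# Methods

## Scope and model

`ventsplit` models only the inspiratory limb of a split ventilator
circuit: a pressure-control ventilator, a Y-splitter, an optional orifice
restrictor per port, and one single-compartment RC patient per port.
Expiration, intrinsic PEEP, spontaneous effort, one-way valves and leaks
are out of scope. The splitter body's own pressure loss is negligible at
circuit scale (~0.1 cmH₂O at 30 L/min through 22 mm fittings), so by
default the two branches decouple and are integrated independently; a
common series resistance hook (`simulate_splitter(...,
common_resistance=...)`, cmH₂O/(L/s)) re-couples them through the shared
splitter-node pressure when wanted, at the cost of a per-step bracketed
root solve.

Per branch, with volume V (L) measured above the end-expiratory
equilibrium at PEEP and driving pressure referenced to PEEP,

    p_vent(t) − PEEP − Δp_restrictor(V̇) = (τ/C)·V̇ + V/C,
    τ = R·C + R_bc(C_bc + C),

with the restrictor law Δp(V̇) = a·V̇|V̇| + b·V̇. The odd (signed)
extension of the quadratic keeps the law dissipative if flow ever
reverses, though reversal is outside the simulated scenario. Referencing
volume to the PEEP equilibrium is exact, not an approximation, because the
RC equation is linear; it makes the end-of-window state directly the tidal
volume.

Air compressibility, which matters inside the restrictor throat where
velocities reach tens of m/s, is not resolved here: it is already folded
into the (a, b) coefficients, which come from compressible resolved-flow
simulations of the assembly. The lumped model's own pressures are
incompressible-circuit quantities. `stagnation_to_static` converts between
stagnation and transducer (static) pressure where needed; at 22 mm ports
the dynamic head is ~0.01 cmH₂O and ignorable.

## Parameters and defaults

| parameter | default | units | note |
| --- | --- | --- | --- |
| PIP / PEEP | 30 / 5 | cmH₂O | pressure-control settings |
| respiratory rate | 16 | min⁻¹ | bounds the inspiratory window |
| pressure-max time | 1.25 | s | hold at PIP |
| rise time | 0 | s | 0 = ideal step; τ_rise = rise/3 when > 0 |
| target tidal volume | 0.480 | L | per patient |
| C (restricted / unrestricted) | 0.1 / 0.2 | L/cmH₂O | compliant patient behind the restrictor |
| R inspiration / expiration | 13 / 12 | cmH₂O/(L/s) | expiratory value carried, unused |
| C_bc, R_bc | 0.004, 22 | L/cmH₂O, cmH₂O/(L/s) | circuit + endotracheal tube |
| gas R, c_p, ν | 265, 936, 2.02×10⁻⁵ | SI | 80% O₂ / 20% dry air; ν is kinematic |
| restrictor (a, b) | per diameter | mixed | 2 mm: 0.22444/0.88262; 3 mm: 0.03961/0.26081; 4 mm: 0.01394/0.07828; bare port: 0/0.00361 |

Compliance values are taken per branch explicitly; the three published
compliance pairs (0.04/0.02, 0.08/0.04, 0.20/0.10 restricted/unrestricted)
can all be run by editing the scenario YAML. The packaged default pairs
C=0.1 behind the restrictor with C=0.2 on the bare port, the combination
used for the tidal-volume rows and the titration sweep it reproduces
qualitatively.

The waveform rise is an exponential approach to PIP with time constant
rise_time/3 (≈95% of the span by the end of the rise). The default is a
pure step — every sample already at PIP — chosen so the analytic RC step
response applies exactly and the integrator can be validated against it to
numerical precision. Real ventilators ramp over ~0.1–0.3 s; setting
`rise_time` accordingly starts the waveform at PEEP.

Interface units are clinical throughout (cmH₂O, L/min, mm); conversion to
SI (1 cmH₂O = 98.0665 Pa) happens only inside hydraulic formulas. The
quadratic coefficients keep their mixed published units,
cmH₂O·(L/min)⁻² and cmH₂O·(L/min)⁻¹.

## Numerics

* **Per-step implicit solve.** The flow balance residual is strictly
  increasing in V̇, so the root always lies in [0, rhs·C/τ] (or its
  mirror). Newton iterations are safeguarded by bisection on that
  shrinking bracket; tolerance 10⁻⁹ L/s on the flow update, 60-iteration
  cap (typically 3–5 used). A stiff DAE solver would be overkill for a
  guaranteed scalar monotone solve.
* **Time stepping.** Heun's explicit trapezoidal rule, default dt = 1 ms
  (window/dt ≈ 1250 steps). Against the closed-form step response the
  max-abs volume error at dt = 1 ms is ~2×10⁻⁹ L; halving dt changes the
  end volume by far less than 0.1%. Volumes agree with the trapezoidal
  integral of the recorded flows to < 10⁻⁶ L.
* **Titration inversion.** End volume is monotone in the inspiratory
  window, so `required_inspiratory_time` bisects to 1 ms. Each sweep point
  rebuilds the waveform at dt = min(solver dt, window/20) so short windows
  stay resolved. Targets above the plateau C·(PIP−PEEP) raise
  `UnreachableTargetError` carrying the plateau.
* **Quadratic fitting.** Zero-intercept least squares of Δp on (V̇², V̇):
  the law has no constant term, and fitting one would absorb transducer
  offset that the noise model deliberately omits. R² is reported in both
  the zero-intercept convention (primary) and mean-centred (for
  comparison); standard errors come from the usual (XᵀX)⁻¹σ̂² with a
  residual-bootstrap alternative for checking. The optional non-negativity
  constraint clips a negative coefficient to zero and refits the other —
  adequate because at most one coefficient goes negative under realistic
  noise.
* **Power-law meta-fit.** Log-log OLS of ln a and ln b on ln D. This
  choice reproduces the published cross-diameter parameters (3.55, −4.03,
  10.27, −3.46) from the per-diameter coefficients to < 1%, strong
  evidence it is the original method. Note the meta-fit is only as good as
  its residuals: its linear coefficient misses the 3 mm law by ~12%, so
  pointwise agreement with the per-diameter laws is ~13% worst case at low
  flows, tightening below 7% once the quadratic term dominates (≳5 L/min).
* **Ridge feature size.** The radius trace is detrended (mean + linear),
  and the spectrum searched within ±30% of the layer frequency
  1/layer-thickness. A peak must exceed 3× the median in-band spectral
  floor, else the profile is declared ridge-free (0 with a warning). The
  amplitude is then refined by least-squares sinusoid fitting over a dense
  frequency grid, making the estimate independent of whether the profile
  span holds an integer number of layer periods. Feature size is reported
  on the diameter scale (2× the radius amplitude). Peak-to-peak bore
  variation is computed on the FFT low-pass trend (below half the layer
  frequency) so ridge texture is not double-counted.
* **Roughness-to-effective-diameter map.** Ridges displace the turbulent
  boundary layer, hydraulically narrowing the bore:
  D_eff = D_measured − 2·k·A_ridge with k = 1 by default. No calibrated
  value of k exists; it is exposed as a parameter.

## Synthetic data

The generators emulate the study's instrumentation, not its physics:

* **Bench measurements** apply independent multiplicative Gaussian noise
  to flow (0.6% of reading, 1σ) and pressure (0.5%), the conventional
  reading of percent-accuracy instrument specs. 200 measurements per
  restrictor by default (20 flows spanning 1–60 L/min, the validity range
  of the power law, × 10 replicates). Not modelled: barometric drift
  (assumed corrected), transducer offset, flow-meter nonlinearity, or any
  systematic bias — so parameter-recovery results show estimator
  correctness under the stated random-error model, not robustness to
  systematics.
* **Wall profiles** are a constant undersized radius plus a layer-periodic
  sinusoidal ridge plus white measurement noise. Real printed bores have
  non-sinusoidal ridge shapes, axial drift and localised defects;
  round-trip tests therefore validate the analyser's estimators, not the
  realism of any particular printer.

All generators are pure functions of (parameters, seed).

## Design choices where the design was open

* The published inlet waveform is an empirical ventilator recording that
  is not tabulated; the parametric step/ramp stand-in makes the solver
  exactly checkable against closed forms. Consequently the simulated
  absolute tidal volumes (e.g. 473/808 mL at 1.25 s for the default pair)
  deliberately exceed the resolved-flow reference values driven by the
  real ramped waveform; only closed-form-checkable quantities and
  structural orderings are asserted numerically.
* Published compliance labels are inconsistent between tables; the package
  takes compliances explicitly per branch and never infers them from
  "stiff"/"healthy" labels.
* The printed orifice relation omits the square on V̇; dimensional
  analysis and the standard orifice law require V̇², which is what
  `orifice_pressure_drop` implements.
* The printed kinematic viscosity carries dynamic-viscosity units; it is
  treated as kinematic (m²/s) because the Reynolds relation divides by a
  kinematic viscosity, and it is exposed in the gas config.
* The published "I.D. error to layer thickness ratio" column is
  inconsistent with its name's formula; `summarize_profile` implements the
  stated-name formula (nominal − mean I.D.)/layer and the printed column
  is not used.

## Known limitations

* One breath, inspiratory only: no cyclic steady state, no expiratory
  dynamics, no patient triggering.
* The restrictor laws are valid for the specific splitter+restrictor
  geometry they were fitted to, 2–4 mm bores, flows ≤ 60 L/min; the
  power-law model extrapolates outside that range with a warning only.
* The discharge coefficient in the orifice relation is a user input; no
  Reynolds-number correlation is provided.
* k_roughness (ridge → effective-diameter loss) is uncalibrated.
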