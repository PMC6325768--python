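# Methods

## Model structure and assumptions

The circulation is a closed lumped-parameter network with eleven volume
states: four chambers (RA, RV, LA, LV) and seven vascular compartments
(ascending aorta, descending aorta, systemic arteries, systemic veins,
pulmonary artery, pulmonary capillaries, pulmonary veins), connected in one
loop with four diode valves plus a purely resistive coronary branch from the
aortic root to the right atrium. Each chamber follows the classical
time-varying elastance model: pressure is the activation-weighted linear
end-systolic relation plus an exponential passive relation, both anchored at
the same volume intercept V0. Activation is a squared sine over a fixed
window (atria 0.10 s starting at cycle time 0; ventricles 0.30 s starting at
17% of the cycle), rising from 0 to exactly 1 and back; this shape is smooth,
has symmetric half-activation times, and reproduces the usual PV-loop
morphology. Vascular compartments are linear compliances with unstressed
volumes and series outflow resistances.

Deliberate simplifications: no baroreflex or autoregulation (interventions
are analysed at fixed autonomic tone), no pericardium, no inertances, no
intrathoracic-pressure or ventilation coupling, no valve regurgitation, and
no pulmonary gas-exchange dynamics beyond a fixed pulmonary-capillary outlet
saturation. These are modelling choices, not oversights: they keep every
intervention effect attributable to the mechanics being studied.

Oxygen is advected through the same network assuming perfect mixing at each
node and upwind transport on every edge. Boundary conditions: pulmonary
capillary saturation pinned at the lung parameter (default 0.98; lower it to
emulate lung failure), ECMO return fully saturated (1.00), and a fixed
whole-body VO2 (250 mL O2/min at 70 kg) extracted in the systemic-venous
node with O2 capacity 1.34 mL/g x hemoglobin (12 g/dL default). With
retrograde ECMO return and failing lungs this reproduces differential
oxygenation: the ascending aorta receives poorly saturated native ejectate
while the descending aorta receives oxygenator blood.

## Devices

* **VA ECMO** — ideal flow source (0-4+ L/min): it removes its setpoint from
  the RA and returns it (plus any vent drainage joining the venous line)
  into the descending aorta. The pump-inlet-node pressure is
  P_RA − (Q_pump + Q_vent)·R_drain with R_drain = 0.3 mmHg·s/mL (about
  20 mmHg of venous-line suction at 4 L/min, typical of a 23-25 Fr femoral
  drainage cannula). Flow derates linearly when RA pressure falls below
  −5 mmHg (suction guard). Pump head-flow curves are intentionally omitted:
  the studied support states fix the flow.
* **IABP** — a 40 mL balloon in the descending aorta, modelled as displaced
  volume inside that compartment's pressure relation (blood volume is
  untouched, so conservation is exact). Inflation starts at the
  aortic-valve-closure time detected on the previous beat; deflation
  completes 50 ms before the previous beat's ejection onset; both ramps are
  50 ms raised cosines. When no valve events occur (nonejecting LV) the
  schedule falls back to the ventricular activation window.
* **Impella** — ideal flow source LV → ascending aorta (1-5 L/min) with a
  linear suction derating below −5 mmHg LV pressure; never negative.
* **Atrial septostomy** — sharp-edged orifice between LA and RA,
  Q = Cd·A·sqrt(2|ΔP|/ρ), Cd = 0.85 (sharp-orifice literature range
  0.6-0.9), ρ = 1060 kg/m³; antisymmetric in ΔP, so the quadratic law makes
  unloading saturate realistically with defect size.
* **Vent** — one-way cannula from LA, PA or LV into the ECMO pump-inlet
  node. Resistance = Hagen-Poiseuille value of the 3/8-inch x 2 m tubing
  (0.26 mmHg·s/mL at 3.5 mPa·s, i.e. ~4.3 mmHg per L/min) plus a single
  lumped tip-loss resistance shared by all three sites. The vent drains into
  the ECMO venous line — the standard clinical hookup — so its flow is set
  by the simulated source-to-pump-inlet gradient, and the drained blood
  returns to the aorta through the pump (volume conserved exactly).

## Calibration

The unavailable provenance of any individual-patient parameter set means all
numbers here are the package's own calibration products, fixed once and
frozen into the presets:

1. **Normal** (HR 70, 5600 mL): systemic arteriolar resistance and venous
   unstressed volume were iterated to CO 7.0 L/min and MAP 92 mmHg (CI 3.9
   at the fixed BSA of 1.8 m², itself implied by the CO/CI pairs the presets
   target). Resulting EF 0.65, PCWP 7.5 mmHg, CVP ~3 mmHg. Venous compliance
   is the literature-standard ~1.5 mL/mmHg/kg (100 mL/mmHg); total arterial
   compliance 2.5 mL/mmHg split 0.6/1.3/0.6 across ascending aorta,
   descending aorta and arteries; aortic valve resistance 0.02 mmHg·s/mL
   gives a physiologic peak transvalvular gradient of 5-10 mmHg.
2. **LV failure** (HR 100, 6400 mL): the chronically remodelled LV gets a
   rightward ESPVR shift (V0 10 → 90 mL, the standard signature of dilated
   remodelling), reduced contractility, and a stiffened EDPVR (A x2.675,
   B x2.0 around the shifted V0). LV Ees and RV Ees were then solved (fixed-
   point iteration on steady-state runs) for CO 3.1 L/min and PCWP 30 mmHg;
   the RV scale is what partitions congestion between the wedge pressure and
   the CVP, which the LV knobs alone cannot do — with only LV contractility
   and stiffness free, output saturates near 3.9 L/min through passive
   congestion and both targets cannot be met simultaneously. Final values:
   LV Ees 0.95, RV Ees 0.18 mmHg/mL; emergent failure MAP 49.5 mmHg and
   CVP ~9 mmHg (neither is a target). Nothing else changes relative to
   normal — in particular systemic resistance is untouched, since the
   failure state is defined by contractility, stiffness, volume and rate
   alone.
3. **Deteriorated LV**: the failure preset with LV Ees set to 0.3 mmHg/mL.
4. **Inotropy**: LV Ees multiplier 2.1160, calibrated once so EF rises by
   exactly 10 percentage points on the failure + ECMO 4 L/min state; the RV
   receives half the fractional increase (inotropic drugs act
   biventricularly but the intervention targets the LV).
5. **Vent loss**: the single shared tip-loss resistance (1.89 mmHg·s/mL) is
   calibrated so the LV vent drains 1.9 L/min on the failure + ECMO 4 state.
   The LA and PA flows (1.39 and 1.50 L/min) then follow from the simulated
   gradients with no further tuning — they are genuine predictions, as is
   the LV > PA > LA ordering.

The `calibrate()` routine exposes the same machinery generically:
coordinate-descent with nested bisection over at most six multiplicative
knobs (LV/RV Ees, LV EDPVR, SVR, pulmonary resistance, venous compliance),
deterministic given the fixed knob order, reporting achieved values and
residuals and raising on non-convergence.

## What the presets emulate — and what they do not

The presets are synthetic study conditions, not patient data: a single
"generic" 70 kg adult whose failure state was constructed to sit exactly on
the stated macro-hemodynamics. Passing tests therefore show that the model
class reproduces the studied support physiology at those operating points;
they do not show predictive accuracy for any real patient, for other body
sizes, or for states far from the calibrated regime (e.g. arrhythmia, RV-
dominant failure, sepsis). Autonomic reflexes are absent by design, so
absolute pressures under strong interventions (e.g. inotropy without
titration) run higher than they would clinically.

## Numerical choices

Fixed-step RK4 at Δt = 0.5 ms (the step is snapped so an integer number of
steps spans one beat); output sampled at 1 ms, ≥600 samples per beat.
Halving Δt changes beat-averaged MAP by < 0.1 mmHg. Steady state is declared
when the end-of-beat volume vector changes by < 0.1 mL (max-abs) between
consecutive beats — typically 10-70 beats from the deterministic initial
state (uniform 8 mmHg filling pressure, residual volume in the venous pool).
Saturations equilibrate more slowly (venous turnover ~30 s) and are not part
of the convergence criterion; runs that interrogate saturations integrate
longer. Total volume drift is < 10⁻⁶ relative per simulated minute (RK4
conserves the sum exactly up to float rounding because every flow enters the
state derivative twice with opposite signs). Chamber passive pressure may go
slightly negative (diastolic suction); any state volume reaching zero or
going non-finite aborts the run with the offending node and time. Valves are
resistive diodes (forward 0.003-0.02, backward 5000 mmHg·s/mL; leak ≪ 1% of
stroke volume). The nonejection threshold is 1 mL of forward aortic-valve
volume per beat, since a strict zero is unattainable with a finite
closed-valve resistance. End systole for the PVA decomposition is the
maximal-elastance sample max P/(V−V0), robust for nonejecting loops;
PE = Pes·(Ves−V0)/2 minus the EDPVR integral, clamped at zero; MVO2 uses the
linear PVA relation with slope 1.8e-5 mL O2/(mmHg·mL), intercept 2.4e-3
mL O2/beat/100 g and LV mass 300 g — only trends are asserted on MVO2, not
absolute values. Afterload titration is plain bisection on a global
systemic-resistance multiplier (bracket 0.2-3.0, monotonicity asserted on
the bracket ends, tolerance 0.5 mmHg): slower than gradient steps but
deterministic and robust. The integration kernel is compiled with numba
(cached); results are bit-reproducible across runs.

## Known limitations

Four qualitative/quantitative features of the studied physiology are not
reproduced by this model class, and their tests are deliberately left
failing rather than loosened:

1. **Combined inotropy + afterload titration overshoots.** Raising EF by 10
   points adds ~1.7 L/min of native output; without a baroreflex that
   raises MAP by ~20 mmHg, and titrating back to 65 mmHg then adds ~7
   further EF points (total ~ +17) instead of ~ +4 (total +14). Matching
   both numbers simultaneously would need an EF-afterload sensitivity of
   ~0.12 points/mmHg, flatter than a linear-ESPVR elastance chamber of this
   size can be.
2. **IABP stroke-volume gain ~15% instead of 5-10%.** The absolute gain
   (+2.6 mL from a 40 mL balloon, with diastolic augmentation ~15 mmHg and
   improved coronary flow) is physiologic; the relative figure is inflated
   by the small supported native stroke volume (~17 mL).
3. **Nonejection is not reached** either by the deteriorated LV
   (Ees 0.3) under full support or by the largest septostomy: both states
   retain ~6 mL/beat of ejection. The aortic diastolic pressure — the
   opening threshold — itself falls as native output falls (MAP tracks
   total flow), while LV peak pressure (EDP plus active pressure) stays a
   few mmHg above it across every parameterization tried (EDPVR shapes,
   valve resistances, pulmonary resistance). Both states are still strongly
   unloaded and their monotone trends (EDV and PCWP falling with device
   flow/defect size; adjuncts emptying the deteriorated LV) all hold.
4. **Stroke work ticks up (+2%) at the first ECMO ramp step** before
   falling monotonically to well below baseline at 4 L/min, because at low
   support the pressure rise initially outweighs the stroke-volume loss.
   MVO2 rises strictly along the whole ramp and PVA ≥ SW everywhere.

Also out of scope: aortic regurgitation (relevant to transvalvular pumps),
cannula-position effects, hemolysis/coagulation, pump head-flow curves, and
oxygenator gas-transfer dynamics beyond the fixed outlet saturation.
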