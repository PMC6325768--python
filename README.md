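# ecmosim

A closed-loop, lumped-parameter (0D) simulator of severe left-ventricular
systolic failure supported by veno-arterial ECMO, built to quantify how much
each adjunct **LV unloading** intervention actually unloads the ventricle:
afterload reduction, volume removal, inotropy, intra-aortic balloon
counterpulsation (IABP), a transvalvular microaxial pump (Impella), atrial
septostomy, and direct LA / PA / LV vent cannulae draining into the ECMO
circuit.

It is aimed at computational physiologists and intensivists who want a
transparent, scriptable model of the VA ECMO loading problem: retrograde
aortic return raises afterload on a failing LV, so filling pressures, cavity
volumes and myocardial oxygen demand *rise* with pump flow even as systemic
perfusion improves.

## Model

Four cardiac chambers follow the time-varying elastance formulation

    P(V, t) = a(t) · Ees · (V − V0) + A · (e^{B (V − V0)} − 1)

with a squared-sine activation `a(t)` ∈ [0, 1], a linear end-systolic
pressure–volume relation (slope `Ees` = contractility, intercept `V0`) and an
exponential end-diastolic relation (scale `A`, exponent `B`). Valves are
resistive diodes; seven vascular compartments (ascending/descending aorta,
systemic arteries and veins, pulmonary artery, capillaries and veins) are
linear compliances `P = (V − Vu)/C` with series resistances, plus a coronary
branch from the aortic root to the right atrium throttled by intramyocardial
pressure (0.75 · P_LV). Oxygen saturations advect through the same network
with fixed lung / oxygenator outlet saturations and a systemic VO₂ sink.

The mass-balance ODEs (11 volume states) are integrated with fixed-step RK4
(Δt = 0.5 ms) to a periodic steady state (beat-to-beat end-of-beat volume
change < 0.1 mL); total blood volume is conserved to < 10⁻⁶ relative drift
per simulated minute. Devices enter as source/sink terms: ECMO and Impella
as ideal flow sources with suction derating, the IABP as displaced volume in
the descending aorta, septostomy as an orifice (Q = Cd·A·√(2ΔP/ρ)), vents as
Hagen–Poiseuille tubing into the ECMO venous line.

Per converged beat the package reports MAP, PCWP (beat-mean pulmonary-venous
pressure), CVP, native and total cardiac output, LV EDV/ESV/SV/EF, stroke
work (PV-loop area), pressure–volume area PVA = SW + PE and the linear
Suga-type MVO₂ estimate, coronary and device flows, and ejection status.

Two calibrated presets anchor all scenarios: **normal** (70 kg adult, HR 70,
5600 mL blood volume; CO 7.0 L/min, CI 3.9 L/min/m² at BSA 1.8 m²) and
**lv_failure** (HR 100, 6400 mL, contractility reduced and diastolic
stiffness increased on a right-shifted ESPVR; CO 3.1 L/min, CI 1.7,
PCWP 30 mmHg). A 17-row scenario registry layers the support combinations on
top. See `docs/methods.md` for the calibration procedure and known limits.

## Worked example

```python
import ecmosim as es
from ecmosim.metrics import summarize

for name, model in [
    ("normal",              es.build_normal()),
    ("lv_failure",          es.build_lv_failure()),
    ("lv_failure + ECMO 4", es.with_ecmo(es.build_lv_failure(), 4.0)),
]:
    s = summarize(es.steady_state(model, max_beats=600))
    print(f"{name:22s} MAP {s.map:6.1f}  CO {s.co_total:5.2f}  "
          f"PCWP {s.pcwp:5.1f}  EDV {s.lv_edv:5.1f}  EF {100*s.lv_ef:5.1f}%  "
          f"SW {s.stroke_work:6.0f}  MVO2 {s.mvo2:5.2f}")
```

prints

```
normal                 MAP   91.9  CO  7.00  PCWP   7.5  EDV 154.9  EF  64.6%  SW  12365  MVO2 19.41
lv_failure             MAP   49.5  CO  3.10  PCWP  30.0  EDV 169.8  EF  18.3%  SW    978  MVO2  4.78
lv_failure + ECMO 4    MAP   78.3  CO  5.71  PCWP  34.7  EDV 172.9  EF   9.9%  SW    889  MVO2  6.61
```

Reading the rows: the failing ventricle dilates (EDV 155 → 170 mL), its
ejection fraction collapses and the wedge pressure reaches pulmonary-edema
territory (30 mmHg). Adding 4 L/min of retrograde VA ECMO restores systemic
pressure (MAP 78 mmHg) and total output (5.7 L/min), but the LV itself gets
*worse*: it dilates further, its native stroke volume halves, the wedge
pressure climbs to 35 mmHg, and — per the pressure–volume-area relation —
myocardial oxygen consumption rises (MVO₂ 4.8 → 6.6 mL O₂/min) while stroke
work falls. That trade-off is the motivation for the unloading adjuncts.

The same runs are available from the shell:

```bash
ecmosim run --scenario lv_failure_ecmo4 --out out/   # one scenario
ecmosim table1 --out table1.csv                      # all 17 registry rows
ecmosim sweep --device impella --grid 1,2,3,4,5      # device-setting sweep
ecmosim make-fixture --kind rectangle                # analytic loop fixture
```

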