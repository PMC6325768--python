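"""Scenario presets, intervention builders, titration and calibration.

Two calibrated presets anchor everything:

* **normal** — a 70 kg adult at HR 70 bpm and 5600 mL blood volume, tuned to
  a cardiac output of 7.0 L/min (cardiac index 3.9 L/min/m^2 at BSA 1.8 m^2)
  with textbook filling pressures.
* **lv_failure** — severe LV systolic failure: contractility reduced,
  passive diastolic stiffness increased, sinus rhythm at 100 bpm, blood
  volume expanded to 6400 mL; tuned to CO 3.1 L/min (CI 1.7) with a PCWP of
  30 mmHg — a cardiogenic-shock state.

Interventions (volume change, inotropy, afterload titration to a MAP
target) and the mechanical-support devices are layered on top in a fixed
order: volume -> contractility -> devices -> titration. A registry mirrors
the 17 studied support combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .devices import (AsdConfig, DeviceSet, EcmoConfig, IabpConfig,
                      ImpellaConfig, VentConfig)
from .engine import ConvergenceError, SimulationResult, steady_state
from .metrics import HemodynamicSummary, summarize
from .parameters import CirculationModel

# ---------------------------------------------------------------------------
# Frozen calibration products (see docs/methods.md for how these were fixed)
# ---------------------------------------------------------------------------

#: LV contractility multiplier of the failure preset (applied to normal Ees)
FAILURE_LV_EES_SCALE = 0.3802
#: rightward ESPVR shift of the chronically remodelled, dilated failing LV
#: (volume intercept moves from 10 to 90 mL)
FAILURE_LV_V0 = 90.0
#: LV diastolic-stiffening multipliers of the failure preset (EDPVR scale A
#: and exponent B are both raised around the shifted V0)
FAILURE_EDPVR_A_SCALE = 2.675
FAILURE_EDPVR_B_SCALE = 2.0
#: RV contractility multiplier of the failure preset (predominant LV failure
#: with secondary RV involvement; partitions congestion between PCWP and CVP)
FAILURE_RV_EES_SCALE = 0.3019
#: LV Ees multiplier of the inotropy intervention, calibrated so that on the
#: failure + ECMO 4 L/min state the LV ejection fraction rises by 10
#: percentage points; the RV receives half the fractional increase
#: (LV-weighted biventricular drug action)
INOTROPY_SCALE = 2.1160
INOTROPY_RV_WEIGHT = 0.5
#: contractility of the further-deteriorated, nonejecting-LV state, mmHg/mL
SEVERE_LV_EES = 0.3

NORMAL_HR = 70.0
NORMAL_BLOOD_VOLUME = 5600.0
FAILURE_HR = 100.0
FAILURE_BLOOD_VOLUME = 6400.0

#: Impella flow tiers (L/min) for the three device sizes (2.5 / CP / 5.0)
IMPELLA_TIERS = (2.5, 3.7, 5.0)

MAP_TARGET_DEFAULT = 65.0


def build_normal() -> CirculationModel:
    """Calibrated normal physiology: CO 7.0 L/min, CI 3.9, MAP ~92 mmHg."""
    return CirculationModel(
        chambers={
            "LA": dict(name="LA", ees=0.40, v0=10.0, passive_a=0.30,
                       passive_b=0.060, act_onset=0.0, act_duration=0.10),
            "LV": dict(name="LV", ees=2.5, v0=10.0, passive_a=0.80,
                       passive_b=0.018, act_onset=0.17, act_duration=0.30),
            "RA": dict(name="RA", ees=0.30, v0=10.0, passive_a=0.30,
                       passive_b=0.060, act_onset=0.0, act_duration=0.10),
            "RV": dict(name="RV", ees=0.60, v0=10.0, passive_a=0.35,
                       passive_b=0.018, act_onset=0.17, act_duration=0.30),
        },
        valves={
            "mitral": dict(name="mitral", r_open=0.004, r_closed=5000.0),
            "aortic": dict(name="aortic", r_open=0.02, r_closed=5000.0),
            "tricuspid": dict(name="tricuspid", r_open=0.003, r_closed=5000.0),
            "pulmonary": dict(name="pulmonary", r_open=0.005, r_closed=5000.0),
        },
        compartments={
            "asc_ao": dict(name="asc_ao", c=0.6, vu=40.0, r_out=0.02),
            "desc_ao": dict(name="desc_ao", c=1.3, vu=120.0, r_out=0.04),
            "sys_art": dict(name="sys_art", c=0.6, vu=400.0, r_out=0.7013),
            "sys_ven": dict(name="sys_ven", c=100.0, vu=3095.0, r_out=0.04),
            "pa": dict(name="pa", c=3.5, vu=60.0, r_out=0.05),
            "pulm_cap": dict(name="pulm_cap", c=5.0, vu=140.0, r_out=0.035),
            "pulm_ven": dict(name="pulm_ven", c=9.0, vu=280.0, r_out=0.012),
        },
        hr=NORMAL_HR,
        total_blood_volume=NORMAL_BLOOD_VOLUME,
    )


def _scale_chamber(model: CirculationModel, name: str, *, ees_scale: float = 1.0,
                   edpvr_scale: float = 1.0, edpvr_b_scale: float = 1.0,
                   ees: Optional[float] = None) -> CirculationModel:
    data = model.model_dump()
    ch = data["chambers"][name]
    ch["ees"] = ees if ees is not None else ch["ees"] * ees_scale
    ch["passive_a"] *= edpvr_scale
    ch["passive_b"] *= edpvr_b_scale
    return CirculationModel.model_validate(data)


def build_lv_failure() -> CirculationModel:
    """Severe LV systolic failure preset: CO 3.1 L/min, PCWP 30 mmHg.

    HR 100 bpm, blood volume expanded from 5600 to 6400 mL, LV contractility
    reduced and passive diastolic stiffness increased (calibrated scales).
    """
    m = build_normal()
    data = m.model_dump()
    lv = data["chambers"]["LV"]
    lv["ees"] *= FAILURE_LV_EES_SCALE
    lv["v0"] = FAILURE_LV_V0
    lv["passive_a"] *= FAILURE_EDPVR_A_SCALE
    lv["passive_b"] *= FAILURE_EDPVR_B_SCALE
    data["chambers"]["RV"]["ees"] *= FAILURE_RV_EES_SCALE
    data["hr"] = FAILURE_HR
    data["total_blood_volume"] = FAILURE_BLOOD_VOLUME
    return CirculationModel.model_validate(data)


def build_lv_failure_severe() -> CirculationModel:
    """Further deteriorated LV (Ees 0.3 mmHg/mL): nonejecting under ECMO 4 L/min."""
    m = build_lv_failure()
    return _scale_chamber(m, "LV", ees=SEVERE_LV_EES)


def with_devices(model: CirculationModel, **devices) -> CirculationModel:
    """Attach devices (ecmo=, iabp=, impella=, asd=, vent=) to a model copy."""
    current = model.devices.model_dump()
    for key, cfg in devices.items():
        current[key] = cfg.model_dump() if isinstance(cfg, BaseModel) else cfg
    return model.copy_with(devices=current)


def with_ecmo(model: CirculationModel, flow_lmin: float) -> CirculationModel:
    return with_devices(model, ecmo=EcmoConfig(pump_flow=flow_lmin))


def apply_volume_change(model: CirculationModel, dv_ml: float) -> CirculationModel:
    """Change total blood volume by dv_ml (e.g. -800 for volume removal).

    Volumes are re-equilibrated across compartments before integration (the
    initial state distributes the new total at a uniform filling pressure).
    """
    if dv_ml == 0:
        return model
    new_volume = model.total_blood_volume + dv_ml
    vu_total = sum(c.vu for c in model.compartments.values())
    if new_volume <= vu_total:
        raise ValueError(
            f"infeasible blood volume {new_volume:.0f} mL "
            f"(unstressed volume is {vu_total:.0f} mL)"
        )
    return model.copy_with(total_blood_volume=new_volume)


def apply_inotropy(model: CirculationModel, scale: float = INOTROPY_SCALE) -> CirculationModel:
    """Scale ventricular contractility (biventricular, as inotropic drugs act).

    The LV receives the full Ees multiplier; the RV half of the fractional
    increase (LV-weighted drug action). Heart rate is left unchanged:
    chronotropic effects are outside the single-beat PV-loop analysis this
    model targets.
    """
    if scale <= 0:
        raise ValueError("inotropy scale must be positive")
    if scale == 1.0:
        return model
    m = _scale_chamber(model, "LV", ees_scale=scale)
    return _scale_chamber(m, "RV",
                          ees_scale=1.0 + INOTROPY_RV_WEIGHT * (scale - 1.0))


def scale_svr(model: CirculationModel, scale: float) -> CirculationModel:
    """Scale the systemic arteriolar resistance (the dominant SVR component)."""
    data = model.model_dump()
    data["compartments"]["sys_art"]["r_out"] *= scale
    return CirculationModel.model_validate(data)


@dataclass
class TitrationInfo:
    svr_scale: float
    achieved_map: float
    iterations: int


def titrate_svr_to_map(model: CirculationModel, target_map: float,
                       tol: float = 0.5, bracket: tuple[float, float] = (0.2, 3.0),
                       max_iter: int = 40, dt: float = 5e-4,
                       max_beats: int = 300) -> tuple[CirculationModel, TitrationInfo]:
    """Bisect a global systemic-resistance multiplier until MAP hits the target.

    MAP is monotone in the multiplier over the bracket (asserted on the
    bracket ends before bisecting); the iteration is fully deterministic.
    """

    def map_at(s: float) -> float:
        res = steady_state(scale_svr(model, s), max_beats=max_beats, dt=dt)
        return summarize(res).map

    current = map_at(1.0)
    if abs(current - target_map) <= tol:
        return model, TitrationInfo(svr_scale=1.0, achieved_map=current, iterations=0)

    lo, hi = bracket
    f_lo, f_hi = map_at(lo), map_at(hi)
    if not f_lo < f_hi:
        raise RuntimeError(
            f"MAP not monotone over SVR bracket: MAP({lo})={f_lo:.1f}, "
            f"MAP({hi})={f_hi:.1f}"
        )
    if not (f_lo <= target_map <= f_hi):
        raise RuntimeError(
            f"MAP target {target_map} unreachable: bracket gives "
            f"[{f_lo:.1f}, {f_hi:.1f}] mmHg"
        )
    it = 0
    f_mid = current
    mid = 1.0
    while it < max_iter:
        mid = 0.5 * (lo + hi)
        f_mid = map_at(mid)
        it += 1
        if abs(f_mid - target_map) <= tol:
            break
        if f_mid < target_map:
            lo = mid
        else:
            hi = mid
    else:
        raise RuntimeError(f"titration did not converge in {max_iter} iterations")
    return scale_svr(model, mid), TitrationInfo(svr_scale=mid, achieved_map=f_mid,
                                                iterations=it)


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------

BaseName = Literal["normal", "lv_failure", "lv_failure_severe"]


class Overrides(BaseModel):
    model_config = ConfigDict(extra="forbid")

    blood_volume_delta: float = 0.0
    contractility_scale: float = 1.0
    edpvr_scale: float = 1.0
    svr_scale: float = 1.0
    hr: Optional[float] = None


class Scenario(BaseModel):
    """A named scenario: base preset + overrides + devices + optional titration.

    Overrides are applied in a fixed order: volume change, then contractility
    (inotropy), then devices, then MAP titration.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    base: BaseName = "lv_failure"
    overrides: Overrides = Field(default_factory=Overrides)
    devices: DeviceSet = Field(default_factory=DeviceSet)
    titration_map: Optional[float] = None
    description: str = ""


_BASE_BUILDERS: dict[str, Callable[[], CirculationModel]] = {
    "normal": build_normal,
    "lv_failure": build_lv_failure,
    "lv_failure_severe": build_lv_failure_severe,
}


def build_scenario_model(scenario: Scenario) -> CirculationModel:
    """Materialize the scenario's model (without running the titration)."""
    m = _BASE_BUILDERS[scenario.base]()
    ov = scenario.overrides
    if ov.hr is not None:
        m = m.copy_with(hr=ov.hr)
    if ov.blood_volume_delta:
        m = apply_volume_change(m, ov.blood_volume_delta)
    if ov.contractility_scale != 1.0:
        m = apply_inotropy(m, ov.contractility_scale)
    if ov.edpvr_scale != 1.0:
        m = _scale_chamber(m, "LV", edpvr_scale=ov.edpvr_scale)
    if ov.svr_scale != 1.0:
        m = scale_svr(m, ov.svr_scale)
    if any(v is not None for v in scenario.devices.model_dump().values()):
        m = m.copy_with(devices=scenario.devices.model_dump())
    return m


@dataclass
class ScenarioRun:
    scenario: Scenario
    model: CirculationModel
    result: SimulationResult
    summary: HemodynamicSummary
    titration: Optional[TitrationInfo] = None


def run_scenario(scenario: Scenario, dt: float = 5e-4, max_beats: int = 300,
                 tol: float = 0.1) -> ScenarioRun:
    """Build, (optionally) titrate, and run a scenario to periodic steady state."""
    model = build_scenario_model(scenario)
    titration = None
    if scenario.titration_map is not None:
        model, titration = titrate_svr_to_map(model, scenario.titration_map,
                                              dt=dt, max_beats=max_beats)
    result = steady_state(model, max_beats=max_beats, tol=tol, dt=dt)
    result.scenario_name = scenario.name
    return ScenarioRun(scenario=scenario, model=model, result=result,
                       summary=summarize(result), titration=titration)


def table1_registry() -> list[Scenario]:
    """The 17 studied support states, in reporting order.

    Rows 1-2 are the unsupported presets; row 3 adds VA ECMO at 4 L/min; rows
    4-7 layer medical therapy or the IABP on top; rows 8-10 the three Impella
    tiers; rows 11-14 atrial septostomy (three sizes, then the mid size with
    afterload titration); rows 15-17 the LA / PA / LV vent cannulae.
    """
    ecmo4 = DeviceSet(ecmo=EcmoConfig(pump_flow=4.0))
    rows: list[Scenario] = [
        Scenario(name="normal", base="normal",
                 description="Normal physiology, HR 70, blood volume 5600 mL"),
        Scenario(name="lv_failure", description="Severe LV failure, HR 100, 6400 mL"),
        Scenario(name="lv_failure_ecmo4", devices=ecmo4,
                 description="LV failure + VA ECMO 4 L/min (ramp endpoint)"),
        Scenario(name="ecmo_map65", devices=ecmo4, titration_map=65.0,
                 description="+ afterload reduction to MAP 65 mmHg"),
        Scenario(name="ecmo_volume_minus800", devices=ecmo4,
                 overrides=Overrides(blood_volume_delta=-800.0),
                 description="+ blood volume reduced by 800 mL"),
        Scenario(name="ecmo_inotropy_map65", devices=ecmo4,
                 overrides=Overrides(contractility_scale=INOTROPY_SCALE),
                 titration_map=65.0,
                 description="+ inotropy, then SVR titrated to MAP 65 mmHg"),
        Scenario(name="ecmo_iabp",
                 devices=DeviceSet(ecmo=EcmoConfig(pump_flow=4.0), iabp=IabpConfig()),
                 description="+ IABP (40 mL balloon, diastolic augmentation)"),
    ]
    for tier in IMPELLA_TIERS:
        rows.append(Scenario(
            name=f"ecmo_impella_{str(tier).replace('.', '_')}",
            devices=DeviceSet(ecmo=EcmoConfig(pump_flow=4.0),
                              impella=ImpellaConfig(flow_setpoint=tier)),
            description=f"+ Impella at {tier} L/min",
        ))
    for area in (0.5, 1.0, 1.5):
        rows.append(Scenario(
            name=f"ecmo_asd_{str(area).replace('.', '_')}",
            devices=DeviceSet(ecmo=EcmoConfig(pump_flow=4.0),
                              asd=AsdConfig(area=area)),
            description=f"+ atrial septostomy {area} cm^2",
        ))
    rows.append(Scenario(
        name="ecmo_asd_1_0_map65",
        devices=DeviceSet(ecmo=EcmoConfig(pump_flow=4.0), asd=AsdConfig(area=1.0)),
        titration_map=65.0,
        description="+ ASD 1.0 cm^2 with SVR titrated to MAP 65 mmHg",
    ))
    for site in ("LA", "PA", "LV"):
        rows.append(Scenario(
            name=f"ecmo_vent_{site.lower()}",
            devices=DeviceSet(ecmo=EcmoConfig(pump_flow=4.0),
                              vent=VentConfig(site=site)),
            description=f"+ {site} vent (3/8 inch x 2 m) into the ECMO venous line",
        ))
    assert len(rows) == 17
    return rows


def scenario_by_name(name: str) -> Scenario:
    for sc in table1_registry():
        if sc.name == name:
            return sc
    names = ", ".join(s.name for s in table1_registry())
    raise KeyError(f"unknown scenario '{name}'; registry has: {names}")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

class CalibrationTarget(BaseModel):
    model_config = ConfigDict(extra="forbid")

    metric: Literal["CO", "CI", "MAP", "PCWP", "CVP", "EF"]
    value: float
    tolerance: float = Field(0.05, gt=0, description="Relative tolerance")


_METRIC_FIELD = {"CO": "co_total", "CI": "ci", "MAP": "map", "PCWP": "pcwp",
                 "CVP": "cvp", "EF": "lv_ef"}

#: knob name -> (apply(model, scale) -> model); scales are multiplicative
_KNOBS: dict[str, Callable[[CirculationModel, float], CirculationModel]] = {
    "lv_ees": lambda m, s: _scale_chamber(m, "LV", ees_scale=s),
    "rv_ees": lambda m, s: _scale_chamber(m, "RV", ees_scale=s),
    "lv_edpvr": lambda m, s: _scale_chamber(m, "LV", edpvr_scale=s),
    "svr": scale_svr,
}


def _venous_c(m: CirculationModel, s: float) -> CirculationModel:
    data = m.model_dump()
    data["compartments"]["sys_ven"]["c"] *= s
    return CirculationModel.model_validate(data)


def _pulm_r(m: CirculationModel, s: float) -> CirculationModel:
    data = m.model_dump()
    data["compartments"]["pa"]["r_out"] *= s
    data["compartments"]["pulm_cap"]["r_out"] *= s
    return CirculationModel.model_validate(data)


_KNOBS["venous_c"] = _venous_c
_KNOBS["pulm_r"] = _pulm_r


@dataclass
class CalibrationReport:
    entries: list[dict]
    converged: bool

    def residuals(self) -> dict[str, float]:
        return {e["metric"]: e["residual"] for e in self.entries}


def calibrate(base_model: CirculationModel, targets: list[CalibrationTarget],
              knobs: list[str], bracket: tuple[float, float] = (0.35, 2.8),
              max_outer: int = 6, max_bisect: int = 18, dt: float = 1e-3,
              max_beats: int = 300) -> tuple[CirculationModel, CalibrationReport]:
    """Coordinate-descent calibration: nested bisection of one knob per target.

    ``knobs[i]`` is bisected (multiplicative scale within ``bracket``) to meet
    ``targets[i]``, sweeping the pairs in order and repeating until every
    target is within its tolerance. Fully deterministic given the fixed
    parameter order. Raises with the best residuals on non-convergence.
    """
    if not targets:
        return base_model, CalibrationReport(entries=[], converged=True)
    if len(targets) != len(knobs):
        raise ValueError("one knob per target, paired by position")
    if len(knobs) > 6:
        raise ValueError("at most 6 free parameters")
    for k in knobs:
        if k not in _KNOBS:
            raise KeyError(f"unknown knob '{k}'; available: {sorted(_KNOBS)}")

    model = base_model

    def achieved(m: CirculationModel) -> dict[str, float]:
        summ = summarize(steady_state(m, max_beats=max_beats, dt=dt))
        return {t.metric: getattr(summ, _METRIC_FIELD[t.metric]) for t in targets}

    def within(vals: dict[str, float]) -> bool:
        return all(abs(vals[t.metric] - t.value) <= t.tolerance * abs(t.value)
                   for t in targets)

    vals = achieved(model)
    for _ in range(max_outer):
        if within(vals):
            break
        for target, knob in zip(targets, knobs):
            apply = _KNOBS[knob]
            if abs(vals[target.metric] - target.value) <= target.tolerance * abs(target.value):
                continue
            lo, hi = bracket
            f_lo = achieved(apply(model, lo))[target.metric]
            f_hi = achieved(apply(model, hi))[target.metric]
            increasing = f_hi >= f_lo
            a, b = (f_lo, f_hi) if increasing else (f_hi, f_lo)
            if not (min(a, b) <= target.value <= max(a, b)):
                continue  # target outside this knob's span; other knobs may move it
            best = 1.0
            for _i in range(max_bisect):
                mid = 0.5 * (lo + hi)
                f_mid = achieved(apply(model, mid))[target.metric]
                best = mid
                if abs(f_mid - target.value) <= 0.5 * target.tolerance * abs(target.value):
                    break
                if (f_mid < target.value) == increasing:
                    lo = mid
                else:
                    hi = mid
            model = apply(model, best)
            vals = achieved(model)
    entries = [
        {"metric": t.metric, "target": t.value, "achieved": vals[t.metric],
         "residual": (vals[t.metric] - t.value) / t.value}
        for t in targets
    ]
    ok = within(vals)
    report = CalibrationReport(entries=entries, converged=ok)
    if not ok:
        unmet = [e for e in entries if abs(e["residual"]) > 0]
        raise ConvergenceError(f"calibration did not meet all targets: {unmet}")
    return model, report


def calibrate_vent_loss(target_lv_flow_lmin: float = 1.9,
                        bracket: tuple[float, float] = (0.2, 8.0),
                        tol: float = 0.02, dt: float = 5e-4,
                        max_beats: int = 300) -> float:
    """Calibrate the single shared vent-cannula loss resistance.

    Bisects ``extra_loss_r`` so the direct LV vent on the LV-failure +
    ECMO 4 L/min state drains the target flow. The LA and PA vent flows then
    follow from the simulated pressure gradients with no further tuning.
    """
    base = with_ecmo(build_lv_failure(), 4.0)

    def flow_at(r: float) -> float:
        m = with_devices(base, vent=VentConfig(site="LV", extra_loss_r=r))
        return summarize(steady_state(m, max_beats=max_beats, dt=dt)).vent_flow

    lo, hi = bracket
    f_lo, f_hi = flow_at(lo), flow_at(hi)
    if not (f_hi <= target_lv_flow_lmin <= f_lo):
        raise RuntimeError(
            f"target vent flow {target_lv_flow_lmin} L/min outside achievable "
            f"range [{f_hi:.2f}, {f_lo:.2f}]"
        )
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        f_mid = flow_at(mid)
        if abs(f_mid - target_lv_flow_lmin) <= tol:
            return mid
        if f_mid > target_lv_flow_lmin:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
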