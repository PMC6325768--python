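"""Beat detection and derived hemodynamic quantities.

Summaries are computed on the final converged beat of a run: mean arterial
pressure, PCWP surrogate (beat-mean pulmonary-venous pressure), cardiac
output (native through the aortic valve, plus device contributions), LV
volumes and ejection fraction, PV-loop stroke work, pressure-volume area
(PVA) with the Suga linear MVO2 estimate, coronary flow and ejection status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .elastance import edpvr_integral
from .engine import SimulationResult
from .parameters import ChamberParams

LMIN_PER_MLS = 0.06

#: Suga-type MVO2 regression defaults: MVO2/beat/100g = A_MVO2 * PVA/100g + B_MVO2
A_MVO2 = 1.8e-5   # mL O2 per mmHg*mL
B_MVO2 = 2.4e-3   # mL O2 per beat per 100 g (basal + E-C coupling)
LV_MASS_G = 300.0

#: per-beat forward aortic-valve volume below which the LV counts as nonejecting
NONEJECTION_THRESHOLD_ML = 1.0


@dataclass
class PVLoop:
    """One converged beat of a chamber in the (volume, pressure) plane."""

    volume: np.ndarray   # mL
    pressure: np.ndarray # mmHg

    def __post_init__(self):
        if len(self.volume) != len(self.pressure):
            raise ValueError("volume and pressure must have equal length")
        if len(self.volume) < 100:
            raise ValueError("a PV loop needs at least 100 samples per beat")

    def closure_gap(self) -> float:
        dv = self.volume[0] - self.volume[-1]
        dp = self.pressure[0] - self.pressure[-1]
        return float(np.hypot(dv, dp))


@dataclass
class HemodynamicSummary:
    """Beat-averaged outputs of one scenario run (pressures mmHg, flows L/min)."""

    map: float
    aortic_systolic: float
    aortic_diastolic: float
    pcwp: float
    cvp: float
    co_native: float
    co_total: float
    ci: float
    hr: float
    lv_edv: float
    lv_esv: float
    lv_sv: float
    lv_ef: float
    stroke_work: float
    potential_energy: float
    pva: float
    mvo2: float
    coronary_flow: float
    ecmo_flow: float
    impella_flow: float
    asd_flow: float
    vent_flow: float
    ejecting: bool
    aortic_open_fraction: float
    converged: bool

    def to_dict(self) -> dict:
        return asdict(self)


def detect_cycles(result: SimulationResult) -> np.ndarray:
    """Sample indices of beat boundaries (activation onsets, model-driven).

    The simulator knows its own phase, so boundaries lie at exact multiples
    of the cycle length on the sample grid.
    """
    spb = result.samples_per_beat
    n = len(result.time)
    if n - 1 < spb:
        raise ValueError("result shorter than one full beat")
    return np.arange(0, n, spb)


def extract_loop(result: SimulationResult, chamber: str = "lv") -> PVLoop:
    """PV loop of the final complete beat for one chamber."""
    sl = result.last_beat_slice()
    return PVLoop(
        volume=result.node("v", chamber)[sl].copy(),
        pressure=result.node("p", chamber)[sl].copy(),
    )


def stroke_work(loop: PVLoop) -> float:
    """Enclosed PV-loop area (shoelace), mmHg*mL; positive for ejecting loops.

    An ejecting beat traverses the (V, P) plane counterclockwise (fill at low
    pressure, eject at high pressure), which the shoelace sum returns as a
    positive area. A degenerate nonejecting loop has zero area.
    """
    span = max(np.ptp(loop.volume), 1.0) + max(np.ptp(loop.pressure), 1.0)
    if loop.closure_gap() > 0.05 * span:
        raise ValueError(
            f"PV loop is not closed (gap {loop.closure_gap():.3g})"
        )
    v, p = loop.volume, loop.pressure
    # signed shoelace area; CCW in (V, P) -> positive
    return float(0.5 * np.sum((v - np.roll(v, 1)) * (p + np.roll(p, 1)))) * -1.0


def stroke_work_trapezoid(loop: PVLoop) -> float:
    """Independent loop-area oracle: -cumulative trapezoid of P dV around the loop."""
    v = np.append(loop.volume, loop.volume[0])
    p = np.append(loop.pressure, loop.pressure[0])
    return float(-np.trapezoid(p, v))


def pva_mvo2(loop: PVLoop, chamber: ChamberParams, hr: float,
             lv_mass_g: float = LV_MASS_G) -> dict[str, float]:
    """Stroke work, potential energy, PVA and the linear MVO2 estimate.

    End systole is located at the sample of maximal elastance P/(V - V0)
    (robust for nonejecting loops). PE is the area between the ESPVR and the
    EDPVR from V0 to the end-systolic volume:
    PE = Pes*(Ves - V0)/2 - integral of the EDPVR. MVO2 (mL O2/min) uses the
    Suga linear PVA relation per 100 g of LV mass.
    """
    sw = stroke_work(loop)
    x = loop.volume - chamber.v0
    with np.errstate(divide="ignore", invalid="ignore"):
        elast = np.where(x > 1e-9, loop.pressure / x, -np.inf)
    i_es = int(np.argmax(elast))
    pes = float(loop.pressure[i_es])
    ves = float(loop.volume[i_es])
    if ves <= chamber.v0:
        warnings.warn("end-systolic volume at or below V0; PE clamped to 0")
        pe = 0.0
    else:
        pe = 0.5 * pes * (ves - chamber.v0) - edpvr_integral(chamber, chamber.v0, ves)
        pe = max(pe, 0.0)
    pva = sw + pe
    mvo2 = (A_MVO2 * pva * 100.0 / lv_mass_g + B_MVO2) * (lv_mass_g / 100.0) * hr
    return {"sw": sw, "pe": pe, "pva": pva, "mvo2": mvo2,
            "pes": pes, "ves": ves}


def ejection_status(result: SimulationResult) -> dict:
    """Ejection flag, aortic-valve open fraction and per-beat ejected volume.

    The LV counts as nonejecting when the forward aortic-valve volume per
    beat falls below 1 mL (a strict zero is unattainable with a finite
    closed-valve resistance).
    """
    sl = result.last_beat_slice()
    t = result.time[sl]
    q_ao = result.flow("q_aortic")[sl]
    p_lv = result.node("p", "lv")[sl]
    p_aa = result.node("p", "asc_ao")[sl]
    forward = np.trapezoid(np.clip(q_ao, 0.0, None), t)
    open_frac = float(np.mean(p_lv > p_aa))
    return {
        "ejecting": bool(forward >= NONEJECTION_THRESHOLD_ML),
        "aortic_open_fraction": open_frac,
        "ejected_volume": float(forward),
    }


def _beat_mean(t: np.ndarray, x: np.ndarray) -> float:
    return float(np.trapezoid(x, t) / (t[-1] - t[0]))


def summarize(result: SimulationResult, model=None) -> HemodynamicSummary:
    """All beat-averaged outputs, computed on the final converged beat."""
    if model is None:
        model = result.model
    if not result.converged:
        warnings.warn("summarizing a non-converged run; metrics may drift")
    sl = result.last_beat_slice()
    t = result.time[sl]
    hr = model.hr

    p_aa = result.node("p", "asc_ao")[sl]
    map_ = _beat_mean(t, p_aa)
    pcwp = _beat_mean(t, result.node("p", "pulm_ven")[sl])
    cvp = _beat_mean(t, result.node("p", "ra")[sl])

    q_ao = result.flow("q_aortic")[sl]
    sv_valve = float(np.trapezoid(q_ao, t))              # mL per beat
    co_native = sv_valve * hr / 1000.0                   # L/min
    ecmo = _beat_mean(t, result.flow("q_ecmo")[sl]) * LMIN_PER_MLS
    impella = _beat_mean(t, result.flow("q_impella")[sl]) * LMIN_PER_MLS
    co_total = co_native + ecmo + impella

    v_lv = result.node("v", "lv")[sl]
    edv = float(v_lv.max())
    esv = float(v_lv.min())
    sv = edv - esv
    ef = sv / edv if edv > 0 else 0.0

    loop = extract_loop(result, "lv")
    energetics = pva_mvo2(loop, model.chambers["LV"], hr)
    status = ejection_status(result)

    return HemodynamicSummary(
        map=map_,
        aortic_systolic=float(p_aa.max()),
        aortic_diastolic=float(p_aa.min()),
        pcwp=pcwp,
        cvp=cvp,
        co_native=co_native,
        co_total=co_total,
        ci=co_total / model.bsa,
        hr=hr,
        lv_edv=edv,
        lv_esv=esv,
        lv_sv=sv,
        lv_ef=ef,
        stroke_work=energetics["sw"],
        potential_energy=energetics["pe"],
        pva=energetics["pva"],
        mvo2=energetics["mvo2"],
        coronary_flow=_beat_mean(t, result.flow("q_coronary")[sl]) * LMIN_PER_MLS,
        ecmo_flow=ecmo,
        impella_flow=impella,
        asd_flow=_beat_mean(t, result.flow("q_asd")[sl]) * LMIN_PER_MLS,
        vent_flow=_beat_mean(t, result.flow("q_vent")[sl]) * LMIN_PER_MLS,
        ejecting=status["ejecting"],
        aortic_open_fraction=status["aortic_open_fraction"],
        converged=result.converged,
    )
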