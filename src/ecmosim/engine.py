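"""Closed-loop integration of the circulation model.

The model is a stiff-ish but well-conditioned ODE system in the node volumes
(11 states) integrated with fixed-step RK4 (default dt = 0.5 ms); oxygen
saturations are advected alongside with an explicit Euler step using the
start-of-step flows. Runs proceed beat by beat to a periodic steady state,
detected as a beat-to-beat end-of-beat volume change below tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as _k
from ._kernels import AUX_NAMES, EDGE_NAMES, N_FLOWS, N_NODES, NODE_NAMES
from .parameters import CirculationModel

#: node index of each chamber in the packed state vector
CHAMBER_NODE = {"RA": _k.RA, "RV": _k.RV, "LA": _k.LA, "LV": _k.LV}
#: node index of each vascular compartment
COMPARTMENT_NODE = {
    "asc_ao": _k.AA, "desc_ao": _k.AD, "sys_art": _k.SA, "sys_ven": _k.SV,
    "pa": _k.PA, "pulm_cap": _k.PC, "pulm_ven": _k.PVN,
}
VENT_SITE_NODE = {"LA": _k.LA, "PA": _k.PA, "LV": _k.LV}

SIGNAL_NAMES = EDGE_NAMES + AUX_NAMES


class SolverInstabilityError(RuntimeError):
    """Raised when the integrator produces a non-finite or negative volume."""


class ConvergenceError(RuntimeError):
    """Raised when no periodic steady state is reached within max_beats."""


class ConfigurationError(ValueError):
    """Raised for structurally invalid model/device configurations."""


def pack_model(model: CirculationModel):
    """Flatten a CirculationModel into the kernel's array layout."""
    node_par = np.zeros((N_NODES, 9))
    for name, idx in CHAMBER_NODE.items():
        ch = model.chambers[name]
        node_par[idx, _k.NP_IS_CHAMBER] = 1.0
        node_par[idx, _k.NP_EES] = ch.ees
        node_par[idx, _k.NP_V0] = ch.v0
        node_par[idx, _k.NP_A] = ch.passive_a
        node_par[idx, _k.NP_B] = ch.passive_b
        node_par[idx, _k.NP_ONSET] = ch.act_onset
        node_par[idx, _k.NP_DUR] = ch.act_duration
    for name, idx in COMPARTMENT_NODE.items():
        comp = model.compartments[name]
        node_par[idx, _k.NP_C] = comp.c
        node_par[idx, _k.NP_VU] = comp.vu

    # per-edge resistances: compartment outflow resistances, valves override
    e_ro = np.empty(_k.N_EDGES)
    e_rc = np.empty(_k.N_EDGES)
    comp_edge = {
        "pulm_ven": 0, "asc_ao": 3, "desc_ao": 4, "sys_art": 5,
        "sys_ven": 6, "pa": 9, "pulm_cap": 10,
    }
    for name, e in comp_edge.items():
        r = model.compartments[name].r_out
        if r <= 0:
            raise ConfigurationError(f"compartment {name} needs r_out > 0 (dangling node)")
        e_ro[e] = r
        e_rc[e] = r
    for vname, e in _k.VALVE_EDGE.items():
        valve = model.valves[vname]
        e_ro[e] = valve.r_open
        e_rc[e] = valve.r_closed

    dev = np.zeros(_k.N_DEV)
    dev[_k.D_VENT_SITE] = -1.0
    dev[_k.D_COR_R] = model.coronary_r
    dev[_k.D_COR_KIM] = model.coronary_im_frac
    dev[_k.D_HB] = model.hemoglobin
    dev[_k.D_VO2] = model.vo2
    dev[_k.D_LUNG_SAT] = model.lung_saturation
    ds = model.devices
    if ds.ecmo is not None:
        dev[_k.D_ECMO_ON] = 1.0
        dev[_k.D_ECMO_Q] = ds.ecmo.pump_flow * 1000.0 / 60.0
        dev[_k.D_ECMO_RD] = ds.ecmo.drainage_cannula_r
        dev[_k.D_ECMO_PLIM] = ds.ecmo.suction_limit
        dev[_k.D_ECMO_W] = ds.ecmo.suction_width
        dev[_k.D_ECMO_SAT] = ds.ecmo.oxygenator_outlet_saturation
    if ds.impella is not None:
        dev[_k.D_IMP_Q] = ds.impella.flow_setpoint * 1000.0 / 60.0
        dev[_k.D_IMP_PLIM] = ds.impella.max_negative_inlet_pressure
        dev[_k.D_IMP_W] = ds.impella.derate_width
    if ds.iabp is not None and ds.iabp.balloon_volume > 0:
        dev[_k.D_IABP_ON] = 1.0
        dev[_k.D_IABP_V] = ds.iabp.balloon_volume
        dev[_k.D_IABP_LEAD] = ds.iabp.deflate_lead
        dev[_k.D_IABP_TR] = ds.iabp.transition_time
        lv = model.chambers["LV"]
        diastole = model.period - lv.act_duration
        if diastole < 2.0 * ds.iabp.transition_time:
            raise ConfigurationError(
                "diastole too short for the IABP inflation/deflation ramps"
            )
    if ds.asd is not None:
        dev[_k.D_ASD_K] = ds.asd.flow_coefficient
    if ds.vent is not None:
        if ds.ecmo is None:
            raise ConfigurationError("a vent cannula requires an active ECMO circuit")
        r_total = ds.vent.total_r(model.viscosity)
        if r_total <= ds.ecmo.drainage_cannula_r:
            raise ConfigurationError(
                "vent resistance must exceed the ECMO drainage-cannula resistance"
            )
        dev[_k.D_VENT_SITE] = float(VENT_SITE_NODE[ds.vent.site])
        dev[_k.D_VENT_R] = r_total
    return node_par, e_ro, e_rc, dev


def initial_volumes(model: CirculationModel, p0: float = 8.0) -> np.ndarray:
    """Deterministic initial volume distribution at a uniform filling pressure.

    Each compartment/chamber is set to the volume giving passive pressure
    ``p0``; the remaining blood volume is placed in the systemic-venous pool.
    """
    v = np.zeros(N_NODES)
    for name, idx in COMPARTMENT_NODE.items():
        comp = model.compartments[name]
        v[idx] = comp.vu + p0 * comp.c
    for name, idx in CHAMBER_NODE.items():
        ch = model.chambers[name]
        v[idx] = ch.v0 + math.log(p0 / ch.passive_a + 1.0) / ch.passive_b
    residual = model.total_blood_volume - v.sum()
    v[_k.SV] += residual
    if v[_k.SV] <= model.compartments["sys_ven"].vu * 0.2:
        raise ConfigurationError(
            "infeasible blood volume: systemic venous pool would be emptied"
        )
    return v


def initial_saturations(model: CirculationModel) -> np.ndarray:
    s = np.full(N_NODES, 0.95)
    for idx in (_k.RA, _k.RV, _k.PA, _k.SV):
        s[idx] = 0.72
    s[_k.PC] = model.lung_saturation
    return s


@dataclass
class SimulationResult:
    """Uniformly sampled time series of one run plus solver diagnostics."""

    time: np.ndarray                 # (n,), s
    volumes: np.ndarray              # (n, 11), mL
    pressures: np.ndarray            # (n, 11), mmHg
    flows: np.ndarray                # (n, N_FLOWS), mL/s (aux slots: see SIGNAL_NAMES)
    saturations: np.ndarray          # (n, 11), fraction
    beat_end_volumes: np.ndarray     # (n_beats, 11)
    model: CirculationModel
    dt: float
    dt_out: float
    n_beats: int
    converged_beat: Optional[int]
    suction_events: int = 0
    scenario_name: Optional[str] = None

    @property
    def converged(self) -> bool:
        return self.converged_beat is not None

    @property
    def samples_per_beat(self) -> int:
        return int(round(self.model.period / self.dt_out))

    def node(self, kind: str, name: str) -> np.ndarray:
        """Signal by node name: kind in {'p', 'v', 's'}."""
        idx = NODE_NAMES.index(name)
        return {"p": self.pressures, "v": self.volumes, "s": self.saturations}[kind][:, idx]

    def flow(self, name: str) -> np.ndarray:
        return self.flows[:, SIGNAL_NAMES.index(name)]

    def last_beat_slice(self) -> slice:
        """Index slice of the final complete beat (boundary to boundary, inclusive)."""
        spb = self.samples_per_beat
        end = (len(self.time) - 1) // spb * spb
        if end < spb:
            raise ValueError("result contains less than one full beat")
        return slice(end - spb, end + 1)

    @property
    def total_volume_drift(self) -> float:
        """Max relative total-blood-volume drift per simulated minute."""
        tot = self.volumes.sum(axis=1)
        dur_min = max((self.time[-1] - self.time[0]) / 60.0, 1e-9)
        return float(np.abs(tot - tot[0]).max() / tot[0] / dur_min)

    def to_frame(self):
        """Tidy DataFrame: one row per sample, one column per signal."""
        import pandas as pd

        data = {"time": self.time}
        for i, n in enumerate(NODE_NAMES):
            data[f"p_{n}"] = self.pressures[:, i]
        for i, n in enumerate(NODE_NAMES):
            data[f"v_{n}"] = self.volumes[:, i]
        for i, n in enumerate(SIGNAL_NAMES):
            data[n] = self.flows[:, i]
        for i, n in enumerate(NODE_NAMES):
            data[f"sat_{n}"] = self.saturations[:, i]
        return pd.DataFrame(data)


def derivatives(volumes: np.ndarray, t: float, model: CirculationModel,
                t_close: Optional[float] = None,
                t_open: Optional[float] = None) -> np.ndarray:
    """Mass-balance dV/dt (mL/s) for every node at state ``volumes``, time ``t``.

    Exposed for inspection and property testing; the integrator uses the same
    compiled kernel. The device source/sink terms appear once as sink and
    once as source, so the returned vector sums to zero to machine precision.
    """
    node_par, e_ro, e_rc, dev = pack_model(model)
    tc, to = _default_valve_events(model)
    if t_close is not None:
        tc = t_close
    if t_open is not None:
        to = t_open
    dv = np.empty(N_NODES)
    fl = np.empty(N_FLOWS)
    p = np.empty(N_NODES)
    _k.derivs(t, np.asarray(volumes, dtype=float), node_par, e_ro, e_rc, dev,
              model.period, tc, to, dv, fl, p)
    return dv


def _default_valve_events(model: CirculationModel) -> tuple[float, float]:
    """Initial guesses for aortic-valve closure/opening cycle times.

    Used for the first beat (and as the standing fallback when the LV never
    ejects): opening shortly after ventricular activation onset, closure at
    activation end.
    """
    lv = model.chambers["LV"]
    t_on = lv.act_onset * model.period
    t_open = t_on + 0.15 * lv.act_duration
    t_close = t_on + lv.act_duration
    return t_close % model.period, t_open % model.period


def _resolve_steps(model: CirculationModel, dt: float, dt_out: float):
    period = model.period
    steps_per_beat = max(int(round(period / dt)), 4)
    dt_eff = period / steps_per_beat
    stride = max(int(round(dt_out / dt_eff)), 1)
    while steps_per_beat % stride != 0:
        stride -= 1
    return dt_eff, steps_per_beat, stride


def _run(model: CirculationModel, max_beats: int, dt: float, dt_out: float,
         conv_tol: float, v0: Optional[np.ndarray] = None,
         s0: Optional[np.ndarray] = None) -> SimulationResult:
    if max_beats < 1:
        raise ValueError("need at least one beat")
    node_par, e_ro, e_rc, dev = pack_model(model)
    dt_eff, _, stride = _resolve_steps(model, dt, dt_out)
    vols0 = initial_volumes(model) if v0 is None else np.asarray(v0, dtype=float)
    sats0 = initial_saturations(model) if s0 is None else np.asarray(s0, dtype=float)
    t_close0, t_open0 = _default_valve_events(model)

    (status, err_node, err_time, n_samp, n_beats, conv_beat,
     t_out, vols_out, press_out, flows_out, sats_out, beat_end,
     suction_events) = _k.run_model(
        vols0, sats0, node_par, e_ro, e_rc, dev, model.period, dt_eff,
        max_beats, stride, conv_tol, t_open0, t_close0,
    )

    if status == _k.ERR_NONFINITE:
        raise SolverInstabilityError(
            f"non-finite volume in node '{NODE_NAMES[err_node]}' at t={err_time:.4f}s; "
            "reduce dt or check parameters"
        )
    if status == _k.ERR_NEGATIVE_VOLUME:
        raise SolverInstabilityError(
            f"compartment '{NODE_NAMES[err_node]}' emptied (V<0) at t={err_time:.4f}s"
        )

    return SimulationResult(
        time=t_out[:n_samp].copy(),
        volumes=vols_out[:n_samp].copy(),
        pressures=press_out[:n_samp].copy(),
        flows=flows_out[:n_samp].copy(),
        saturations=sats_out[:n_samp].copy(),
        beat_end_volumes=beat_end[:n_beats].copy(),
        model=model,
        dt=dt_eff,
        dt_out=dt_eff * stride,
        n_beats=n_beats,
        converged_beat=conv_beat if conv_beat >= 0 else None,
        suction_events=int(suction_events),
    )


def integrate(model: CirculationModel, duration_beats: int,
              dt: float = 5e-4, dt_out: float = 1e-3,
              v0: Optional[np.ndarray] = None,
              s0: Optional[np.ndarray] = None) -> SimulationResult:
    """Integrate for a fixed number of beats (no early stopping)."""
    return _run(model, duration_beats, dt, dt_out, conv_tol=-1.0, v0=v0, s0=s0)


def steady_state(model: CirculationModel, max_beats: int = 200, tol: float = 0.1,
                 dt: float = 5e-4, dt_out: float = 1e-3,
                 v0: Optional[np.ndarray] = None,
                 s0: Optional[np.ndarray] = None) -> SimulationResult:
    """Run until the periodic steady state (beat-to-beat volume change < tol mL).

    Returns the full run with the converged beat marked; all summary metrics
    are computed on that final beat. Raises ConvergenceError with the drift
    trace if max_beats is exhausted.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    res = _run(model, max_beats, dt, dt_out, conv_tol=tol, v0=v0, s0=s0)
    if not res.converged:
        drift = np.abs(np.diff(res.beat_end_volumes, axis=0)).max(axis=1)
        raise ConvergenceError(
            f"no steady state within {max_beats} beats; "
            f"last beat-to-beat volume changes (mL): {drift[-5:].round(4).tolist()}"
        )
    return res
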