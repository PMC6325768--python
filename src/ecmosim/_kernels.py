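"""Compiled numerical kernels (numba) for the circulation ODEs.

Node layout (index constants below): four elastance chambers and seven
compliance compartments. Generic resistive/valve edges connect them in one
closed loop; the coronary branch, ECMO, Impella, ASD and vent enter as extra
source/sink terms so that the sum of all dV/dt is zero by construction.

Everything here operates on flat float64 arrays packed by
:func:`ecmosim.engine.pack_model`; the scalar functions are also the single
source of truth for the pure-Python device/elastance wrappers.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# node indices
RA, RV, PA, PC, PVN, LA, LV, AA, AD, SA, SV = range(11)
N_NODES = 11

NODE_NAMES = (
    "ra", "rv", "pa", "pulm_cap", "pulm_ven", "la", "lv",
    "asc_ao", "desc_ao", "sys_art", "sys_ven",
)

# generic edges: (src, dst); resistances supplied per edge
E_SRC = np.array([PVN, LA, LV, AA, AD, SA, SV, RA, RV, PA, PC], dtype=np.int64)
E_DST = np.array([LA, LV, AA, AD, SA, SV, RA, RV, PA, PC, PVN], dtype=np.int64)
N_EDGES = 11

EDGE_NAMES = (
    "q_pulm_ven", "q_mitral", "q_aortic", "q_asc_desc", "q_desc_art",
    "q_systemic", "q_ven_return", "q_tricuspid", "q_pulmonary",
    "q_pa_cap", "q_cap_ven",
)
VALVE_EDGE = {"mitral": 1, "aortic": 2, "tricuspid": 7, "pulmonary": 8}

# auxiliary signal slots appended after the generic edges
AUX_NAMES = (
    "q_coronary", "q_ecmo", "q_vent", "q_impella", "q_asd",
    "p_pump_inlet", "iabp_volume",
)
N_FLOWS = N_EDGES + len(AUX_NAMES)
IX_QCOR, IX_QECMO, IX_QVENT, IX_QIMP, IX_QASD, IX_PINLET, IX_BAL = range(
    N_EDGES, N_FLOWS
)

# node_par columns
NP_IS_CHAMBER, NP_EES, NP_V0, NP_A, NP_B, NP_ONSET, NP_DUR, NP_C, NP_VU = range(9)

# device parameter vector indices
(D_ECMO_ON, D_ECMO_Q, D_ECMO_RD, D_ECMO_PLIM, D_ECMO_W, D_ECMO_SAT,
 D_IMP_Q, D_IMP_PLIM, D_IMP_W,
 D_IABP_ON, D_IABP_V, D_IABP_LEAD, D_IABP_TR,
 D_ASD_K,
 D_VENT_SITE, D_VENT_R,
 D_COR_R, D_COR_KIM,
 D_HB, D_VO2, D_LUNG_SAT) = range(21)
N_DEV = 21

# run_model status codes
OK_CONVERGED = 0
OK_MAXBEATS = 1
ERR_NEGATIVE_VOLUME = 2
ERR_NONFINITE = 3


@njit(cache=True)
def activation(t_cycle, period, onset_frac, duration):
    """Squared-sine activation: 0 outside the window, peak exactly 1."""
    x = t_cycle - onset_frac * period
    if x < 0.0:
        x += period
    if x < duration:
        s = math.sin(math.pi * x / duration)
        return s * s
    return 0.0


@njit(cache=True)
def chamber_pressure_scalar(ees, v0, a, b, act, v):
    x = v - v0
    return act * ees * x + a * math.expm1(b * x)


@njit(cache=True)
def valve_flow_scalar(p_up, p_down, r_open, r_closed):
    dp = p_up - p_down
    if dp > 0.0:
        return dp / r_open
    return dp / r_closed


@njit(cache=True)
def asd_flow_scalar(p_la, p_ra, k):
    dp = p_la - p_ra
    if dp >= 0.0:
        return k * math.sqrt(dp)
    return -k * math.sqrt(-dp)


@njit(cache=True)
def derated_flow(q_set, p_inlet, p_limit, width):
    """Ideal flow source with a linear suction derating below p_limit."""
    if p_inlet >= p_limit:
        return q_set
    f = 1.0 + (p_inlet - p_limit) / width
    if f < 0.0:
        f = 0.0
    return q_set * f


@njit(cache=True)
def balloon_volume(t_cycle, period, vb, t_close, t_open, lead, tr):
    """IABP balloon volume at cycle time t_cycle (raised-cosine ramps)."""
    if vb <= 0.0:
        return 0.0
    u = t_cycle - t_close
    if u < 0.0:
        u += period
    # deflation start, measured from inflation start
    d = ((t_open - lead - tr) - t_close) % period
    if d < tr:
        d = tr  # degenerate guard: keep at least the inflation ramp
    if u < tr:
        return vb * 0.5 * (1.0 - math.cos(math.pi * u / tr))
    if u < d:
        return vb
    if u < d + tr:
        return vb * 0.5 * (1.0 + math.cos(math.pi * (u - d) / tr))
    return 0.0


@njit(cache=True)
def pressures(vols, t_cycle, period, node_par, bal_vol, out):
    for i in range(N_NODES):
        if node_par[i, NP_IS_CHAMBER] > 0.5:
            act = activation(t_cycle, period, node_par[i, NP_ONSET], node_par[i, NP_DUR])
            out[i] = chamber_pressure_scalar(
                node_par[i, NP_EES], node_par[i, NP_V0],
                node_par[i, NP_A], node_par[i, NP_B], act, vols[i],
            )
        else:
            v = vols[i]
            if i == AD:
                v += bal_vol
            out[i] = (v - node_par[i, NP_VU]) / node_par[i, NP_C]
    return out


@njit(cache=True)
def derivs(t, vols, node_par, e_ro, e_rc, dev, period,
           t_close, t_open, dv, flows, p):
    """Mass-balance derivatives dV/dt for every node plus auxiliary signals.

    ``flows`` (length N_FLOWS) and ``p`` (length N_NODES) are scratch outputs.
    The sum of dv is zero by construction: every flow enters once as a sink
    and once as a source (vent drainage returns via the ECMO circuit).
    """
    t_cycle = t % period
    bal = 0.0
    if dev[D_IABP_ON] > 0.5:
        bal = balloon_volume(t_cycle, period, dev[D_IABP_V], t_close, t_open,
                             dev[D_IABP_LEAD], dev[D_IABP_TR])
    pressures(vols, t_cycle, period, node_par, bal, p)

    for i in range(N_NODES):
        dv[i] = 0.0
    for e in range(N_EDGES):
        q = valve_flow_scalar(p[E_SRC[e]], p[E_DST[e]], e_ro[e], e_rc[e])
        flows[e] = q
        dv[E_SRC[e]] -= q
        dv[E_DST[e]] += q

    # coronary branch: aortic root -> RA, throttled by intramyocardial pressure
    q_cor = (p[AA] - p[RA] - dev[D_COR_KIM] * p[LV]) / dev[D_COR_R]
    if q_cor < 0.0:
        q_cor = 0.0
    flows[IX_QCOR] = q_cor
    dv[AA] -= q_cor
    dv[RA] += q_cor

    # VA ECMO + vent (vent drains into the pump-inlet node)
    q_pump = 0.0
    q_vent = 0.0
    p_inlet = p[RA]
    if dev[D_ECMO_ON] > 0.5:
        q_pump = derated_flow(dev[D_ECMO_Q], p[RA], dev[D_ECMO_PLIM], dev[D_ECMO_W])
        site = int(dev[D_VENT_SITE])
        if site >= 0:
            rd = dev[D_ECMO_RD]
            rv_ = dev[D_VENT_R]
            q_vent = (p[site] - p[RA] + q_pump * rd) / (rv_ - rd)
            if q_vent < 0.0:
                q_vent = 0.0
            else:
                dv[site] -= q_vent
        p_inlet = p[RA] - (q_pump + q_vent) * dev[D_ECMO_RD]
        dv[RA] -= q_pump
        dv[AD] += q_pump + q_vent
    flows[IX_QECMO] = q_pump
    flows[IX_QVENT] = q_vent
    flows[IX_PINLET] = p_inlet

    # Impella: LV -> ascending aorta
    q_imp = 0.0
    if dev[D_IMP_Q] > 0.0:
        q_imp = derated_flow(dev[D_IMP_Q], p[LV], dev[D_IMP_PLIM], dev[D_IMP_W])
        dv[LV] -= q_imp
        dv[AA] += q_imp
    flows[IX_QIMP] = q_imp

    # atrial septostomy: LA <-> RA orifice
    q_asd = 0.0
    if dev[D_ASD_K] > 0.0:
        q_asd = asd_flow_scalar(p[LA], p[RA], dev[D_ASD_K])
        dv[LA] -= q_asd
        dv[RA] += q_asd
    flows[IX_QASD] = q_asd

    flows[IX_BAL] = bal
    return dv


@njit(cache=True)
def _advect_saturations(sats, vols_new, flows, dev, dt):
    """Explicit-Euler O2 advection with perfect mixing and upwinding.

    Boundary conditions: pulmonary-capillary saturation is pinned to the lung
    saturation parameter (gas exchange), the ECMO return arrives fully
    oxygenated at the oxygenator outlet saturation, and systemic O2
    extraction (VO2) is applied in the systemic-venous node.
    """
    qin = np.zeros(N_NODES)
    o2in = np.zeros(N_NODES)
    for e in range(N_EDGES):
        q = flows[e]
        if q > 0.0:
            qin[E_DST[e]] += q
            o2in[E_DST[e]] += q * sats[E_SRC[e]]
        elif q < 0.0:
            qin[E_SRC[e]] += -q
            o2in[E_SRC[e]] += -q * sats[E_DST[e]]
    q = flows[IX_QCOR]
    if q > 0.0:
        qin[RA] += q
        o2in[RA] += q * sats[AA]
    if dev[D_ECMO_ON] > 0.5:
        q = flows[IX_QECMO] + flows[IX_QVENT]
        qin[AD] += q
        o2in[AD] += q * dev[D_ECMO_SAT]
    q = flows[IX_QIMP]
    if q > 0.0:
        qin[AA] += q
        o2in[AA] += q * sats[LV]
    q = flows[IX_QASD]
    if q > 0.0:
        qin[RA] += q
        o2in[RA] += q * sats[LA]
    elif q < 0.0:
        qin[LA] += -q
        o2in[LA] += -q * sats[RA]

    capacity = 0.0134 * dev[D_HB]  # mL O2 per mL blood at saturation 1
    vo2_rate = dev[D_VO2] / 60.0   # mL O2 / s
    for i in range(N_NODES):
        v = vols_new[i]
        if v < 1e-9:
            continue
        ds = (o2in[i] - qin[i] * sats[i]) / v
        s = sats[i] + dt * ds
        if i == SV and capacity > 0.0:
            s -= dt * vo2_rate / (capacity * v)
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
        sats[i] = s
    sats[PC] = dev[D_LUNG_SAT]


@njit(cache=True)
def run_model(vols0, sats0, node_par, e_ro, e_rc, dev, period, dt,
              max_beats, stride, conv_tol, t_open0, t_close0):
    """Fixed-step RK4 integration of the circulation for up to max_beats.

    Samples every ``stride`` steps. If ``conv_tol`` > 0, stops after the
    first beat whose end-of-beat volume vector differs from the previous
    beat's by less than conv_tol (max-abs, mL).

    Returns (status, err_node, err_time, n_samples, n_beats, conv_beat,
    t_out, vols_out, press_out, flows_out, sats_out, beat_end_vols,
    suction_events).
    """
    steps_per_beat = int(round(period / dt))
    n_steps = steps_per_beat * max_beats
    n_samp_max = n_steps // stride + 1

    t_out = np.empty(n_samp_max)
    vols_out = np.empty((n_samp_max, N_NODES))
    press_out = np.empty((n_samp_max, N_NODES))
    flows_out = np.empty((n_samp_max, N_FLOWS))
    sats_out = np.empty((n_samp_max, N_NODES))
    beat_end = np.empty((max_beats, N_NODES))

    v = vols0.copy()
    s = sats0.copy()
    prev_end = vols0.copy()

    dv1 = np.empty(N_NODES); dv2 = np.empty(N_NODES)
    dv3 = np.empty(N_NODES); dv4 = np.empty(N_NODES)
    fl = np.empty(N_FLOWS); fl_scratch = np.empty(N_FLOWS)
    p = np.empty(N_NODES); p_scratch = np.empty(N_NODES)
    vtmp = np.empty(N_NODES)

    t_open = t_open0
    t_close = t_close0
    seen_open = False
    seen_close = False
    new_open = -1.0
    new_close = -1.0

    status = OK_MAXBEATS
    err_node = -1
    err_time = -1.0
    conv_beat = -1
    n_samp = 0
    n_beats = 0
    suction_events = 0
    ecmo_setpoint = dev[D_ECMO_Q]
    imp_setpoint = dev[D_IMP_Q]

    for step in range(n_steps):
        t = step * dt
        t_cycle = t % period

        derivs(t, v, node_par, e_ro, e_rc, dev, period, t_close, t_open, dv1, fl, p)

        if step % stride == 0:
            t_out[n_samp] = t
            for i in range(N_NODES):
                vols_out[n_samp, i] = v[i]
                press_out[n_samp, i] = p[i]
                sats_out[n_samp, i] = s[i]
            for i in range(N_FLOWS):
                flows_out[n_samp, i] = fl[i]
            n_samp += 1

        # aortic-valve event detection from the stage-1 evaluation
        q_ao = fl[2]
        if not seen_open and q_ao > 1e-9:
            seen_open = True
            new_open = t_cycle
        elif seen_open and not seen_close and q_ao <= 0.0:
            seen_close = True
            new_close = t_cycle
        if dev[D_ECMO_ON] > 0.5 and fl[IX_QECMO] < ecmo_setpoint - 1e-9:
            suction_events += 1
        if imp_setpoint > 0.0 and fl[IX_QIMP] < imp_setpoint - 1e-9:
            suction_events += 1

        # RK4 stages
        for i in range(N_NODES):
            vtmp[i] = v[i] + 0.5 * dt * dv1[i]
        derivs(t + 0.5 * dt, vtmp, node_par, e_ro, e_rc, dev, period,
               t_close, t_open, dv2, fl_scratch, p_scratch)
        for i in range(N_NODES):
            vtmp[i] = v[i] + 0.5 * dt * dv2[i]
        derivs(t + 0.5 * dt, vtmp, node_par, e_ro, e_rc, dev, period,
               t_close, t_open, dv3, fl_scratch, p_scratch)
        for i in range(N_NODES):
            vtmp[i] = v[i] + dt * dv3[i]
        derivs(t + dt, vtmp, node_par, e_ro, e_rc, dev, period,
               t_close, t_open, dv4, fl_scratch, p_scratch)
        for i in range(N_NODES):
            v[i] += dt / 6.0 * (dv1[i] + 2.0 * dv2[i] + 2.0 * dv3[i] + dv4[i])

        _advect_saturations(s, v, fl, dev, dt)

        for i in range(N_NODES):
            vi = v[i]
            if not math.isfinite(vi):
                status = ERR_NONFINITE
                err_node = i
                err_time = t + dt
                break
            if vi < 0.0:
                status = ERR_NEGATIVE_VOLUME
                err_node = i
                err_time = t + dt
                break
        if status >= ERR_NEGATIVE_VOLUME:
            break

        if (step + 1) % steps_per_beat == 0:
            for i in range(N_NODES):
                beat_end[n_beats, i] = v[i]
            dmax = 0.0
            for i in range(N_NODES):
                d = abs(v[i] - prev_end[i])
                if d > dmax:
                    dmax = d
            for i in range(N_NODES):
                prev_end[i] = v[i]
            n_beats += 1
            if seen_open and seen_close:
                t_open = new_open
                t_close = new_close
            seen_open = False
            seen_close = False
            if conv_tol > 0.0 and dmax < conv_tol:
                conv_beat = n_beats - 1
                status = OK_CONVERGED
                break

    if status <= OK_MAXBEATS and n_samp < n_samp_max:
        # close the final beat with one extra sample at its boundary
        t_end = (step + 1) * dt
        derivs(t_end, v, node_par, e_ro, e_rc, dev, period, t_close, t_open,
               dv1, fl, p)
        t_out[n_samp] = t_end
        for i in range(N_NODES):
            vols_out[n_samp, i] = v[i]
            press_out[n_samp, i] = p[i]
            sats_out[n_samp, i] = s[i]
        for i in range(N_FLOWS):
            flows_out[n_samp, i] = fl[i]
        n_samp += 1

    return (status, err_node, err_time, n_samp, n_beats, conv_beat,
            t_out, vols_out, press_out, flows_out, sats_out, beat_end,
            suction_events)
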