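"""Chamber mechanics: activation waveform and pressure-volume relation.

The chamber model follows the classical time-varying elastance formulation:
systolic pressure rises linearly with volume along the ESPVR (slope Ees,
intercept V0) scaled by a periodic activation function, on top of an
exponential passive EDPVR:

    P(V, t) = a(t) * Ees * (V - V0) + A * (exp(B * (V - V0)) - 1)

with a squared-sine activation a(t) that rises from 0 to exactly 1 and back
within the activation window.
"""

from __future__ import annotations

from . import _kernels as _k
from .parameters import ChamberParams


def activation_waveform(t_cycle: float, chamber: ChamberParams, period: float) -> float:
    """Activation fraction in [0, 1] at cycle time ``t_cycle``.

    Zero outside the window [act_onset*period, act_onset*period +
    act_duration] (taken circularly), continuous, with peak value exactly 1
    at the window midpoint; the half-activation times are symmetric about
    the peak.
    """
    if chamber.act_duration >= period:
        raise ValueError(
            f"activation duration {chamber.act_duration}s must be shorter than "
            f"the cycle {period}s"
        )
    if not 0.0 <= t_cycle < period:
        t_cycle = t_cycle % period
    return _k.activation(t_cycle, period, chamber.act_onset, chamber.act_duration)


def chamber_pressure(chamber: ChamberParams, v: float, activation: float) -> float:
    """Instantaneous chamber pressure, mmHg.

    At activation 1 (and negligible passive term) pressure is linear in V
    with slope Ees; at activation 0 it equals the passive EDPVR value.
    Slightly negative pressures are allowed (diastolic suction below V0).
    """
    return _k.chamber_pressure_scalar(
        chamber.ees, chamber.v0, chamber.passive_a, chamber.passive_b,
        activation, v,
    )


def edpvr_integral(chamber: ChamberParams, v_from: float, v_to: float) -> float:
    """Area under the passive EDPVR between two volumes, mmHg*mL."""
    a, b, v0 = chamber.passive_a, chamber.passive_b, chamber.v0

    def antideriv(v: float) -> float:
        import math
        x = v - v0
        return a * (math.expm1(b * x) / b - x)

    return antideriv(v_to) - antideriv(v_from)


def valve_flow(p_up: float, p_down: float, valve) -> float:
    """Resistive diode valve flow, mL/s: forward through r_open, leak through r_closed."""
    return _k.valve_flow_scalar(p_up, p_down, valve.r_open, valve.r_closed)
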