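"""Mechanical circulatory-support device models.

Five devices can be attached to the circulation:

* **VA ECMO** — ideal flow source draining the right atrium through a
  cannula resistance and reinfusing retrograde into the descending aorta
  (peripheral bi-femoral configuration). Flow is fixed (0-4+ L/min) with a
  linear suction derating when RA pressure falls below a guard limit.
* **IABP** — a balloon in the descending aorta that inflates at aortic valve
  closure and deflates just before the next ejection; modelled as volume
  displacement inside the descending-aorta compartment.
* **Impella** — transvalvular microaxial pump, ideal flow source from the LV
  to the ascending aorta with a suction guard on LV pressure.
* **ASD (atrial septostomy)** — orifice flow between LA and RA following the
  quadratic orifice law Q = Cd * A * sqrt(2*|dP|/rho).
* **Vent** — a drainage cannula (LA, PA or LV) into the ECMO venous line,
  with Hagen-Poiseuille tubing resistance plus a lumped tip-loss term.

The pure flow functions here are the single source of truth for the device
physics; the integration kernel calls the same compiled scalar kernels (see
:mod:`ecmosim._kernels`).
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from . import _kernels as _k

MMHG_PER_PA = 1.0 / 133.322
MLS_PER_LMIN = 1000.0 / 60.0

#: Shared vent-cannula tip/valve loss resistance, mmHg*s/mL. Calibrated once
#: so that a direct LV vent on the LV-failure + ECMO 4 L/min state drains
#: ~1.9 L/min; the LA and PA vent flows then follow from the simulated
#: pressure gradients with no further tuning (see docs/methods.md).
DEFAULT_VENT_EXTRA_LOSS_R = 1.8906


class EcmoConfig(BaseModel):
    """VA ECMO circuit: fixed-flow pump, RA drainage, descending-aorta return."""

    model_config = ConfigDict(extra="forbid")

    pump_flow: float = Field(ge=0, description="Pump flow setpoint, L/min")
    drainage_cannula_r: float = Field(
        0.3, gt=0, description="Venous drainage cannula resistance, mmHg*s/mL"
    )
    oxygenator_outlet_saturation: float = Field(1.0, ge=0, le=1)
    circuit_volume: float = Field(500.0, ge=0, description="Priming volume of the circuit, mL")
    suction_limit: float = Field(
        -5.0, description="RA pressure below which pump flow is derated, mmHg"
    )
    suction_width: float = Field(
        5.0, gt=0, description="Pressure span over which derating goes from 1 to 0, mmHg"
    )

    # sites are fixed by the modelled cannulation and exposed read-only
    @property
    def drainage_site(self) -> str:
        return "RA"

    @property
    def return_site(self) -> str:
        return "desc_ao"


class IabpConfig(BaseModel):
    """Intra-aortic balloon pump (counterpulsation in the descending aorta)."""

    model_config = ConfigDict(extra="forbid")

    balloon_volume: float = Field(40.0, ge=0, description="Balloon volume, mL")
    deflate_lead: float = Field(
        0.05, gt=0, description="Deflation completed this long before next ejection, s"
    )
    transition_time: float = Field(0.05, gt=0, description="Inflation/deflation ramp time, s")

    @property
    def location(self) -> str:
        return "desc_ao"


class ImpellaConfig(BaseModel):
    """Transvalvular microaxial pump, LV inlet to ascending-aorta outlet."""

    model_config = ConfigDict(extra="forbid")

    flow_setpoint: float = Field(ge=0, le=6, description="Device flow, L/min")
    max_negative_inlet_pressure: float = Field(
        -5.0, description="LV suction guard: derate below this pressure, mmHg"
    )
    derate_width: float = Field(10.0, gt=0, description="Linear derating span, mmHg")

    @property
    def inlet(self) -> str:
        return "LV"

    @property
    def outlet(self) -> str:
        return "asc_ao"


class AsdConfig(BaseModel):
    """Created atrial septal defect, modelled as a sharp-edged orifice."""

    model_config = ConfigDict(extra="forbid")

    area: float = Field(gt=0, description="Defect area, cm^2")
    discharge_coefficient: float = Field(0.85, gt=0, le=1)
    blood_density: float = Field(1060.0, gt=0, description="kg/m^3")

    @property
    def flow_coefficient(self) -> float:
        """k such that Q [mL/s] = k * sqrt(|dP| [mmHg]), signed by dP."""
        # Q [m^3/s] = Cd * A[m^2] * sqrt(2 * dP[Pa] / rho); 1 mmHg = 133.322 Pa
        return (
            self.discharge_coefficient
            * self.area
            * 1e-4
            * math.sqrt(2.0 * 133.322 / self.blood_density)
            * 1e6
        )


VentSite = Literal["LA", "PA", "LV"]


class VentConfig(BaseModel):
    """Drainage cannula from LA, PA or LV into the ECMO venous (pump-inlet) line."""

    model_config = ConfigDict(extra="forbid")

    site: VentSite
    tubing_inner_diameter: float = Field(
        0.009525, gt=0, description="Tubing inner diameter, m (default 3/8 inch)"
    )
    tubing_length: float = Field(2.0, gt=0, description="Tubing length, m")
    extra_loss_r: float = Field(
        DEFAULT_VENT_EXTRA_LOSS_R, ge=0,
        description="Lumped cannula-tip loss resistance, mmHg*s/mL (shared calibration)",
    )

    def poiseuille_r(self, viscosity_mpas: float) -> float:
        """Hagen-Poiseuille tubing resistance, mmHg*s/mL."""
        return vent_poiseuille_resistance(
            self.tubing_inner_diameter, self.tubing_length, viscosity_mpas
        )

    def total_r(self, viscosity_mpas: float) -> float:
        return self.poiseuille_r(viscosity_mpas) + self.extra_loss_r


class DeviceSet(BaseModel):
    """The devices attached to a circulation model (all optional)."""

    model_config = ConfigDict(extra="forbid")

    ecmo: Optional[EcmoConfig] = None
    iabp: Optional[IabpConfig] = None
    impella: Optional[ImpellaConfig] = None
    asd: Optional[AsdConfig] = None
    vent: Optional[VentConfig] = None


# ---------------------------------------------------------------------------
# Pure flow functions (thin wrappers over the compiled scalar kernels)
# ---------------------------------------------------------------------------

def asd_flow(p_la: float, p_ra: float, cfg: AsdConfig) -> float:
    """Orifice shunt flow, mL/s, positive LA -> RA; antisymmetric in dP."""
    return _k.asd_flow_scalar(p_la, p_ra, cfg.flow_coefficient)


def impella_flow(p_lv: float, p_ao: float, cfg: ImpellaConfig) -> float:
    """Device flow, mL/s: the setpoint, linearly derated below the suction guard.

    Never negative (the pump cannot run backward); independent of the
    LV-aorta gradient otherwise (ideal flow source).
    """
    return _k.derated_flow(
        cfg.flow_setpoint * MLS_PER_LMIN,
        p_lv,
        cfg.max_negative_inlet_pressure,
        cfg.derate_width,
    )


def vent_poiseuille_resistance(diameter_m: float, length_m: float,
                               viscosity_mpas: float) -> float:
    """Hagen-Poiseuille resistance 8*mu*L/(pi*r^4) of the vent tubing, mmHg*s/mL."""
    r = diameter_m / 2.0
    r_si = 8.0 * viscosity_mpas * 1e-3 * length_m / (math.pi * r**4)  # Pa*s/m^3
    return r_si * MMHG_PER_PA * 1e-6


def vent_flow(p_source: float, p_pump_inlet: float, cfg: VentConfig,
              viscosity_mpas: float = 3.5) -> float:
    """One-way vent drainage flow, mL/s, floored at zero."""
    q = (p_source - p_pump_inlet) / cfg.total_r(viscosity_mpas)
    return max(q, 0.0)


def ecmo_contributions(p_ra: float, cfg: EcmoConfig,
                       vent_flow_mls: float = 0.0) -> dict[str, float]:
    """Instantaneous ECMO source/sink terms and pump-inlet-node pressure.

    The pump is an ideal flow source: it removes ``pump_flow`` from the RA
    (derated if RA pressure approaches the suction limit) and returns that
    flow, plus any vent drainage joining the venous line, into the descending
    aorta. The pump-inlet pressure, exposed so vents can drain into it, is
    ``P_RA - (Q_pump + Q_vent) * R_drain``.
    """
    q_pump = _k.derated_flow(
        cfg.pump_flow * MLS_PER_LMIN, p_ra, cfg.suction_limit, cfg.suction_width
    )
    p_inlet = p_ra - (q_pump + vent_flow_mls) * cfg.drainage_cannula_r
    return {
        "ra_sink": q_pump,
        "desc_ao_source": q_pump + vent_flow_mls,
        "pump_inlet_pressure": p_inlet,
    }


def iabp_balloon_volume(t_cycle: float, cfg: IabpConfig, period: float,
                        t_close: float, t_open: float) -> float:
    """Balloon volume at cycle time ``t_cycle``, mL.

    Inflation starts at the aortic-valve closure time ``t_close`` of the
    previous beat; deflation is completed ``deflate_lead`` seconds before the
    next ejection onset ``t_open``. Ramps are raised-cosine of length
    ``transition_time``, so the displaced volume is cycle-periodic with zero
    net displacement per beat.
    """
    return _k.balloon_volume(
        t_cycle % period, period, cfg.balloon_volume, t_close, t_open,
        cfg.deflate_lead, cfg.transition_time,
    )
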