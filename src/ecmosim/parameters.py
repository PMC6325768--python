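"""Parameter containers for the closed-loop cardiovascular model.

The circulation is a lumped-parameter (0D) network: four cardiac chambers
described by time-varying elastance, four resistive diode valves, and seven
passive vascular compartments (compliance + unstressed volume + outflow
resistance) arranged in one closed loop:

    LV -> ascending aorta -> descending aorta -> systemic arteries
       -> systemic veins -> RA -> RV -> pulmonary artery
       -> pulmonary capillaries -> pulmonary veins -> LA -> LV

plus a resistive coronary branch from the aortic root to the RA, and any
attached mechanical-support devices (see :mod:`ecmosim.devices`).

Units are mmHg, mL and s throughout; flows are reported in L/min at the
interface level (1 mL/s = 0.06 L/min).
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .devices import DeviceSet

ChamberName = Literal["LA", "LV", "RA", "RV"]
ValveName = Literal["mitral", "aortic", "tricuspid", "pulmonary"]

#: Fixed ordering of the vascular compartments (keys of
#: :attr:`CirculationModel.compartments`).
COMPARTMENT_NAMES = (
    "asc_ao",
    "desc_ao",
    "sys_art",
    "sys_ven",
    "pa",
    "pulm_cap",
    "pulm_ven",
)


class ChamberParams(BaseModel):
    """Time-varying elastance description of one cardiac chamber.

    Instantaneous pressure is

        P(V, t) = a(t) * Ees * (V - V0) + A * (exp(B * (V - V0)) - 1)

    where ``a(t)`` is the activation waveform (0 in diastole, 1 at end
    systole), ``Ees`` the end-systolic elastance (contractility) and the
    exponential term the passive end-diastolic pressure-volume relation.
    """

    model_config = ConfigDict(extra="forbid")

    name: ChamberName
    ees: float = Field(gt=0, description="End-systolic elastance, mmHg/mL")
    v0: float = Field(description="ESPVR volume intercept, mL")
    passive_a: float = Field(ge=0, description="EDPVR scale, mmHg")
    passive_b: float = Field(gt=0, description="EDPVR exponent, 1/mL")
    act_onset: float = Field(ge=0, lt=1, description="Activation onset, fraction of cycle")
    act_duration: float = Field(gt=0, description="Activation duration, s")


class ValveParams(BaseModel):
    """Resistive diode valve: low resistance forward, high resistance backward."""

    model_config = ConfigDict(extra="forbid")

    name: ValveName
    r_open: float = Field(gt=0, description="Forward resistance, mmHg*s/mL")
    r_closed: float = Field(gt=0, description="Backward (leak) resistance, mmHg*s/mL")

    @model_validator(mode="after")
    def _ordered(self) -> "ValveParams":
        if not self.r_open < self.r_closed:
            raise ValueError("valve r_open must be much smaller than r_closed")
        return self


class VascularCompartmentParams(BaseModel):
    """Linear compliance compartment: P = (V - Vu) / C, draining through R_out."""

    model_config = ConfigDict(extra="forbid")

    name: str
    c: float = Field(gt=0, description="Compliance, mL/mmHg")
    vu: float = Field(ge=0, description="Unstressed volume, mL")
    r_out: float = Field(ge=0, description="Resistance to downstream node, mmHg*s/mL")


class CirculationModel(BaseModel):
    """Complete closed-loop circulation: topology, parameters and devices.

    Total blood volume is conserved: at t=0 the compartment and chamber
    volumes (plus the constant ECMO circuit volume when attached) sum to
    ``total_blood_volume`` plus circuit volume, and the mass-balance ODEs
    preserve the sum exactly.
    """

    model_config = ConfigDict(extra="forbid")

    chambers: dict[ChamberName, ChamberParams]
    valves: dict[ValveName, ValveParams]
    compartments: dict[str, VascularCompartmentParams]
    hr: float = Field(gt=0, description="Heart rate, bpm")
    total_blood_volume: float = Field(gt=0, description="Circulating blood volume, mL")
    viscosity: float = Field(3.5, gt=0, description="Blood viscosity, mPa*s")
    weight: float = Field(70.0, gt=0, description="Body weight, kg")
    bsa: float = Field(1.8, gt=0, description="Body surface area, m^2")
    coronary_r: float = Field(12.0, gt=0, description="Coronary branch resistance, mmHg*s/mL")
    coronary_im_frac: float = Field(
        0.75, ge=0, le=1,
        description="Intramyocardial pressure as a fraction of instantaneous LV pressure",
    )
    hemoglobin: float = Field(12.0, gt=0, description="Hemoglobin, g/dL")
    vo2: float = Field(250.0, ge=0, description="Systemic O2 consumption, mL O2/min")
    lung_saturation: float = Field(
        0.98, ge=0, le=1,
        description="Pulmonary capillary outlet O2 saturation (reduce to emulate lung failure)",
    )
    devices: DeviceSet = Field(default_factory=DeviceSet)

    @property
    def period(self) -> float:
        """Cardiac cycle length, s."""
        return 60.0 / self.hr

    @model_validator(mode="after")
    def _check(self) -> "CirculationModel":
        for name in ("LA", "LV", "RA", "RV"):
            if name not in self.chambers:
                raise ValueError(f"missing chamber {name}")
        for name in ("mitral", "aortic", "tricuspid", "pulmonary"):
            if name not in self.valves:
                raise ValueError(f"missing valve {name}")
        missing = [n for n in COMPARTMENT_NAMES if n not in self.compartments]
        if missing:
            raise ValueError(f"missing compartments: {missing}")
        period = self.period
        for ch in self.chambers.values():
            if ch.act_duration >= period:
                raise ValueError(
                    f"{ch.name} activation duration {ch.act_duration}s >= cycle {period:.3f}s"
                )
        # atria must activate before the ventricles in the default timing set
        if not (
            self.chambers["LA"].act_onset <= self.chambers["LV"].act_onset
            and self.chambers["RA"].act_onset <= self.chambers["RV"].act_onset
        ):
            raise ValueError("atria must activate before ventricles")
        if self.devices.vent is not None and self.devices.ecmo is None:
            raise ValueError("a vent cannula requires an active ECMO circuit")
        vu_total = sum(c.vu for c in self.compartments.values())
        if self.total_blood_volume <= vu_total:
            raise ValueError(
                "total blood volume must exceed the summed unstressed volumes "
                f"({vu_total:.0f} mL)"
            )
        return self

    def copy_with(self, **updates) -> "CirculationModel":
        """Deep copy with top-level field updates (validation re-run)."""
        data = self.model_dump()
        data.update(updates)
        return CirculationModel.model_validate(data)
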