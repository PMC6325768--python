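"""Integrator properties: mass balance, conservation, convergence, stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecmosim as es
from ecmosim.devices import AsdConfig, EcmoConfig, IabpConfig, ImpellaConfig, VentConfig
from ecmosim.engine import (ConvergenceError, derivatives, initial_volumes,
                            integrate, steady_state)
from ecmosim.metrics import detect_cycles, summarize


def devices_everything():
    return dict(
        ecmo=EcmoConfig(pump_flow=3.0),
        iabp=IabpConfig(),
        impella=ImpellaConfig(flow_setpoint=2.0),
        asd=AsdConfig(area=1.0),
        vent=VentConfig(site="LV"),
    )


class TestDerivatives:
    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_mass_balance_sums_to_zero_with_all_devices(self, data):
        model = es.with_devices(es.build_lv_failure(), **devices_everything())
        v0 = initial_volumes(model)
        scale = np.array([data.draw(st.floats(0.7, 1.4)) for _ in v0])
        t = data.draw(st.floats(0.0, 0.6))
        dv = derivatives(v0 * scale, t, model)
        assert abs(dv.sum()) < 1e-9 * max(1.0, np.abs(dv).max())

    def test_uniform_pressure_equilibrium_is_stationary(self):
        # equal pressures everywhere, no activation, no devices -> dV/dt = 0
        # (the coronary branch is shut by its intramyocardial throttle)
        import math

        from ecmosim.engine import CHAMBER_NODE, COMPARTMENT_NODE

        model = es.build_normal()
        p0 = 8.0
        v = np.zeros(11)
        for name, idx in COMPARTMENT_NODE.items():
            comp = model.compartments[name]
            v[idx] = comp.vu + p0 * comp.c
        for name, idx in CHAMBER_NODE.items():
            ch = model.chambers[name]
            v[idx] = ch.v0 + math.log(p0 / ch.passive_a + 1.0) / ch.passive_b
        t_inactive = 0.55  # between atrial and next ventricular activation
        dv = derivatives(v, t_inactive, model)
        assert np.abs(dv).max() < 1e-9

    def test_ecmo_moves_exactly_the_set_flow_between_ra_and_aorta(self):
        # 4 L/min = 66.67 mL/s leaves the RA and enters the descending aorta
        from ecmosim.engine import CHAMBER_NODE, COMPARTMENT_NODE

        model = es.with_ecmo(es.build_lv_failure(), 4.0)
        base = es.build_lv_failure()
        v = initial_volumes(base)
        t = 0.55
        dv_ecmo = derivatives(v, t, model)
        dv_base = derivatives(v, t, base)
        delta = dv_ecmo - dv_base
        assert delta[CHAMBER_NODE["RA"]] == pytest.approx(-66.6667, abs=1e-3)
        assert delta[COMPARTMENT_NODE["desc_ao"]] == pytest.approx(66.6667, abs=1e-3)


class TestIntegration:
    def test_volume_conserved_within_tolerance(self, ecmo4_run):
        res, _ = ecmo4_run
        assert res.total_volume_drift < 1e-6

    def test_periodic_steady_state_signals_repeat(self, failure_run):
        res, _ = failure_run
        spb = res.samples_per_beat
        last = res.volumes[-spb - 1:]
        prev = res.volumes[-2 * spb - 1:-spb]
        assert np.abs(last[:spb] - prev[:spb]).max() < 0.2  # mL

    def test_already_converged_state_returns_in_one_beat(self, failure_run):
        res, _ = failure_run
        again = steady_state(res.model, max_beats=50,
                             v0=res.volumes[-1], s0=res.saturations[-1])
        assert again.converged_beat == 0

    def test_failure_preset_converges_well_under_sixty_beats(self):
        res = es.steady_state(es.build_lv_failure(), max_beats=60)
        assert res.converged

    def test_nonconvergence_raises_with_drift_trace(self):
        with pytest.raises(ConvergenceError, match="volume changes"):
            steady_state(es.build_lv_failure(), max_beats=3)

    def test_convergence_flag_implies_small_beat_to_beat_change(self, ecmo4_run):
        res, _ = ecmo4_run
        diffs = np.abs(np.diff(res.beat_end_volumes, axis=0)).max(axis=1)
        assert diffs[res.converged_beat - 1] < 0.1

    def test_halving_dt_changes_map_by_less_than_tenth_mmhg(self):
        m = es.build_lv_failure()
        map_coarse = summarize(steady_state(m, dt=5e-4, max_beats=400)).map
        map_fine = summarize(steady_state(m, dt=2.5e-4, max_beats=400)).map
        assert abs(map_coarse - map_fine) < 0.1

    def test_without_activation_flows_decay_to_equilibrium(self):
        # quench all chamber activation: the circulation relaxes, flows -> 0
        data = es.build_normal().model_dump()
        for ch in data["chambers"].values():
            ch["act_duration"] = 1e-6
        from ecmosim.parameters import CirculationModel

        model = CirculationModel.model_validate(data)
        res = integrate(model, duration_beats=40)
        spb = res.samples_per_beat
        final_flows = res.flows[-spb:, :11]
        assert np.abs(final_flows).max() < 1.0  # mL/s

    def test_doubling_systemic_resistance_raises_map(self, normal_run):
        _, s_base = normal_run
        s_high = summarize(steady_state(es.scale_svr(es.build_normal(), 2.0),
                                        max_beats=400))
        assert s_high.map > s_base.map + 10

    def test_infeasible_blood_volume_is_rejected(self):
        with pytest.raises(ValueError, match="(?i)volume"):
            es.apply_volume_change(es.build_normal(), -2000.0)


class TestDeviceNoOpIdentity:
    def test_zero_setpoints_reproduce_device_free_run_bit_identically(self):
        base = es.build_lv_failure()
        noop = es.with_devices(
            base,
            ecmo=EcmoConfig(pump_flow=0.0),
            iabp=IabpConfig(balloon_volume=0.0),
            impella=ImpellaConfig(flow_setpoint=0.0),
        )
        r1 = integrate(base, duration_beats=12)
        r2 = integrate(noop, duration_beats=12)
        assert np.array_equal(r1.volumes, r2.volumes)
        assert np.array_equal(r1.pressures, r2.pressures)

    def test_reruns_are_bit_identical(self):
        m = es.build_lv_failure()
        r1 = steady_state(m, max_beats=80)
        r2 = steady_state(m, max_beats=80)
        assert np.array_equal(r1.volumes, r2.volumes)
        assert np.array_equal(r1.saturations, r2.saturations)


class TestCycleDetection:
    def test_boundaries_exactly_one_period_apart(self, failure_run):
        res, _ = failure_run
        bounds = detect_cycles(res)
        spacing = np.diff(res.time[bounds])
        assert np.allclose(spacing, 0.6, atol=1e-9)  # HR 100 -> 0.6 s

    def test_boundary_count_matches_duration(self):
        res = integrate(es.build_normal(), duration_beats=5)
        bounds = detect_cycles(res)
        assert len(bounds) == 6  # 5 beats -> 6 fenceposts incl. final sample

    def test_result_shorter_than_one_beat_is_an_error(self):
        res = integrate(es.build_normal(), duration_beats=1)
        res.time = res.time[:100]
        with pytest.raises(ValueError):
            detect_cycles(res)
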