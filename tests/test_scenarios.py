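"""Presets, interventions, titration controller, registry, calibrator."""

import numpy as np
import pytest

import ecmosim as es
from ecmosim.metrics import summarize
from ecmosim.scenarios import (CalibrationTarget, INOTROPY_SCALE, Scenario,
                               build_scenario_model, calibrate, run_scenario,
                               scenario_by_name, table1_registry)


class TestNormalPreset:
    def test_cardiac_output_and_index(self, normal_run):
        _, s = normal_run
        assert s.co_total == pytest.approx(7.0, rel=0.02)
        assert s.ci == pytest.approx(3.9, rel=0.02)

    def test_normal_ejection_fraction_physiological(self, normal_run):
        _, s = normal_run
        assert s.lv_ef >= 0.55

    def test_blood_volume_and_rate(self):
        m = es.build_normal()
        assert m.total_blood_volume == 5600.0
        assert m.hr == 70.0
        assert m.weight == 70.0 and m.bsa == 1.8


class TestFailurePreset:
    def test_cardiac_output_collapses_to_shock_level(self, failure_run):
        _, s = failure_run
        assert s.co_total == pytest.approx(3.1, rel=0.02)
        assert s.ci == pytest.approx(1.7, rel=0.03)

    def test_wedge_pressure_reflects_congestion(self, failure_run):
        _, s = failure_run
        assert s.pcwp == pytest.approx(30.0, abs=0.5)

    def test_preset_inputs_echoed(self):
        m = es.build_lv_failure()
        assert m.hr == 100.0
        assert m.total_blood_volume == 6400.0

    def test_failing_lv_dilates_beyond_normal(self, normal_run, failure_run):
        assert failure_run[1].lv_edv > normal_run[1].lv_edv

    def test_severe_preset_pins_contractility(self):
        m = es.build_lv_failure_severe()
        assert m.chambers["LV"].ees == pytest.approx(0.3)
        # everything else inherited from the failure preset
        base = es.build_lv_failure()
        assert m.chambers["LV"].passive_a == base.chambers["LV"].passive_a
        assert m.hr == base.hr


class TestInterventions:
    def test_volume_change_updates_total(self):
        m = es.apply_volume_change(es.build_lv_failure(), -800.0)
        assert m.total_blood_volume == 5600.0

    def test_zero_volume_change_is_identity(self):
        m = es.build_lv_failure()
        assert es.apply_volume_change(m, 0.0) is m

    def test_unit_inotropy_is_identity(self):
        m = es.build_lv_failure()
        assert es.apply_inotropy(m, 1.0) is m

    def test_map_monotone_in_inotropy_scale(self, ecmo4_model, ecmo4_run):
        maps = [ecmo4_run[1].map]
        for scale in (1.5, 2.2):
            maps.append(summarize(es.steady_state(
                es.apply_inotropy(ecmo4_model, scale), max_beats=600)).map)
        assert maps[0] < maps[1] < maps[2]

    def test_inotropy_weights_lv_over_rv(self):
        m = es.apply_inotropy(es.build_lv_failure(), 2.0)
        base = es.build_lv_failure()
        lv_gain = m.chambers["LV"].ees / base.chambers["LV"].ees
        rv_gain = m.chambers["RV"].ees / base.chambers["RV"].ees
        assert lv_gain == pytest.approx(2.0)
        assert 1.0 < rv_gain < lv_gain


class TestTitration:
    def test_converges_to_target_map(self, ecmo4_model):
        m, info = es.titrate_svr_to_map(ecmo4_model, 65.0)
        assert info.achieved_map == pytest.approx(65.0, abs=0.5)
        assert info.svr_scale < 1.0  # afterload reduced from the ECMO state

    def test_target_equal_to_current_map_returns_immediately(self, ecmo4_model,
                                                             ecmo4_run):
        _, s = ecmo4_run
        m, info = es.titrate_svr_to_map(ecmo4_model, s.map)
        assert info.iterations == 0
        assert info.svr_scale == 1.0
        assert m is ecmo4_model

    def test_unreachable_target_reports_bracket(self, ecmo4_model):
        with pytest.raises(RuntimeError, match="unreachable"):
            es.titrate_svr_to_map(ecmo4_model, 200.0)


class TestRegistry:
    def test_seventeen_rows_in_reporting_order(self):
        rows = table1_registry()
        assert len(rows) == 17
        assert rows[0].name == "normal"
        assert rows[1].name == "lv_failure"
        assert rows[2].name == "lv_failure_ecmo4"
        assert [r.name for r in rows[-3:]] == [
            "ecmo_vent_la", "ecmo_vent_pa", "ecmo_vent_lv"]
        assert len({r.name for r in rows}) == 17

    def test_first_row_is_the_normal_preset(self):
        model = build_scenario_model(table1_registry()[0])
        assert model == es.build_normal()

    def test_unknown_scenario_lists_registry(self):
        with pytest.raises(KeyError, match="normal"):
            scenario_by_name("no_such_row")

    def test_scenario_overrides_apply_in_documented_order(self):
        sc = Scenario(name="x", base="lv_failure",
                      overrides=dict(blood_volume_delta=-800.0,
                                     contractility_scale=1.5, svr_scale=0.8))
        m = build_scenario_model(sc)
        base = es.build_lv_failure()
        assert m.total_blood_volume == 5600.0
        assert m.chambers["LV"].ees == pytest.approx(
            base.chambers["LV"].ees * 1.5)
        assert m.compartments["sys_art"].r_out == pytest.approx(
            base.compartments["sys_art"].r_out * 0.8)

    def test_run_scenario_executes_titration(self):
        sr = run_scenario(scenario_by_name("ecmo_map65"))
        assert sr.titration is not None
        assert sr.summary.map == pytest.approx(65.0, abs=0.6)


class TestCalibrator:
    def test_empty_target_set_returns_model_unchanged(self):
        m = es.build_normal()
        out, report = calibrate(m, [], [])
        assert out is m and report.converged

    def test_mismatched_knobs_rejected(self):
        with pytest.raises(ValueError):
            calibrate(es.build_normal(),
                      [CalibrationTarget(metric="CO", value=7.0)], [])

    def test_recovers_failure_targets_from_perturbed_start(self):
        # +/-20% perturbation of the two contractility knobs; the calibrator
        # must bring CO and PCWP back within tolerance
        from ecmosim.scenarios import _scale_chamber

        perturbed = _scale_chamber(es.build_lv_failure(), "LV", ees_scale=1.2)
        perturbed = _scale_chamber(perturbed, "RV", ees_scale=0.8)
        targets = [CalibrationTarget(metric="CO", value=3.1, tolerance=0.05),
                   CalibrationTarget(metric="PCWP", value=30.0, tolerance=0.05)]
        model, report = calibrate(perturbed, targets, ["lv_ees", "rv_ees"],
                                  dt=1e-3)
        assert report.converged
        assert all(abs(e["residual"]) <= 0.05 for e in report.entries)
        # recovered parameters close to the frozen preset values
        ref = es.build_lv_failure()
        assert model.chambers["LV"].ees == pytest.approx(
            ref.chambers["LV"].ees, rel=0.15)
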