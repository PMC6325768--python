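"""PV-loop analysis: stroke work, PVA/MVO2 energetics, ejection status."""

import numpy as np
import pytest

import ecmosim as es
from ecmosim.fixtures import make_loop
from ecmosim.metrics import (PVLoop, ejection_status, extract_loop, pva_mvo2,
                             stroke_work, stroke_work_trapezoid, summarize)
from ecmosim.parameters import ChamberParams


class TestStrokeWork:
    def test_rectangle_loop_area(self):
        # 60 mL excursion between 10 and 100 mmHg -> 5400 mmHg*mL
        fx = make_loop("rectangle", dv=60.0, dp=90.0)
        assert stroke_work(fx.loop) == pytest.approx(5400.0, rel=1e-12)

    def test_nonejecting_loop_has_zero_area(self):
        fx = make_loop("nonejecting")
        assert stroke_work(fx.loop) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("kind", ["rectangle", "trapezoid", "nonejecting"])
    def test_shoelace_matches_analytic_area(self, kind):
        fx = make_loop(kind)
        assert stroke_work(fx.loop) == pytest.approx(fx.analytic_area,
                                                     abs=1e-9, rel=1e-9)

    def test_shoelace_and_trapezoid_oracles_agree_on_simulated_loop(
            self, failure_run, ecmo4_run, normal_run):
        for res, _ in (failure_run, ecmo4_run, normal_run):
            loop = extract_loop(res, "lv")
            sw = stroke_work(loop)
            sw_trap = stroke_work_trapezoid(loop)
            assert sw == pytest.approx(sw_trap, rel=1e-3)

    def test_open_loop_is_rejected(self):
        v = np.linspace(100, 160, 150)
        p = np.linspace(10, 100, 150)
        with pytest.raises(ValueError, match="closed"):
            stroke_work(PVLoop(volume=v, pressure=p))


class TestPvaMvo2:
    chamber = ChamberParams(name="LV", ees=1.0, v0=20.0, passive_a=1e-9,
                            passive_b=0.01, act_onset=0.17, act_duration=0.3)

    def make_es_loop(self, pes=100.0, ves=100.0):
        # rectangle whose top-left corner is the end-systolic point
        fx = make_loop("rectangle", dv=60.0, dp=pes - 10.0, v0=ves, p0=10.0)
        return fx

    def test_potential_energy_is_espvr_triangle(self):
        # Pes 100 at Ves 100 with V0 20 and negligible EDPVR -> PE 4000
        fx = self.make_es_loop()
        out = pva_mvo2(fx.loop, self.chamber, hr=100.0)
        assert out["pes"] == pytest.approx(100.0)
        assert out["ves"] == pytest.approx(100.0)
        assert out["pe"] == pytest.approx(4000.0, rel=1e-6)

    def test_pva_is_sum_of_work_and_potential_energy(self):
        fx = self.make_es_loop()
        out = pva_mvo2(fx.loop, self.chamber, hr=100.0)
        assert out["pva"] == pytest.approx(out["sw"] + out["pe"])
        assert out["sw"] == pytest.approx(5400.0)
        assert out["pva"] == pytest.approx(9400.0)

    def test_mvo2_linear_in_pva(self):
        fx1 = self.make_es_loop()
        fx2 = make_loop("rectangle", dv=30.0, dp=90.0, v0=100.0)
        m1 = pva_mvo2(fx1.loop, self.chamber, hr=100.0)
        m2 = pva_mvo2(fx2.loop, self.chamber, hr=100.0)
        # same intercept term; slope 1.8e-5 mL O2 per mmHg*mL per beat
        dm = m1["mvo2"] - m2["mvo2"]
        dpva = m1["pva"] - m2["pva"]
        assert dm == pytest.approx(1.8e-5 * dpva * 100.0, rel=1e-9)

    def test_ves_below_v0_clamps_pe_with_warning(self):
        fx = make_loop("rectangle", dv=10.0, dp=90.0, v0=2.0)
        with pytest.warns(UserWarning, match="V0"):
            out = pva_mvo2(fx.loop, self.chamber, hr=100.0)
        assert out["pe"] == 0.0

    def test_pva_never_below_stroke_work_on_simulated_loops(
            self, normal_run, failure_run, ecmo4_run):
        for res, _ in (normal_run, failure_run, ecmo4_run):
            out = pva_mvo2(extract_loop(res, "lv"),
                           res.model.chambers["LV"], res.model.hr)
            assert out["pva"] >= out["sw"] - 1e-9


class TestEjectionStatus:
    def test_normal_heart_ejects_with_systolic_valve_opening(self, normal_run):
        res, _ = normal_run
        status = ejection_status(res)
        assert status["ejecting"]
        assert status["ejected_volume"] == pytest.approx(100.0, rel=0.05)
        # valve open for a fraction of the cycle comparable to systole
        assert 0.1 < status["aortic_open_fraction"] < 0.5

    def test_impella_full_support_is_nonejecting_with_device_flow(
            self, impella_runs):
        res, summ = impella_runs[5.0]
        status = ejection_status(res)
        assert not status["ejecting"]
        assert summ.impella_flow > 4.0  # L/min through the device
        assert summ.lv_sv > 0  # volume still cycles through the pump


class TestSummary:
    def test_ef_is_sv_over_edv(self, failure_run):
        _, s = failure_run
        assert s.lv_ef == pytest.approx(s.lv_sv / s.lv_edv)
        assert 0.0 <= s.lv_ef <= 1.0

    def test_co_total_equals_native_without_devices(self, failure_run):
        _, s = failure_run
        assert s.co_total == pytest.approx(s.co_native)
        assert s.ecmo_flow == 0.0 and s.impella_flow == 0.0

    def test_co_total_adds_device_flows(self, ecmo4_run):
        _, s = ecmo4_run
        assert s.co_total == pytest.approx(s.co_native + s.ecmo_flow)
        assert s.ecmo_flow == pytest.approx(4.0, rel=1e-3)

    def test_summary_deterministic_across_reruns(self):
        m = es.build_lv_failure()
        s1 = summarize(es.steady_state(m, max_beats=80))
        s2 = summarize(es.steady_state(m, max_beats=80))
        assert s1.to_dict() == s2.to_dict()

    def test_minimum_loop_sampling_density(self, failure_run):
        res, _ = failure_run
        loop = extract_loop(res, "lv")
        assert len(loop.volume) >= 100
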