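"""Shared fixtures: expensive steady-state runs are computed once per session."""

from __future__ import annotations

import pytest

import ecmosim as es
from ecmosim.devices import (AsdConfig, EcmoConfig, IabpConfig, ImpellaConfig,
                             VentConfig)
from ecmosim.metrics import summarize


@pytest.fixture(scope="session")
def normal_run():
    res = es.steady_state(es.build_normal(), max_beats=400)
    return res, summarize(res)


@pytest.fixture(scope="session")
def failure_run():
    res = es.steady_state(es.build_lv_failure(), max_beats=600)
    return res, summarize(res)


@pytest.fixture(scope="session")
def ecmo4_model():
    return es.with_ecmo(es.build_lv_failure(), 4.0)


@pytest.fixture(scope="session")
def ecmo4_run(ecmo4_model):
    res = es.steady_state(ecmo4_model, max_beats=600)
    return res, summarize(res)


@pytest.fixture(scope="session")
def ecmo_ramp(ecmo4_run):
    """Summaries over the ECMO support ramp 0-4 L/min on the failure base."""
    fail = es.build_lv_failure()
    out = {}
    for q in (0.0, 1.0, 2.0, 3.0):
        m = es.with_ecmo(fail, q) if q > 0 else fail
        out[q] = summarize(es.steady_state(m, max_beats=600))
    out[4.0] = ecmo4_run[1]
    return out


@pytest.fixture(scope="session")
def impella_runs(ecmo4_model):
    out = {}
    for q in (1.0, 3.0, 5.0):
        m = es.with_devices(ecmo4_model, impella=ImpellaConfig(flow_setpoint=q))
        res = es.steady_state(m, max_beats=600)
        out[q] = (res, summarize(res))
    return out


@pytest.fixture(scope="session")
def asd_runs(ecmo4_model):
    out = {}
    for area in (0.5, 1.0, 1.5):
        m = es.with_devices(ecmo4_model, asd=AsdConfig(area=area))
        res = es.steady_state(m, max_beats=600)
        out[area] = (res, summarize(res))
    return out


@pytest.fixture(scope="session")
def vent_runs(ecmo4_model):
    out = {}
    for site in ("LA", "PA", "LV"):
        m = es.with_devices(ecmo4_model, vent=VentConfig(site=site))
        res = es.steady_state(m, max_beats=600)
        out[site] = (res, summarize(res))
    return out


@pytest.fixture(scope="session")
def iabp_run(ecmo4_model):
    m = es.with_devices(ecmo4_model, iabp=IabpConfig())
    res = es.steady_state(m, max_beats=600)
    return res, summarize(res)


@pytest.fixture(scope="session")
def registry_summaries():
    """Summaries of all 17 registry rows, keyed by scenario name."""
    from ecmosim.scenarios import run_scenario, table1_registry

    return {sc.name: run_scenario(sc).summary for sc in table1_registry()}


@pytest.fixture(scope="session")
def inotropy_run(ecmo4_model):
    res = es.steady_state(es.apply_inotropy(ecmo4_model), max_beats=600)
    return res, summarize(res)
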