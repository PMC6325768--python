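"""Run configuration schema and file exports.

Configs are strict (unknown keys rejected: a typo must fail fast rather than
silently change the physiology). Scenario files are YAML or JSON with the
same schema; time series export as tidy CSV (one row per sample, one column
per signal) and summaries as JSON/CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .engine import SimulationResult
from .metrics import HemodynamicSummary
from .scenarios import Scenario, scenario_by_name


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dt: float = Field(5e-4, gt=0, description="Integration step, s")
    dt_out: float = Field(1e-3, gt=0, description="Output sampling step, s")
    max_beats: int = Field(300, ge=1)
    tol: float = Field(0.1, gt=0, description="Steady-state volume tolerance, mL")


class RunConfig(BaseModel):
    """One simulation run: a scenario (by name or inline) plus solver/export options."""

    model_config = ConfigDict(extra="forbid")

    scenario: Union[str, Scenario]
    solver: SolverSettings = Field(default_factory=SolverSettings)
    out_dir: Path = Path("ecmosim_out")
    export_timeseries: bool = True
    export_summary: bool = True
    export_pv_plot: bool = False

    def resolve_scenario(self) -> Scenario:
        if isinstance(self.scenario, str):
            return scenario_by_name(self.scenario)
        return self.scenario


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration (strict schema)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = json.loads(cfg.model_dump_json())
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_timeseries_csv(result: SimulationResult, path: str | Path) -> Path:
    """Tidy CSV: one row per sample, one column per signal (full precision)."""
    path = Path(path)
    df = result.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries_csv(path: str | Path):
    import pandas as pd

    # round_trip parser: exact inverse of the %.17g writer at double precision
    return pd.read_csv(path, float_precision="round_trip")


def write_summary_json(summary: HemodynamicSummary, path: str | Path,
                       extra: Optional[dict] = None) -> Path:
    path = Path(path)
    data = summary.to_dict()
    if extra:
        data.update(extra)
    path.write_text(json.dumps(data, indent=2))
    return path


def summaries_to_frame(rows: list[tuple[str, HemodynamicSummary]]):
    """Summary table (one row per scenario) in fixed column order."""
    import pandas as pd

    records = []
    for name, summ in rows:
        rec = {"scenario": name}
        rec.update(summ.to_dict())
        records.append(rec)
    return pd.DataFrame.from_records(records)
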