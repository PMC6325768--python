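"""PV-loop and time-series plots (matplotlib, non-interactive backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .engine import SimulationResult
from .metrics import extract_loop


def plot_pv_loops(results: list[SimulationResult], labels: list[str],
                  path: str | Path, chamber: str = "lv",
                  model=None) -> Path:
    """Overlay LV pressure-volume loops of one or more converged runs.

    Optionally draws the ESPVR and EDPVR of ``model``'s LV for context.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    for res, label in zip(results, labels):
        loop = extract_loop(res, chamber)
        ax.plot(loop.volume, loop.pressure, label=label, lw=1.5)
    if model is not None:
        ch = model.chambers["LV"]
        v = np.linspace(ch.v0, max(extract_loop(r, chamber).volume.max()
                                   for r in results) * 1.05, 200)
        espvr = ch.ees * (v - ch.v0)
        edpvr = ch.passive_a * np.expm1(ch.passive_b * (v - ch.v0))
        ax.plot(v, espvr, "r--", lw=0.8, alpha=0.6)
        ax.plot(v, edpvr, "r-", lw=0.8, alpha=0.6)
    ax.set_xlabel("LV volume (mL)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.set_ylim(bottom=min(0, ax.get_ylim()[0]))
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_timeseries(result: SimulationResult, path: str | Path,
                    signals=("p_lv", "p_asc_ao", "p_pulm_ven"),
                    last_beats: int = 3) -> Path:
    """Pressure traces of the last few beats."""
    fig, ax = plt.subplots(figsize=(7, 4))
    df = result.to_frame()
    t_end = df["time"].iloc[-1]
    window = df[df["time"] >= t_end - last_beats * result.model.period]
    for sig in signals:
        ax.plot(window["time"], window[sig], label=sig, lw=1.0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (mmHg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
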