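"""Analytic PV-loop fixtures for testing the metrics without the solver.

Each generator returns a densely sampled closed loop together with its exact
analytic area, so loop-area routines can be checked against a closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import PVLoop

LOOP_KINDS = ("rectangle", "trapezoid", "nonejecting")


@dataclass
class SyntheticLoopFixture:
    kind: str
    loop: PVLoop
    analytic_area: float
    params: dict

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Write the loop as two-column CSV plus a JSON ground-truth file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"loop_{self.kind}.csv"
        json_path = directory / f"loop_{self.kind}.json"
        data = np.column_stack([self.loop.volume, self.loop.pressure])
        np.savetxt(csv_path, data, delimiter=",", header="volume_ml,pressure_mmhg",
                   comments="")
        json_path.write_text(json.dumps(
            {"kind": self.kind, "analytic_sw": self.analytic_area,
             "params": self.params}, indent=2))
        return csv_path, json_path


def _densify(vertices: np.ndarray, n_per_edge: int) -> np.ndarray:
    pts = []
    m = len(vertices)
    for i in range(m):
        a, b = vertices[i], vertices[(i + 1) % m]
        t = np.linspace(0.0, 1.0, n_per_edge, endpoint=False)[:, None]
        pts.append(a + t * (b - a))
    return np.vstack(pts)


def make_loop(kind: str, dv: float = 60.0, dp: float = 90.0, v0: float = 100.0,
              p0: float = 10.0, n_per_edge: int = 50) -> SyntheticLoopFixture:
    """Generate a parametric PV loop with exact analytic area.

    rectangle: isovolumic/isobaric rectangle traversed counterclockwise,
    area dv*dp. trapezoid: quadrilateral with sloped filling and ejection
    limbs (area from the shoelace closed form of its four vertices).
    nonejecting: an isovolumic pressure excursion with zero enclosed area.
    """
    if kind == "rectangle":
        verts = np.array([
            [v0, p0], [v0 + dv, p0], [v0 + dv, p0 + dp], [v0, p0 + dp],
        ], dtype=float)
        # counterclockwise in (V, P): fill at low P, eject (V down) at high P
        area = dv * dp
    elif kind == "trapezoid":
        verts = np.array([
            [v0, p0], [v0 + dv, p0 + 0.2 * dp],
            [v0 + 0.9 * dv, p0 + dp], [v0 + 0.05 * dv, p0 + 0.85 * dp],
        ], dtype=float)
        x, y = verts[:, 0], verts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    elif kind == "nonejecting":
        verts = np.array([[v0, p0], [v0, p0 + dp]], dtype=float)
        area = 0.0
    else:
        raise ValueError(f"unknown loop kind '{kind}'; choose from {LOOP_KINDS}")
    pts = _densify(verts, n_per_edge)
    pts = np.vstack([pts, pts[0]])  # close
    return SyntheticLoopFixture(
        kind=kind,
        loop=PVLoop(volume=pts[:, 0], pressure=pts[:, 1]),
        analytic_area=float(area),
        params={"dv": dv, "dp": dp, "v0": v0, "p0": p0},
    )
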