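"""Robustness scenario set and voxel-wise scenario aggregates.

Scenario-based robust optimization evaluates dose under discrete error
scenarios combining rigid setup shifts with proton range errors. The robust
set is 21 scenarios: the nominal one, range undershoot/overshoot of 3%
without setup error (2), setup errors of 3 mm along each of the three axes
in both directions without range error (6), and the same six shifts combined
with undershoot (6) and overshoot (6).

Range error is realized as a global density scaling: undershoot means the
patient is effectively denser (scale 1 + 3%), so a fixed-energy Bragg peak
falls short. Setup error is a rigid beam-to-patient translation; for the
parallel-beam model used here the scenario dose field is the nominal dose
field sampled at ``x + shift``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["Scenario", "ScenarioSet", "build_scenarios", "voxelwise_aggregate"]


@dataclass(frozen=True)
class Scenario:
    setup_shift_mm: tuple[float, float, float]
    range_scale: float  # density multiplier; undershoot = denser = > 1
    label: str

    def __post_init__(self) -> None:
        if self.range_scale <= 0:
            raise ValueError("range_scale must be positive")

    @property
    def is_nominal(self) -> bool:
        return self.range_scale == 1.0 and all(s == 0.0 for s in self.setup_shift_mm)


@dataclass(frozen=True)
class ScenarioSet:
    scenarios: tuple[Scenario, ...]

    def __post_init__(self) -> None:
        if not self.scenarios[0].is_nominal:
            raise ValueError("first scenario must be the nominal one")

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def __getitem__(self, i: int) -> Scenario:
        return self.scenarios[i]

    @property
    def nominal_index(self) -> int:
        return 0

    def to_json(self) -> str:
        return json.dumps(
            [
                {"label": s.label, "setup_shift_mm": s.setup_shift_mm, "range_scale": s.range_scale}
                for s in self.scenarios
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSet":
        return cls(
            tuple(
                Scenario(tuple(d["setup_shift_mm"]), d["range_scale"], d["label"])
                for d in json.loads(text)
            )
        )


def build_scenarios(
    setup_mm: float = 3.0, range_pct: float = 3.0, mode: str = "robust"
) -> ScenarioSet:
    """Build the scenario set: 21 scenarios in robust mode, 1 in nominal_only.

    Order: nominal; range-only under/over; 6 setup-only (±x, ±y, ±z);
    6 setup × undershoot; 6 setup × overshoot.
    """
    if setup_mm < 0 or range_pct < 0:
        raise ValueError("setup_mm and range_pct must be nonnegative")
    nominal = Scenario((0.0, 0.0, 0.0), 1.0, "nominal")
    if mode == "nominal_only":
        return ScenarioSet((nominal,))
    if mode != "robust":
        raise ValueError(f"unknown scenario mode {mode!r}")

    under = 1.0 + range_pct / 100.0
    over = 1.0 - range_pct / 100.0
    shifts = []
    for axis, ax in enumerate("xyz"):
        for sign, sg in ((+1.0, "+"), (-1.0, "-")):
            v = [0.0, 0.0, 0.0]
            v[axis] = sign * setup_mm
            shifts.append((tuple(v), f"{sg}{ax}"))

    scens = [nominal]
    scens.append(Scenario((0.0, 0.0, 0.0), under, "undershoot"))
    scens.append(Scenario((0.0, 0.0, 0.0), over, "overshoot"))
    scens += [Scenario(v, 1.0, f"setup{lab}") for v, lab in shifts]
    scens += [Scenario(v, under, f"setup{lab}_under") for v, lab in shifts]
    scens += [Scenario(v, over, f"setup{lab}_over") for v, lab in shifts]
    return ScenarioSet(tuple(scens))


def voxelwise_aggregate(doses: list[np.ndarray], which: str) -> np.ndarray:
    """Element-wise extreme over scenario dose rasters (VWmin / VWmax)."""
    if which not in ("min", "max"):
        raise ValueError(f"which must be 'min' or 'max', got {which!r}")
    arrs = [np.asarray(d) for d in doses]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError(f"dose raster shape mismatch: {a.shape} vs {shape}")
    stack = np.stack(arrs)
    return stack.min(axis=0) if which == "min" else stack.max(axis=0)
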