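"""Beam configurations, candidate spots and dose-influence matrices.

The dose engine is a deliberately simple analytic pencil-beam model: dose
per MU at a voxel is ``D(z; R) * exp(-r^2 / 2 sigma(z)^2)`` (times a fixed
MU calibration) where ``z`` is the radiological depth (WET) along the beam,
``R`` the spot's nominal range, ``D`` an analytic Bragg curve (plateau with
an erfc distal rolloff plus a Gaussian-smeared peak at ``z = R``), and
``sigma(z) = sqrt(sigma0^2 + (k z)^2)`` a depth-growing lateral penumbra.
A range shifter of water-equivalent thickness ``rs_wet_mm`` adds to the
upstream WET (pulling the in-patient peak back by exactly that amount) and
adds a fixed increment to sigma (wider penumbra — the clinical argument
against shifters when many fields are available).

Beams are parallel (infinite SAD). Geometry convention: the gantry rotates
in the axial (x, y) plane; gantry 0 points along +y, and the couch angle
rotates the beam about the room's vertical axis (the y axis for a supine
patient). Setup-error scenarios evaluate the nominal dose field at
``x + shift``; range scenarios scale the density during WET integration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import map_coordinates
from scipy.special import erfc

from .phantom import Phantom, GridSpec
from .scenarios import Scenario, ScenarioSet

__all__ = [
    "BeamConfig",
    "Spot",
    "DoseModel",
    "BeamlineSettings",
    "DoseInfluence",
    "make_beam_set",
    "beam_axes",
    "wet_at_points",
    "generate_candidate_spots",
    "block_spots",
    "compute_dij",
    "compute_dose_influence",
    "write_dose_influence",
    "read_dose_influence",
]

RS_WET_MM = 34.0  # clinical range-shifter water-equivalent thickness

CS4_ANGLES = [(150.0, 0.0), (60.0, 0.0), (300.0, 0.0), (210.0, 0.0)]
CS6_ANGLES = [(200.0, 0.0), (260.0, 20.0), (310.0, 0.0), (50.0, 0.0), (100.0, 340.0), (160.0, 0.0)]
CS6_NO_RS_GANTRY = (160.0, 200.0)


@dataclass(frozen=True)
class BeamConfig:
    gantry_deg: float
    couch_deg: float = 0.0
    range_shifter: bool = False
    rs_wet_mm: float = RS_WET_MM

    def __post_init__(self) -> None:
        if self.range_shifter and self.rs_wet_mm <= 0:
            raise ValueError("rs_wet_mm must be positive when range_shifter is set")


@dataclass(frozen=True)
class Spot:
    """One candidate pencil beam: (field, energy layer, lateral position)."""

    field_index: int
    el_index: int
    nominal_range_mm: float  # machine WET of the Bragg peak, incl. any shifter
    lateral_mm: tuple[float, float]
    id: int

    def __post_init__(self) -> None:
        if self.nominal_range_mm <= 0:
            raise ValueError("nominal_range_mm must be positive")


@dataclass(frozen=True)
class DoseModel:
    """Analytic Bragg/penumbra parameters (mm)."""

    sigma0_mm: float = 3.0  # lateral sigma at the surface
    sigma_growth: float = 0.04  # k in sigma(z) = sqrt(sigma0^2 + (k z)^2)
    sigma_rs_mm: float = 4.0  # additive sigma increment behind a range shifter
    peak_w80_mm: float = 6.0  # Bragg peak width at 80% of maximum
    plateau: float = 0.35  # entrance plateau level relative to peak
    sparsity_floor: float = 1e-4  # drop Dij entries below floor * column max
    mu_calibration: float = 3.0  # Gy per MU on the spot axis at the Bragg peak

    @property
    def peak_sigma_mm(self) -> float:
        # full width at 80% max of a Gaussian = 2 sigma sqrt(2 ln(1/0.8))
        return self.peak_w80_mm / (2.0 * np.sqrt(2.0 * np.log(1.0 / 0.8)))

    def depth_dose(self, z: np.ndarray, r: np.ndarray) -> np.ndarray:
        """Analytic Bragg curve, peak (== 1) at depth z = r."""
        z = np.asarray(z, dtype=float)
        sp_ = self.peak_sigma_mm
        peak = np.exp(-0.5 * ((z - r) / sp_) ** 2)
        rolloff = 0.5 * erfc((z - r) / (np.sqrt(2.0) * sp_))
        buildup = 1.0 + 0.6 * np.clip(z, 0.0, None) / np.maximum(r, 1e-9)
        return peak + self.plateau * np.minimum(buildup, 1.6) * rolloff

    def sigma(self, z: np.ndarray, range_shifter: bool) -> np.ndarray:
        s = np.sqrt(self.sigma0_mm**2 + (self.sigma_growth * np.asarray(z, dtype=float)) ** 2)
        return s + (self.sigma_rs_mm if range_shifter else 0.0)


@dataclass(frozen=True)
class BeamlineSettings:
    lateral_spacing_mm: float = 5.0
    el_spacing_mm: float = 5.0  # energy-layer separation in WET
    margin_mm: float = 8.0  # lateral and radiological expansion of the target
    raymarch_step_mm: float = 2.0
    model: DoseModel = field(default_factory=DoseModel)


# ---------------------------------------------------------------------------
# beam sets


def make_beam_set(
    mode: str, angles: list[tuple[float, float]] | None = None, range_shifter: bool = False
) -> list[BeamConfig]:
    """Beam configurations for a planning mode.

    ``pat36``/``utopia36``: 36 coplanar equiangular fields starting at 0 deg,
    no range shifter by default. ``cs4``/``cs6``: the clinical class-solution
    (gantry, couch) templates with their range-shifter rules (all fields for
    cs4; all but gantry 160/200 for cs6). ``bao_candidates``: 72 coplanar
    equiangular candidate fields. ``explicit``: caller-provided angles.
    """
    if mode in ("pat36", "utopia36"):
        return [BeamConfig(g, 0.0, range_shifter) for g in np.arange(36) * 10.0]
    if mode == "cs4":
        return [BeamConfig(g, c, True) for g, c in CS4_ANGLES]
    if mode == "cs6":
        return [BeamConfig(g, c, g not in CS6_NO_RS_GANTRY) for g, c in CS6_ANGLES]
    if mode == "bao_candidates":
        return [BeamConfig(g, 0.0, range_shifter) for g in np.arange(72) * 5.0]
    if mode == "explicit":
        if not angles:
            raise ValueError("explicit mode requires a list of (gantry, couch) angles")
        return [BeamConfig(g, c, range_shifter) for g, c in angles]
    raise ValueError(f"unknown beam-set mode {mode!r}")


def beam_axes(beam: BeamConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit beam direction and the two lateral axes of the beam's-eye view."""
    g = np.deg2rad(beam.gantry_deg)
    d = np.array([np.sin(g), np.cos(g), 0.0])
    e1 = np.array([np.cos(g), -np.sin(g), 0.0])
    e2 = np.cross(d, e1)  # = (0, 0, -1) at couch 0
    c = np.deg2rad(beam.couch_deg)
    if c != 0.0:
        ry = np.array(
            [[np.cos(c), 0.0, np.sin(c)], [0.0, 1.0, 0.0], [-np.sin(c), 0.0, np.cos(c)]]
        )
        d, e1, e2 = ry @ d, ry @ e1, ry @ e2
    return d, e1, e2


# ---------------------------------------------------------------------------
# radiological depth


def _sample_density(phantom: Phantom, pts: np.ndarray) -> np.ndarray:
    """Trilinear density lookup at world points; quasi-2D slabs extrude in z."""
    idx = phantom.grid.world_to_index(pts)
    if phantom.grid.shape[2] == 1:
        idx = idx.copy()
        idx[:, 2] = 0.0
    return map_coordinates(phantom.density, idx.T, order=1, mode="constant", cval=0.0)


def _grid_diameter(grid: GridSpec) -> float:
    lo, hi = grid.bounds_mm()
    return float(np.linalg.norm(hi - lo))


def wet_at_points(
    phantom: Phantom,
    direction: np.ndarray,
    points: np.ndarray,
    range_scale: float = 1.0,
    step_mm: float = 2.0,
) -> np.ndarray:
    """Water-equivalent depth of each point along a parallel beam.

    Midpoint-rule line integral of (scenario-scaled) density from outside the
    grid down to each point, marching upstream along ``-direction``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    diam = _grid_diameter(phantom.grid)
    n_steps = max(int(np.ceil(diam / step_mm)), 1)
    offs = (np.arange(n_steps) + 0.5) * step_mm
    sample = pts[None, :, :] - offs[:, None, None] * direction[None, None, :]
    dens = _sample_density(phantom, sample.reshape(-1, 3)).reshape(n_steps, -1)
    return dens.sum(axis=0) * step_mm * range_scale


# ---------------------------------------------------------------------------
# candidate spots


def isocenter(phantom: Phantom) -> np.ndarray:
    """Isocenter = center of mass of the elective target (clinical rule)."""
    elective = phantom.structures_with_role("target_elective")
    if elective:
        return phantom.com_mm(elective[0])
    (high,) = phantom.structures_with_role("target_high")
    return phantom.com_mm(high)


def _lateral_grid(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Multiples of ``spacing`` covering [lo, hi]; at least one position."""
    k_lo = int(np.ceil(lo / spacing - 1e-9))
    k_hi = int(np.floor(hi / spacing + 1e-9))
    if k_lo > k_hi:
        k_lo = k_hi = int(np.round((lo + hi) / (2.0 * spacing)))
    return np.arange(k_lo, k_hi + 1) * spacing


def generate_candidate_spots(
    phantom: Phantom,
    beam: BeamConfig,
    field_index: int = 0,
    settings: BeamlineSettings | None = None,
    id_start: int = 0,
) -> list[Spot]:
    """Candidate spots for one field.

    A lateral grid covers the union-target projection in beam's-eye view,
    expanded by the margin; per lateral position, energy layers sit on a
    global WET grid spanning the target's radiological depth interval along
    that ray, again expanded by the margin. With a range shifter the stored
    nominal range includes the shifter's WET so the in-patient peak still
    spans the target.
    """
    st = settings or BeamlineSettings()
    tmask = phantom.union_target_mask().ravel()
    if not tmask.any():
        warnings.warn("union target is empty; no candidate spots", stacklevel=2)
        return []
    d, e1, e2 = beam_axes(beam)
    iso = isocenter(phantom)
    centers = phantom.grid.voxel_centers()[tmask]
    rel = centers - iso
    lat1 = rel @ e1
    lat2 = rel @ e2
    wet = wet_at_points(phantom, d, centers, 1.0, st.raymarch_step_mm)

    m = st.margin_mm
    grid1 = _lateral_grid(lat1.min() - m, lat1.max() + m, st.lateral_spacing_mm)
    grid2 = _lateral_grid(lat2.min() - m, lat2.max() + m, st.lateral_spacing_mm)
    half = st.lateral_spacing_mm / 2.0
    rs_off = beam.rs_wet_mm if beam.range_shifter else 0.0

    spots: list[Spot] = []
    sid = id_start
    for l1 in grid1:
        near1 = np.abs(lat1 - l1) <= half + m
        if not near1.any():
            continue
        for l2 in grid2:
            near = near1 & (np.abs(lat2 - l2) <= half + m)
            if not near.any():
                continue
            w = wet[near]
            prox, dist = w.min() - m, w.max() + m
            k_lo = int(np.ceil(prox / st.el_spacing_mm - 1e-9))
            k_hi = int(np.floor(dist / st.el_spacing_mm + 1e-9))
            if k_lo > k_hi:
                k_lo = k_hi = max(int(np.round(w.mean() / st.el_spacing_mm)), 1)
            k_lo = max(k_lo, 1)  # no zero/negative-range layers
            for k in range(k_lo, k_hi + 1):
                spots.append(
                    Spot(field_index, k, k * st.el_spacing_mm + rs_off, (float(l1), float(l2)), sid)
                )
                sid += 1
    return spots


# ---------------------------------------------------------------------------
# spot blocking


def block_spots(
    spots: list[Spot],
    phantom: Phantom,
    blocking_names: list[str],
    beams: list[BeamConfig],
    settings: BeamlineSettings | None = None,
) -> list[Spot]:
    """Remove spots whose entrance ray (upstream of the Bragg peak) crosses a
    blocking structure. Order and ids are preserved."""
    st = settings or BeamlineSettings()
    for name in blocking_names:
        if name not in phantom.masks:
            raise KeyError(f"unknown blocking structure {name!r}")
    if not blocking_names or not spots:
        return list(spots)

    blocked_mask = np.zeros(phantom.grid.shape, dtype=bool)
    for name in blocking_names:
        blocked_mask |= phantom.masks[name]
    iso = isocenter(phantom)
    diam = _grid_diameter(phantom.grid)
    step = min(phantom.grid.spacing_mm) / 2.0
    n_steps = int(np.ceil(2.0 * diam / step))
    ts = -diam + (np.arange(n_steps) + 0.5) * step  # ray parameter around iso

    keep: list[Spot] = []
    by_field: dict[int, list[Spot]] = {}
    for s in spots:
        by_field.setdefault(s.field_index, []).append(s)

    keep_ids: set[int] = set()
    for fi, fspots in by_field.items():
        beam = beams[fi]
        d, e1, e2 = beam_axes(beam)
        base = np.array([iso + s.lateral_mm[0] * e1 + s.lateral_mm[1] * e2 for s in fspots])
        pts = base[:, None, :] + ts[None, :, None] * d[None, None, :]  # (ns, K, 3)
        flat = pts.reshape(-1, 3)
        idx = phantom.grid.world_to_index(flat)
        if phantom.grid.shape[2] == 1:
            idx[:, 2] = 0.0
        hit = map_coordinates(
            blocked_mask.astype(np.float32), idx.T, order=0, mode="constant", cval=0.0
        ).reshape(len(fspots), n_steps)
        dens = _sample_density(phantom, flat).reshape(len(fspots), n_steps)
        wet_cum = np.cumsum(dens, axis=1) * step
        rs_off = beam.rs_wet_mm if beam.range_shifter else 0.0
        for i, s in enumerate(fspots):
            in_range = s.nominal_range_mm - rs_off
            upstream = wet_cum[i] <= in_range + 1e-9
            if not (hit[i] > 0.5)[upstream].any():
                keep_ids.add(s.id)

    return [s for s in spots if s.id in keep_ids]


# ---------------------------------------------------------------------------
# dose influence


def compute_dij(
    phantom: Phantom,
    beams: list[BeamConfig],
    spots: list[Spot],
    scenario: Scenario,
    settings: BeamlineSettings | None = None,
) -> sp.csc_matrix:
    """Sparse (n_voxels, n_spots) dose-per-MU block for one scenario.

    Dose is restricted to body voxels (the model deposits nothing in air).
    """
    st = settings or BeamlineSettings()
    model = st.model
    grid = phantom.grid
    n_vox = grid.n_voxels
    if not spots:
        return sp.csc_matrix((n_vox, 0))

    body_flat = phantom.body_mask.ravel()
    vox_idx = np.flatnonzero(body_flat)
    shift = np.asarray(scenario.setup_shift_mm, dtype=float)
    if grid.shape[2] == 1:
        # quasi-2D slabs model one slice of a z-extruded anatomy: spot rows
        # exist at every z, so a z setup shift maps the dose onto itself
        shift = shift * np.array([1.0, 1.0, 0.0])
    q = grid.voxel_centers()[vox_idx] + shift
    iso = isocenter(phantom)

    cols_data = [None] * len(spots)
    by_field: dict[int, list[int]] = {}
    for j, s in enumerate(spots):
        by_field.setdefault(s.field_index, []).append(j)

    for fi, js in by_field.items():
        beam = beams[fi]
        d, e1, e2 = beam_axes(beam)
        wet = wet_at_points(phantom, d, q, scenario.range_scale, st.raymarch_step_mm)
        rs_off = beam.rs_wet_mm if beam.range_shifter else 0.0
        z_eff = wet + rs_off
        rel = q - iso
        lat1, lat2 = rel @ e1, rel @ e2
        sig = model.sigma(z_eff, beam.range_shifter)
        for j in js:
            s = spots[j]
            dz = model.depth_dose(z_eff, s.nominal_range_mm)
            r2 = (lat1 - s.lateral_mm[0]) ** 2 + (lat2 - s.lateral_mm[1]) ** 2
            # on-axis dose is D(z) itself: the depth of maximum equals the
            # nominal range by construction (no fluence-spreading factor)
            dose = model.mu_calibration * dz * np.exp(-0.5 * r2 / sig**2)
            peak = dose.max(initial=0.0)
            if peak > 0:
                dose[dose < model.sparsity_floor * peak] = 0.0
            nz = np.flatnonzero(dose)
            cols_data[j] = (vox_idx[nz], dose[nz])

    rows, vals, indptr = [], [], [0]
    for col in cols_data:
        r, v = col if col is not None else (np.array([], int), np.array([]))
        rows.append(r)
        vals.append(v)
        indptr.append(indptr[-1] + len(r))
    return sp.csc_matrix(
        (np.concatenate(vals), np.concatenate(rows), np.array(indptr)),
        shape=(n_vox, len(spots)),
    )


@dataclass
class DoseInfluence:
    """Per-scenario sparse dose-per-MU matrices over a shared spot list."""

    grid: GridSpec
    beams: list[BeamConfig]
    spots: list[Spot]
    scenario_set: ScenarioSet
    matrices: list[sp.csc_matrix]  # one (n_voxels, n_spots) block per scenario

    def __post_init__(self) -> None:
        ns = len(self.spots)
        for m in self.matrices:
            if m.shape[1] != ns:
                raise ValueError("matrix column count does not match spot count")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def nominal(self) -> sp.csc_matrix:
        return self.matrices[self.scenario_set.nominal_index]

    def dose(self, weights: np.ndarray, scenario_index: int = 0) -> np.ndarray:
        """Flat dose raster (n_voxels,) for spot weights in one scenario."""
        return np.asarray(self.matrices[scenario_index] @ weights).ravel()

    def scenario_doses(self, weights: np.ndarray) -> list[np.ndarray]:
        return [self.dose(weights, i) for i in range(len(self.scenario_set))]

    def field_columns(self, field_index: int) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.spots) if s.field_index == field_index], int)

    def restrict(self, columns: np.ndarray) -> "DoseInfluence":
        """New DoseInfluence over a subset of spot columns (ids preserved)."""
        columns = np.asarray(columns, int)
        return DoseInfluence(
            grid=self.grid,
            beams=self.beams,
            spots=[self.spots[j] for j in columns],
            scenario_set=self.scenario_set,
            matrices=[m[:, columns].tocsc() for m in self.matrices],
        )

    def columns_for_ids(self, spot_ids: set[int]) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.spots) if s.id in spot_ids], int)


def compute_dose_influence(
    phantom: Phantom,
    beams: list[BeamConfig],
    scenario_set: ScenarioSet,
    settings: BeamlineSettings | None = None,
    block: bool = True,
) -> DoseInfluence:
    """Full pipeline front end: candidate spots per beam, spot blocking,
    then one Dij block per scenario."""
    st = settings or BeamlineSettings()
    spots: list[Spot] = []
    for fi, beam in enumerate(beams):
        spots += generate_candidate_spots(phantom, beam, fi, st, id_start=len(spots))
    if block:
        blocking = phantom.structures_with_role("blocking")
        if blocking:
            spots = block_spots(spots, phantom, blocking, beams, st)
    matrices = [compute_dij(phantom, beams, spots, sc, st) for sc in scenario_set]
    return DoseInfluence(phantom.grid, list(beams), spots, scenario_set, matrices)


# ---------------------------------------------------------------------------
# I/O (spots.json + per-scenario Matrix Market blocks)


def write_dose_influence(dij: DoseInfluence, path: str | Path) -> None:
    from scipy.io import mmwrite

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "spots.json").write_text(
        json.dumps(
            {
                "grid": asdict(dij.grid),
                "beams": [asdict(b) for b in dij.beams],
                "spots": [asdict(s) for s in dij.spots],
            },
            indent=2,
        )
    )
    (path / "grid.json").write_text(json.dumps(asdict(dij.grid), indent=2))
    (path / "scenarios.json").write_text(dij.scenario_set.to_json())
    for i, m in enumerate(dij.matrices):
        mmwrite(str(path / f"dij_s{i:02d}.mtx"), m)


def read_dose_influence(path: str | Path) -> DoseInfluence:
    from scipy.io import mmread

    path = Path(path)
    meta = json.loads((path / "spots.json").read_text())
    grid = GridSpec(
        tuple(meta["grid"]["shape"]),
        tuple(meta["grid"]["spacing_mm"]),
        tuple(meta["grid"]["origin_mm"]),
    )
    beams = [BeamConfig(**b) for b in meta["beams"]]
    spots = [
        Spot(s["field_index"], s["el_index"], s["nominal_range_mm"], tuple(s["lateral_mm"]), s["id"])
        for s in meta["spots"]
    ]
    scen = ScenarioSet.from_json((path / "scenarios.json").read_text())
    mats = [sp.csc_matrix(mmread(str(path / f"dij_s{i:02d}.mtx"))) for i in range(len(scen))]
    return DoseInfluence(grid, beams, spots, scen, mats)
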