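"""Synthetic oropharynx-like planning phantoms.

A phantom is a relative-stopping-power raster plus named binary structure
masks on a regular voxel grid. Phantoms stand in for planning CTs and
delineations of head-and-neck patients: two nested target volumes
(``ctv70``, ``ctv54``), bilateral parotid-like organs at risk, a midline
posterior cord-like cylinder, a pharyngeal-constrictor shell, and two
shoulder-like blocking slabs through which pencil beams must not pass.

Conventions
-----------
* 0-based voxel indices; world coordinate of voxel ``i`` along an axis is
  ``origin + (i + 0.5) * spacing`` (voxel centers). All lengths in mm.
* Quasi-2D slabs (``nz == 1``) are first-class: structures are defined in
  3D and simply rasterized on the single slice, and downstream ray tracing
  treats the slab as extruded along z.
* Masks are rasterized with a voxel-center-inside test and clipped to the
  body; the body is therefore a superset of every structure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "StructureSpec",
    "PhantomSpec",
    "Phantom",
    "BoundsError",
    "FormatError",
    "generate_phantom",
    "default_spec",
    "default_quasi2d_spec",
    "write_phantom",
    "read_phantom",
]

ROLES = (
    "target_high",
    "target_elective",
    "oar_serial",
    "oar_parallel",
    "body",
    "blocking",
)


class BoundsError(ValueError):
    """A structure does not fit inside the phantom grid (or is degenerate)."""


class FormatError(ValueError):
    """On-disk phantom rasters are inconsistent with each other."""


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: shape ``(nx, ny, nz)``, spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three integers >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"grid spacings must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm[axis]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx*ny*nz, 3), C order."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (center of voxel i maps to i)."""
        p = np.atleast_2d(points)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm) - 0.5

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin_mm)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing_mm)
        return lo, hi


@dataclass
class StructureSpec:
    """Parametric structure: an analytic shape, a role and an optional density.

    Shapes (all sizes are half-extents / radii in mm):

    * ``ellipsoid``: ``size`` = three semi-axes around ``center``
    * ``cylinder``: ``size = (r, r, half_length)``, axis along z
    * ``shell``: ellipsoidal shell, ``size`` = outer semi-axes,
      ``thickness_mm`` the radial wall thickness
    * ``box``: ``size`` = three half-extents
    """

    name: str
    role: str
    shape: str
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    thickness_mm: float = 0.0
    density: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.shape not in ("ellipsoid", "cylinder", "shell", "box"):
            raise ValueError(f"unknown shape {self.shape!r} for {self.name!r}")


@dataclass
class PhantomSpec:
    """Full parametric phantom description (JSON-serializable)."""

    grid: GridSpec
    structures: list[StructureSpec]
    body_density: float = 1.0
    jitter_mm: float = 0.0
    radius_jitter_frac: float = 0.0

    def to_json(self) -> str:
        d = {
            "grid": asdict(self.grid),
            "structures": [asdict(s) for s in self.structures],
            "body_density": self.body_density,
            "jitter_mm": self.jitter_mm,
            "radius_jitter_frac": self.radius_jitter_frac,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        return cls(
            grid=GridSpec(
                tuple(d["grid"]["shape"]),
                tuple(d["grid"]["spacing_mm"]),
                tuple(d["grid"].get("origin_mm", (0, 0, 0))),
            ),
            structures=[
                StructureSpec(
                    name=s["name"],
                    role=s["role"],
                    shape=s["shape"],
                    center_mm=tuple(s["center_mm"]),
                    size_mm=tuple(s["size_mm"]),
                    thickness_mm=s.get("thickness_mm", 0.0),
                    density=s.get("density"),
                )
                for s in d["structures"]
            ],
            body_density=d.get("body_density", 1.0),
            jitter_mm=d.get("jitter_mm", 0.0),
            radius_jitter_frac=d.get("radius_jitter_frac", 0.0),
        )


@dataclass
class Phantom:
    """Density raster + structure masks on a shared grid."""

    grid: GridSpec
    density: np.ndarray  # (nx, ny, nz), relative stopping power, >= 0
    masks: dict[str, np.ndarray]  # name -> bool raster, same shape
    roles: dict[str, str]  # name -> role

    def __post_init__(self) -> None:
        if self.density.shape != self.grid.shape:
            raise ValueError("density raster shape does not match grid")
        for name, m in self.masks.items():
            if m.shape != self.grid.shape:
                raise ValueError(f"mask {name!r} shape does not match grid")

    def structures_with_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    @property
    def body_mask(self) -> np.ndarray:
        (name,) = self.structures_with_role("body")
        return self.masks[name]

    def union_target_mask(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for role in ("target_high", "target_elective"):
            for n in self.structures_with_role(role):
                out |= self.masks[n]
        return out

    def mask_volume_ml(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_mm3 / 1000.0

    def com_mm(self, name: str) -> np.ndarray:
        """Center of mass (mm) of a structure mask — e.g. the isocenter rule."""
        idx = np.argwhere(self.masks[name])
        if idx.size == 0:
            raise ValueError(f"mask {name!r} is empty")
        centers = np.asarray(self.grid.origin_mm) + (idx + 0.5) * np.asarray(self.grid.spacing_mm)
        return centers.mean(axis=0)


# ---------------------------------------------------------------------------
# rasterization


def _inside(struct: StructureSpec, pts: np.ndarray) -> np.ndarray:
    c = np.asarray(struct.center_mm, dtype=float)
    s = np.asarray(struct.size_mm, dtype=float)
    d = pts - c
    if struct.shape == "ellipsoid":
        return np.sum((d / s) ** 2, axis=1) <= 1.0
    if struct.shape == "cylinder":
        r = s[0]
        radial = (d[:, 0] / r) ** 2 + (d[:, 1] / r) ** 2 <= 1.0
        return radial & (np.abs(d[:, 2]) <= s[2])
    if struct.shape == "shell":
        outer = np.sum((d / s) ** 2, axis=1) <= 1.0
        inner_ax = np.maximum(s - struct.thickness_mm, 1e-6)
        inner = np.sum((d / inner_ax) ** 2, axis=1) <= 1.0
        return outer & ~inner
    if struct.shape == "box":
        return np.all(np.abs(d) <= s, axis=1)
    raise AssertionError(struct.shape)


def _check_bounds(struct: StructureSpec, grid: GridSpec) -> None:
    if any(x <= 0 for x in struct.size_mm):
        raise BoundsError(f"structure {struct.name!r} has a non-positive size: {struct.size_mm}")
    lo, hi = grid.bounds_mm()
    c = np.asarray(struct.center_mm)
    s = np.asarray(struct.size_mm)
    # Bounding boxes may run off the grid along z for extruded quasi-2D shapes.
    axes = range(3) if grid.shape[2] > 1 else range(2)
    for a in axes:
        if c[a] - s[a] < lo[a] - 1e-9 or c[a] + s[a] > hi[a] + 1e-9:
            raise BoundsError(
                f"structure {struct.name!r} exceeds grid bounds along axis {a}: "
                f"[{c[a] - s[a]:.1f}, {c[a] + s[a]:.1f}] vs [{lo[a]:.1f}, {hi[a]:.1f}]"
            )


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Rasterize a parametric phantom. Deterministic for fixed (spec, seed).

    ``seed`` drives the optional anatomy jitter (``jitter_mm`` on structure
    centers, ``radius_jitter_frac`` on sizes) used to emulate inter-patient
    variation in planning studies; with both set to 0 the spec is rasterized
    verbatim.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid
    pts = grid.voxel_centers()

    structs: list[StructureSpec] = []
    for s in spec.structures:
        center = np.asarray(s.center_mm, dtype=float)
        size = np.asarray(s.size_mm, dtype=float)
        if s.role != "body":
            center = center + rng.uniform(-spec.jitter_mm, spec.jitter_mm, 3)
            size = size * (1.0 + rng.uniform(-spec.radius_jitter_frac, spec.radius_jitter_frac))
        structs.append(
            StructureSpec(
                s.name, s.role, s.shape, tuple(center), tuple(size), s.thickness_mm, s.density
            )
        )

    body = [s for s in structs if s.role == "body"]
    if len(body) != 1:
        raise ValueError("spec must contain exactly one body structure")
    # The body may extend beyond the grid (the grid is a window into the
    # anatomy); only degenerate sizes are rejected for it.
    if any(x <= 0 for x in body[0].size_mm):
        raise BoundsError(
            f"structure {body[0].name!r} has a non-positive size: {body[0].size_mm}"
        )
    body_mask = _inside(body[0], pts).reshape(grid.shape)
    if not body_mask.any():
        raise BoundsError(f"body structure {body[0].name!r} rasterizes to zero volume")

    masks: dict[str, np.ndarray] = {body[0].name: body_mask}
    roles: dict[str, str] = {body[0].name: "body"}
    density = np.where(body_mask, spec.body_density, 0.0)

    for s in structs:
        if s.role == "body":
            continue
        _check_bounds(s, grid)
        m = _inside(s, pts).reshape(grid.shape) & body_mask
        masks[s.name] = m
        roles[s.name] = s.role
        if s.density is not None:
            density = np.where(m, float(s.density), density)

    # Overlap between targets and OARs is clinically real; surface it but allow it.
    for tname in [n for n, r in roles.items() if r == "target_high"]:
        for oname in [n for n, r in roles.items() if r.startswith("oar")]:
            if (masks[tname] & masks[oname]).any():
                warnings.warn(
                    f"target {tname!r} overlaps OAR {oname!r}", stacklevel=2
                )

    return Phantom(grid=grid, density=density, masks=masks, roles=roles)


# ---------------------------------------------------------------------------
# default specs


def default_spec() -> PhantomSpec:
    """3D oropharynx-like phantom.

    Target volumes are sized to the ~83 mL high-dose and ~270 mL elective
    volumes typical of oropharyngeal cases; all other geometry is schematic.
    +y is posterior, +x is patient-left, +z superior.
    """
    grid = GridSpec((64, 64, 40), (3.0, 3.0, 3.0), (-96.0, -96.0, -60.0))
    structures = [
        StructureSpec("body", "body", "ellipsoid", (0, 0, 0), (85, 92, 200)),
        StructureSpec("ctv70", "target_high", "ellipsoid", (12, 8, 0), (27, 27, 27)),
        StructureSpec("ctv54", "target_elective", "ellipsoid", (0, 8, 0), (55, 40, 30)),
        StructureSpec("parotid_l", "oar_parallel", "ellipsoid", (-60, -5, 5), (12, 16, 22)),
        StructureSpec("parotid_r", "oar_parallel", "ellipsoid", (60, -5, 5), (12, 16, 22)),
        StructureSpec("constrictor", "oar_parallel", "shell", (0, 30, 0), (24, 18, 45), 7.0),
        StructureSpec("cord", "oar_serial", "cylinder", (0, 55, 0), (5.5, 5.5, 60)),
        StructureSpec("shoulder_l", "blocking", "box", (-55, 45, -46), (16, 16, 13), density=1.3),
        StructureSpec("shoulder_r", "blocking", "box", (55, 45, -46), (16, 16, 13), density=1.3),
    ]
    return PhantomSpec(grid=grid, structures=structures)


def default_quasi2d_spec(n: int = 48, spacing_mm: float = 4.0) -> PhantomSpec:
    """Single-slice (nz = 1) phantom for fast optimization runs.

    Same anatomy schema as :func:`default_spec` collapsed onto one axial
    slice; shapes are extruded along z so the slice sees their mid-plane
    cross-sections.
    """
    half = n * spacing_mm / 2.0
    grid = GridSpec((n, n, 1), (spacing_mm,) * 3, (-half, -half, -spacing_mm / 2.0))
    zext = 1e4  # extruded along z
    scale = half / 96.0  # keep anatomy proportional to the grid extent
    def sz(*v):
        return tuple(x * scale for x in v[:2]) + (zext,)
    def ct(*v):
        return tuple(x * scale for x in v[:2]) + (0.0,)
    structures = [
        StructureSpec("body", "body", "ellipsoid", ct(0, 0), sz(80, 88)),
        StructureSpec("ctv70", "target_high", "ellipsoid", ct(12, 10), sz(16, 16)),
        StructureSpec("ctv54", "target_elective", "ellipsoid", ct(0, 8), sz(44, 30)),
        StructureSpec("parotid_l", "oar_parallel", "ellipsoid", ct(-58, 0), sz(12, 14)),
        StructureSpec("parotid_r", "oar_parallel", "ellipsoid", ct(58, 0), sz(12, 14)),
        StructureSpec("constrictor", "oar_parallel", "shell", ct(0, 46), sz(22, 16), 6.0 * scale),
        StructureSpec("cord", "oar_serial", "cylinder", ct(0, 70), (6 * scale, 6 * scale, zext)),
        StructureSpec("shoulder_l", "blocking", "box", ct(-52, 52), sz(12, 12), density=1.3),
        StructureSpec("shoulder_r", "blocking", "box", ct(52, 52), sz(12, 12), density=1.3),
    ]
    return PhantomSpec(grid=grid, structures=structures)


# ---------------------------------------------------------------------------
# NRRD I/O (via SimpleITK)


def _write_nrrd(path: Path, arr: np.ndarray, grid: GridSpec) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.astype(np.float32).T))
    img.SetSpacing(tuple(grid.spacing_mm))
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(grid.origin_mm, grid.spacing_mm)))
    sitk.WriteImage(img, str(path), useCompression=False)


def _read_nrrd(path: Path) -> tuple[np.ndarray, GridSpec]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T  # back to (nx, ny, nz)
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
    return np.asarray(arr), GridSpec(arr.shape, spacing, origin)


def write_phantom(phantom: Phantom, path: str | Path) -> None:
    """Write density + masks as NRRD rasters plus a roles/metadata JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_nrrd(path / "density.nrrd", phantom.density, phantom.grid)
    for name, m in phantom.masks.items():
        _write_nrrd(path / f"mask_{name}.nrrd", m.astype(np.float32), phantom.grid)
    meta = {
        "grid": asdict(phantom.grid),
        "roles": phantom.roles,
        "structures": sorted(phantom.masks),
    }
    (path / "phantom.json").write_text(json.dumps(meta, indent=2))


def read_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    meta = json.loads((path / "phantom.json").read_text())
    density, grid = _read_nrrd(path / "density.nrrd")
    masks: dict[str, np.ndarray] = {}
    for name in meta["structures"]:
        arr, g = _read_nrrd(path / f"mask_{name}.nrrd")
        if g.shape != grid.shape or not np.allclose(g.spacing_mm, grid.spacing_mm):
            raise FormatError(
                f"mask {name!r} grid {g.shape}/{g.spacing_mm} does not match "
                f"density grid {grid.shape}/{grid.spacing_mm}"
            )
        masks[name] = arr > 0.5
    return Phantom(grid=grid, density=density, masks=masks, roles=dict(meta["roles"]))
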