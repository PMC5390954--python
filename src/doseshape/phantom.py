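"""Voxelized patient model and seeded synthetic prostate phantoms.

The phantom emulates a male pelvis as segmented for prostate IMRT
planning: a body contour, a planning target volume (PTV) around the
prostate, a simultaneous integrated boost volume inside the PTV, the
rectum posterior to the PTV and the bladder anterior/superior to it.
Organs are jittered superellipsoids; the jitter is drawn from a seeded
generator so the same spec always yields a voxel-identical phantom.

Axis convention (fixed throughout the package): x = left-right,
y = anterior-posterior (increasing posterior), z = inferior-superior
(increasing superior). Voxel indices are 0-based and voxel centers sit
at ``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "VoxelGrid",
    "VOI",
    "Prescription",
    "OrganSpec",
    "PhantomSpec",
    "GeometryError",
    "generate_phantom",
    "nontumor_mask",
    "default_phantom_spec",
]


class GeometryError(ValueError):
    """Raised when requested organ geometry cannot fit the voxel grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel grid.

    Parameters
    ----------
    dims : (nx, ny, nz) voxel counts.
    spacing : voxel size in mm along (x, y, z).
    origin : position in mm of the grid corner; voxel center ``i`` is at
        ``origin + (i + 0.5) * spacing``.
    """

    dims: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.dims

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def center_mm(self) -> np.ndarray:
        """Physical center of the grid."""
        return np.asarray(self.origin) + np.asarray(self.dims) * np.asarray(self.spacing) / 2.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (mm)."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of all voxel center coordinates, C-order flat index."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def flat_index(self, ijk: Tuple[int, int, int]) -> int:
        return int(np.ravel_multi_index(ijk, self.dims))

    def point_to_index(self, p_mm: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to voxel indices (floor convention)."""
        rel = (np.asarray(p_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)
        return np.floor(rel).astype(np.int64)


@dataclass
class VOI:
    """A volume of interest: a named boolean mask over the grid."""

    name: str
    role: str  # one of body / target / boost / oar
    mask: np.ndarray

    _ROLES = ("body", "target", "boost", "oar")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def centroid_index(self) -> np.ndarray:
        """Mean voxel index of the mask, per axis."""
        if not self.mask.any():
            raise ValueError(f"VOI {self.name!r} is empty")
        return np.array([idx.mean() for idx in np.nonzero(self.mask)])


@dataclass(frozen=True)
class Prescription:
    """Per-VOI prescribed dose in Gy; PTV and boost entries are mandatory."""

    ptv_gy: float
    boost_gy: float
    other: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ptv_gy > 0 and self.boost_gy > 0):
            raise ValueError("prescribed doses must be positive")
        if self.boost_gy < self.ptv_gy:
            raise ValueError(
                f"boost prescription ({self.boost_gy} Gy) must be >= "
                f"PTV prescription ({self.ptv_gy} Gy)"
            )

    @property
    def mean_target_gy(self) -> float:
        """Average of PTV and boost prescriptions (the open-field D50% goal)."""
        return 0.5 * (self.ptv_gy + self.boost_gy)


@dataclass(frozen=True)
class OrganSpec:
    """One superellipsoid organ: center/radii in mm relative to grid center."""

    center_mm: Tuple[float, float, float]
    radii_mm: Tuple[float, float, float]
    exponent: float = 2.2


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for a synthetic pelvic phantom.

    The same spec always produces a voxel-identical phantom: all shape
    jitter is drawn from ``numpy.random.default_rng(seed)`` in a fixed
    order.
    """

    seed: int = 0
    dims: Tuple[int, int, int] = (64, 64, 48)
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    jitter_mm: float = 3.0
    ptv_boost_margin_mm: float = 10.0
    oar_gap_mm: float = 6.0
    body: OrganSpec = OrganSpec((0.0, 0.0, 0.0), (116.0, 100.0, 1e4), 2.0)
    ptv: OrganSpec = OrganSpec((0.0, 10.0, -10.0), (34.0, 28.0, 32.0), 2.2)
    boost: OrganSpec = OrganSpec((0.0, 8.0, -12.0), (19.0, 15.0, 18.0), 2.2)
    rectum: OrganSpec = OrganSpec((0.0, 58.0, -8.0), (14.0, 14.0, 60.0), 2.0)
    bladder: OrganSpec = OrganSpec((0.0, -55.0, 18.0), (36.0, 30.0, 30.0), 2.2)
    ptv_gy: float = 73.0
    boost_gy: float = 76.0


def default_phantom_spec(seed: int = 0, clinical_scale: bool = False) -> PhantomSpec:
    """Convenience presets.

    The default is a fast 64x64x48 grid at 4 mm isotropic spacing;
    ``clinical_scale=True`` gives 256x256x160 voxels at 1.95x1.95x2.0 mm,
    comparable to a clinical pencil-beam dose grid.
    """
    if clinical_scale:
        return PhantomSpec(seed=seed, dims=(256, 256, 160), spacing=(1.95, 1.95, 2.0))
    return PhantomSpec(seed=seed)


def _superellipsoid_mask(
    grid: VoxelGrid,
    organ: OrganSpec,
    rng: np.random.Generator,
    jitter_mm: float,
) -> np.ndarray:
    """Boolean mask of a jittered superellipsoid.

    The boundary radius is modulated by a smooth low-order angular field
    whose five coefficients are drawn from ``rng``; the field has zero
    mean over directions so the jitter deforms rather than inflates the
    organ.
    """
    coeffs = rng.standard_normal(5)  # always drawn, keeps the stream aligned
    c = np.asarray(grid.center_mm) + np.asarray(organ.center_mm)
    r = np.asarray(organ.radii_mm, dtype=float)
    p = float(organ.exponent)

    xs = grid.axis_centers(0) - c[0]
    ys = grid.axis_centers(1) - c[1]
    zs = grid.axis_centers(2) - c[2]
    dx, dy, dz = np.meshgrid(xs, ys, zs, indexing="ij")

    s = (
        np.abs(dx / r[0]) ** p + np.abs(dy / r[1]) ** p + np.abs(dz / r[2]) ** p
    ) ** (1.0 / p)

    if jitter_mm > 0:
        rho = np.sqrt(dx * dx + dy * dy + dz * dz)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(rho > 0, dx / rho, 0.0)
            uy = np.where(rho > 0, dy / rho, 0.0)
            uz = np.where(rho > 0, dz / rho, 0.0)
        ang = (
            coeffs[0] * ux * uy
            + coeffs[1] * uy * uz
            + coeffs[2] * ux * uz
            + coeffs[3] * (ux * ux - uy * uy)
            + coeffs[4] * (uy * uy - uz * uz)
        )
        # relative boundary perturbation, bounded so organs never collapse
        rel = np.clip(jitter_mm * ang / float(np.mean(r[:2])), -0.25, 0.25)
        s = s * (1.0 + rel)

    return s <= 1.0


def _check_fits(grid: VoxelGrid, name: str, organ: OrganSpec) -> None:
    half_extent = np.asarray(grid.dims) * np.asarray(grid.spacing) / 2.0
    c = np.abs(np.asarray(organ.center_mm))
    r = np.asarray(organ.radii_mm)
    # the z radius of the body is deliberately huge (clipped column)
    if name != "body" and np.any(c + r > half_extent * 1.5):
        raise GeometryError(
            f"organ {name!r} (center {organ.center_mm}, radii {organ.radii_mm}) "
            f"exceeds the grid extent {tuple(2 * half_extent)} mm"
        )


def generate_phantom(spec: PhantomSpec) -> Tuple[VoxelGrid, List[VOI], Prescription]:
    """Generate a synthetic pelvic phantom from a deterministic spec.

    Returns the grid, the five VOIs (body, ptv, boost, rectum, bladder)
    and the prescription. Structural invariants are enforced by
    construction: boost ⊆ PTV ⊆ body, and both OARs are disjoint from
    the PTV; the rectum centroid lies posterior of the PTV centroid and
    the bladder centroid anterior and superior of it.
    """
    grid = VoxelGrid(dims=spec.dims, spacing=spec.spacing)
    for name in ("body", "ptv", "boost", "rectum", "bladder"):
        _check_fits(grid, name, getattr(spec, name))

    rng = np.random.default_rng(spec.seed)
    body = _superellipsoid_mask(grid, spec.body, rng, spec.jitter_mm)
    ptv = _superellipsoid_mask(grid, spec.ptv, rng, spec.jitter_mm)
    boost = _superellipsoid_mask(grid, spec.boost, rng, spec.jitter_mm)
    rectum = _superellipsoid_mask(grid, spec.rectum, rng, spec.jitter_mm)
    bladder = _superellipsoid_mask(grid, spec.bladder, rng, spec.jitter_mm)

    # containment / disjointness invariants, enforced exactly
    ptv &= body
    boost &= ptv
    rectum &= body & ~ptv
    bladder &= body & ~ptv & ~rectum

    vois = [
        VOI("body", "body", body),
        VOI("ptv", "target", ptv),
        VOI("boost", "boost", boost),
        VOI("rectum", "oar", rectum),
        VOI("bladder", "oar", bladder),
    ]
    for v in vois:
        if not v.mask.any():
            raise GeometryError(f"generated VOI {v.name!r} is empty on grid {spec.dims}")

    rx = Prescription(ptv_gy=spec.ptv_gy, boost_gy=spec.boost_gy)
    return grid, vois, rx


def nontumor_mask(body: VOI, ptv: VOI) -> np.ndarray:
    """Non-tumor tissue: the body with the PTV subtracted (body ∧ ¬PTV)."""
    if body.mask.shape != ptv.mask.shape:
        raise ValueError(
            f"mask shapes differ: body {body.mask.shape} vs ptv {ptv.mask.shape}"
        )
    return body.mask & ~ptv.mask


def voi_dict(vois: List[VOI]) -> Dict[str, VOI]:
    return {v.name: v for v in vois}
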