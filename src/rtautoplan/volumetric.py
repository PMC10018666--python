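"""Spatial grids, contour/mask conversion and mask morphology.

All geometry lives in the DICOM patient coordinate system (LPS, millimetres).
Grids are axis-aligned (identity direction cosines) and a voxel is identified
with its center; voxel indices are 0-based and ordered (z, y, x) in the
occupancy arrays so that ``occupancy[k]`` is one axial slice.

The :class:`StructureMask` is the unit of all downstream geometry: derived
structures, beam's-eye-view projections and DVH sampling all operate on
voxelized structures rather than on the original contour polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage
from skimage import measure

__all__ = [
    "SpatialGrid",
    "ContourSet",
    "StructureMask",
    "DoseGrid",
    "rasterize_contours",
    "mask_to_contours",
    "boolean_combine",
    "expand_margin",
    "ring",
    "volume_cc",
    "centroid",
    "GridMismatchError",
]

_GRID_TOL = 1e-6  # mm; two grids closer than this are the same grid


class GridMismatchError(ValueError):
    """Raised when an operation mixes masks or doses on different grids."""


@dataclass(frozen=True)
class SpatialGrid:
    """Axis-aligned voxel grid in patient coordinates.

    Parameters
    ----------
    origin:
        (x, y, z) of the center of voxel (0, 0, 0), in mm (LPS).
    spacing:
        (dx, dy, dz) voxel size in mm; strictly positive.
    dims:
        (nx, ny, nz) voxel counts; each >= 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(int(d) < 1 or int(d) != d for d in self.dims):
            raise ValueError(f"dims must be integers >= 1, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    # -- derived quantities -------------------------------------------------
    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        nx, ny, nz = self.dims
        return (nz, ny, nx)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates along ``axis`` (0=x, 1=y, 2=z)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def z_index(self, z_mm: float) -> int | None:
        """Nearest slice index for a z position, or None beyond one spacing."""
        zc = self.axis_coords(2)
        k = int(np.argmin(np.abs(zc - z_mm)))
        if abs(zc[k] - z_mm) > self.spacing[2] + _GRID_TOL:
            return None
        return k

    def matches(self, other: "SpatialGrid") -> bool:
        return (
            self.dims == other.dims
            and all(abs(a - b) <= _GRID_TOL for a, b in zip(self.origin, other.origin))
            and all(abs(a - b) <= _GRID_TOL for a, b in zip(self.spacing, other.spacing))
        )


@dataclass
class ContourSet:
    """Planar closed polygons per axial slice, as stored in an RT Structure Set.

    ``slices`` maps a z position (mm) to a list of polygons; each polygon is an
    (n, 2) array of (x, y) vertices in mm. Polygons are implicitly closed.
    """

    structure_id: str
    slices: list[tuple[float, list[np.ndarray]]] = field(default_factory=list)
    color: tuple[int, int, int] = (255, 0, 0)

    def validate(self) -> None:
        for z, polys in self.slices:
            for poly in polys:
                arr = np.asarray(poly, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                    raise ValueError(
                        f"structure {self.structure_id!r}, slice z={z}: polygon "
                        f"must have >= 3 (x, y) vertices, got shape {arr.shape}"
                    )

    @property
    def n_polygons(self) -> int:
        return sum(len(p) for _, p in self.slices)


@dataclass
class StructureMask:
    """Voxelized structure: boolean occupancy on a :class:`SpatialGrid`."""

    grid: SpatialGrid
    occupancy: np.ndarray  # bool, shape (nz, ny, nx)
    structure_id: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != self.grid.shape_zyx:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid {self.grid.shape_zyx}"
            )
        self.occupancy = occ

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def copy(self, structure_id: str | None = None) -> "StructureMask":
        return StructureMask(
            self.grid,
            self.occupancy.copy(),
            self.structure_id if structure_id is None else structure_id,
        )


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) per voxel, co-registered with a :class:`SpatialGrid`."""

    grid: SpatialGrid
    values: np.ndarray  # float Gy, shape (nz, ny, nx)
    scaling_note: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape_zyx:
            raise ValueError(
                f"dose shape {vals.shape} does not match grid {self.grid.shape_zyx}"
            )
        if not np.isfinite(vals).all():
            raise ValueError("dose values must be finite")
        if (vals < 0).any():
            raise ValueError("dose values must be non-negative")
        self.values = vals


# ---------------------------------------------------------------------------
# contour <-> mask
# ---------------------------------------------------------------------------

def rasterize_contours(contours: ContourSet, grid: SpatialGrid) -> StructureMask:
    """Voxelize planar contours on ``grid`` with the voxel-center even-odd rule.

    A voxel is occupied iff its center lies inside an odd number of that
    slice's polygons, so inner polygons behave as holes. An empty contour set
    yields an empty mask.
    """
    contours.validate()
    occ = np.zeros(grid.shape_zyx, dtype=bool)
    if not contours.slices:
        return StructureMask(grid, occ, contours.structure_id)

    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    xx, yy = np.meshgrid(xs, ys)  # shape (ny, nx)
    pts = np.column_stack([xx.ravel(), yy.ravel()])

    for z, polys in contours.slices:
        k = grid.z_index(z)
        if k is None:
            raise ValueError(
                f"structure {contours.structure_id!r}: contour at z={z} mm lies "
                "outside the grid extent (plus one slice spacing)"
            )
        plane = np.zeros(pts.shape[0], dtype=bool)
        for poly in polys:
            arr = np.asarray(poly, dtype=float)
            path = _MplPath(arr)  # implicitly closed by contains_points
            # DICOM contours are simple polygons, so the winding test equals
            # the even-odd test per polygon; XOR across polygons gives the
            # even-odd rule for the whole slice (holes supported).
            plane ^= path.contains_points(pts)
        occ[k] |= plane.reshape(grid.dims[1], grid.dims[0])
    return StructureMask(grid, occ, contours.structure_id)


def mask_to_contours(mask: StructureMask) -> ContourSet:
    """Trace axial iso-contours of a mask (marching squares at the 0.5 level).

    Re-rasterizing the result on the same grid reproduces the occupancy for
    voxels whose centers are farther than half a voxel from the traced curve.
    """
    grid = mask.grid
    out = ContourSet(structure_id=mask.structure_id, slices=[])
    if mask.is_empty:
        return out
    ox, oy, _ = grid.origin
    dx, dy, _ = grid.spacing
    zs = grid.axis_coords(2)
    for k in range(grid.dims[2]):
        plane = mask.occupancy[k]
        if not plane.any():
            continue
        padded = np.pad(plane.astype(float), 1)
        polys: list[np.ndarray] = []
        for loop in measure.find_contours(padded, 0.5):
            # find_contours yields (row, col) = (y, x) in padded index space
            y_idx = loop[:, 0] - 1.0
            x_idx = loop[:, 1] - 1.0
            verts = np.column_stack([ox + dx * x_idx, oy + dy * y_idx])
            if np.allclose(verts[0], verts[-1]):
                verts = verts[:-1]
            if verts.shape[0] >= 3:
                polys.append(verts)
        if polys:
            out.slices.append((float(zs[k]), polys))
    return out


# ---------------------------------------------------------------------------
# boolean and morphological operations
# ---------------------------------------------------------------------------

_BOOLEAN_OPS = ("union", "intersection", "subtraction", "xor")


def _require_shared_grid(masks: list[StructureMask]) -> SpatialGrid:
    grid = masks[0].grid
    for m in masks[1:]:
        if not grid.matches(m.grid):
            raise GridMismatchError(
                f"masks {masks[0].structure_id!r} and {m.structure_id!r} are on "
                "different grids; resample explicitly before combining"
            )
    return grid


def boolean_combine(
    operands: list[StructureMask], op: str, structure_id: str = ""
) -> StructureMask:
    """Per-voxel boolean combination of masks sharing one grid.

    ``subtraction`` is the first operand minus the union of the rest.
    """
    if not operands:
        raise ValueError("boolean_combine requires at least one operand")
    if op not in _BOOLEAN_OPS:
        raise ValueError(f"unknown boolean op {op!r}; expected one of {_BOOLEAN_OPS}")
    grid = _require_shared_grid(operands)
    arrays = [m.occupancy for m in operands]
    if op == "union":
        out = np.logical_or.reduce(arrays)
    elif op == "intersection":
        out = np.logical_and.reduce(arrays)
    elif op == "xor":
        out = np.logical_xor.reduce(arrays)
    else:  # subtraction
        rest = np.logical_or.reduce(arrays[1:]) if len(arrays) > 1 else np.zeros_like(arrays[0])
        out = arrays[0] & ~rest
    return StructureMask(grid, out.copy(), structure_id)


def expand_margin(mask: StructureMask, distance_mm: float, structure_id: str = "") -> StructureMask:
    """Isotropic margin in physical millimetres via Euclidean distance transform.

    Positive distances dilate: a voxel becomes occupied iff its center lies
    within ``distance_mm`` (center-to-center Euclidean distance, respecting
    anisotropic spacing) of an occupied voxel center. Negative distances erode
    under the same metric (complement of dilating the complement); zero is the
    identity.
    """
    if abs(distance_mm) > 50:
        raise ValueError(f"|margin| must be <= 50 mm, got {distance_mm}")
    sid = structure_id or mask.structure_id
    if distance_mm == 0 or mask.is_empty:
        return StructureMask(mask.grid, mask.occupancy.copy(), sid)
    sz, sy, sx = mask.grid.spacing[2], mask.grid.spacing[1], mask.grid.spacing[0]
    sampling = (sz, sy, sx)  # arrays are (z, y, x)
    if distance_mm > 0:
        dist = ndimage.distance_transform_edt(~mask.occupancy, sampling=sampling)
        out = dist <= distance_mm + _GRID_TOL
    else:
        dist = ndimage.distance_transform_edt(mask.occupancy, sampling=sampling)
        out = dist > abs(distance_mm) + _GRID_TOL
    return StructureMask(mask.grid, out, sid)


def ring(
    mask: StructureMask, inner_mm: float, outer_mm: float, structure_id: str = ""
) -> StructureMask:
    """Band of voxels between the ``inner_mm`` and ``outer_mm`` expansions.

    The source structure itself is excluded whenever ``inner_mm >= 0``: the
    ring is strictly outside the inner expansion (which contains the source).
    """
    if inner_mm < 0:
        raise ValueError(f"inner_mm must be >= 0, got {inner_mm}")
    if outer_mm <= inner_mm:
        raise ValueError(f"outer_mm ({outer_mm}) must exceed inner_mm ({inner_mm})")
    outer = expand_margin(mask, outer_mm)
    inner = expand_margin(mask, inner_mm)
    return boolean_combine([outer, inner], "subtraction", structure_id or f"{mask.structure_id}_ring")


def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cm^3 (occupied voxels x voxel volume)."""
    return mask.n_occupied * mask.grid.voxel_volume_mm3 / 1000.0


def centroid(mask: StructureMask) -> tuple[float, float, float]:
    """Unweighted mean of occupied voxel centers, in patient mm."""
    if mask.is_empty:
        raise ValueError(f"centroid of empty mask {mask.structure_id!r} is undefined")
    zi, yi, xi = np.nonzero(mask.occupancy)
    g = mask.grid
    return (
        float(g.origin[0] + g.spacing[0] * xi.mean()),
        float(g.origin[1] + g.spacing[1] * yi.mean()),
        float(g.origin[2] + g.spacing[2] * zi.mean()),
    )


def bounding_box_mm(mask: StructureMask) -> tuple[np.ndarray, np.ndarray]:
    """(min_corner, max_corner) of occupied voxel centers, in mm (x, y, z)."""
    if mask.is_empty:
        raise ValueError(f"bounding box of empty mask {mask.structure_id!r} is undefined")
    zi, yi, xi = np.nonzero(mask.occupancy)
    g = mask.grid
    lo = np.array(
        [
            g.origin[0] + g.spacing[0] * xi.min(),
            g.origin[1] + g.spacing[1] * yi.min(),
            g.origin[2] + g.spacing[2] * zi.min(),
        ]
    )
    hi = np.array(
        [
            g.origin[0] + g.spacing[0] * xi.max(),
            g.origin[1] + g.spacing[1] * yi.max(),
            g.origin[2] + g.spacing[2] * zi.max(),
        ]
    )
    return lo, hi
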