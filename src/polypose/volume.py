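"""Volumes, labelmaps, NIfTI I/O, trilinear sampling, and warping.

Conventions
-----------
* World coordinates are millimetres; voxel indices are 0-based; a voxel's
  world position is its **center**.
* Volumes store linear attenuation coefficients (1/mm); sampling outside the
  volume returns 0 (air), so anatomy leaving the field of view attenuates
  nothing.
* Orientation is carried entirely by the 4x4 voxel-to-world affine.  The
  constructors build axis-aligned affines from (spacing, origin); arbitrary
  affines read from NIfTI headers are honoured as long as they are invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "Labelmap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "sample_trilinear",
    "sample_trilinear_grad",
    "sample_nearest",
    "warp_volume",
    "warp_labelmap",
    "erode_labelmap",
]


def _affine_from_spacing_origin(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


@dataclass
class Grid:
    """Shared lattice geometry: shape + voxel-to-world affine."""

    shape: tuple
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3].copy()

    @property
    def world_to_voxel(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``shape + (3,)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.moveaxis(idx, 0, -1)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def bounds(self) -> tuple:
        """Axis-aligned world bounding box spanned by voxel centers (min, max)."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        world = corners @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world.min(axis=0), world.max(axis=0)

    def same_lattice(self, other: "Grid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)


@dataclass
class Volume:
    """3D grid of linear attenuation coefficients (1/mm) with world geometry."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @classmethod
    def from_spacing(cls, values, spacing, origin=(0.0, 0.0, 0.0)) -> "Volume":
        return cls(values, _affine_from_spacing_origin(np.asarray(spacing, float), origin))

    @property
    def grid(self) -> Grid:
        return Grid(self.values.shape, self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.grid.origin

    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class Labelmap:
    """Integer grid of disjoint rigid structures (ids 1..K; background 0)."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labelmap must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labelmap must be integer-valued")
        self.affine = np.asarray(self.affine, dtype=float)

    @classmethod
    def from_spacing(cls, labels, spacing, origin=(0.0, 0.0, 0.0)) -> "Labelmap":
        return cls(labels, _affine_from_spacing_origin(np.asarray(spacing, float), origin))

    @property
    def grid(self) -> Grid:
        return Grid(self.labels.shape, self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing

    def structure_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, structure_id: int) -> np.ndarray:
        return self.labels == structure_id


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D scalar image, got {data.ndim}D: {path}")
    return Volume(np.asarray(data, dtype=float), np.asarray(img.affine, dtype=float))


def write_volume(volume: Volume, path) -> None:
    nib.save(nib.Nifti1Image(volume.values.astype(np.float64), volume.affine), str(path))


def read_labelmap(path) -> Labelmap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D labelmap, got {data.ndim}D: {path}")
    return Labelmap(np.rint(data).astype(np.int32), np.asarray(img.affine, dtype=float))


def write_labelmap(lm: Labelmap, path) -> None:
    nib.save(nib.Nifti1Image(lm.labels.astype(np.int16), lm.affine), str(path))


# ---------------------------------------------------------------------------
# Sampling

def _world_to_voxel_coords(grid: Grid, points: np.ndarray) -> np.ndarray:
    inv = grid.world_to_voxel
    return points @ inv[:3, :3].T + inv[:3, 3]


def _trilinear_corners(values: np.ndarray, coords: np.ndarray):
    """Corner values and fractional offsets for trilinear interpolation.

    Out-of-range corners contribute value 0 (zero padding).
    Returns (c, f) with c shaped ``(..., 2, 2, 2)`` and f ``(..., 3)``.
    """
    shape = np.array(values.shape)
    i0 = np.floor(coords).astype(np.int64)
    f = (coords - i0).astype(values.dtype, copy=False)
    c = np.empty(coords.shape[:-1] + (2, 2, 2), dtype=values.dtype)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = i0 + np.array([dx, dy, dz])
                valid = np.all((idx >= 0) & (idx < shape), axis=-1)
                clipped = np.clip(idx, 0, shape - 1)
                vals = values[clipped[..., 0], clipped[..., 1], clipped[..., 2]]
                c[..., dx, dy, dz] = np.where(valid, vals, 0.0)
    return c, f


def sample_trilinear(volume: Volume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the volume at world points (mm).

    Points outside the volume (beyond the outermost voxel centers, with the
    surrounding half-voxel interpolation shell) evaluate to 0.
    """
    points = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(points)):
        raise ValueError("sample points must be finite")
    coords = _world_to_voxel_coords(volume.grid, points)
    c, f = _trilinear_corners(volume.values, coords)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    c00 = c[..., 0, 0, 0] * (1 - fx) + c[..., 1, 0, 0] * fx
    c10 = c[..., 0, 1, 0] * (1 - fx) + c[..., 1, 1, 0] * fx
    c01 = c[..., 0, 0, 1] * (1 - fx) + c[..., 1, 0, 1] * fx
    c11 = c[..., 0, 1, 1] * (1 - fx) + c[..., 1, 1, 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


def sample_trilinear_grad(volume: Volume, points: np.ndarray):
    """Trilinear value and its exact spatial gradient in world units (1/mm per mm).

    The gradient is the derivative of the piecewise-trilinear interpolant with
    respect to the world coordinates of the query point (chained through the
    affine); it is piecewise-smooth with jumps at cell faces.
    """
    points = np.asarray(points, dtype=float)
    coords = _world_to_voxel_coords(volume.grid, points)
    c, f = _trilinear_corners(volume.values, coords)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    c000, c100 = c[..., 0, 0, 0], c[..., 1, 0, 0]
    c010, c110 = c[..., 0, 1, 0], c[..., 1, 1, 0]
    c001, c101 = c[..., 0, 0, 1], c[..., 1, 0, 1]
    c011, c111 = c[..., 0, 1, 1], c[..., 1, 1, 1]
    gx_, gy_, gz_ = 1 - fx, 1 - fy, 1 - fz

    m00 = c000 * gx_ + c100 * fx
    m10 = c010 * gx_ + c110 * fx
    m01 = c001 * gx_ + c101 * fx
    m11 = c011 * gx_ + c111 * fx
    n0 = m00 * gy_ + m10 * fy
    n1 = m01 * gy_ + m11 * fy
    val = n0 * gz_ + n1 * fz

    a00, a10 = c100 - c000, c110 - c010
    a01, a11 = c101 - c001, c111 - c011
    gx = (a00 * gy_ + a10 * fy) * gz_ + (a01 * gy_ + a11 * fy) * fz
    gy = (m10 - m00) * gz_ + (m11 - m01) * fz
    gz = n1 - n0
    grad_voxel = np.stack([gx, gy, gz], axis=-1)
    inv = volume.grid.world_to_voxel
    grad_world = grad_voxel @ inv[:3, :3]  # d(voxel)/d(world) chain rule
    return val, grad_world


def sample_nearest(labels: np.ndarray, grid: Grid, points: np.ndarray, fill=0) -> np.ndarray:
    """Nearest-neighbour sampling (for labelmaps) at world points."""
    points = np.asarray(points, dtype=float)
    coords = _world_to_voxel_coords(grid, points)
    idx = np.rint(coords).astype(np.int64)
    shape = np.array(labels.shape)
    valid = np.all((idx >= 0) & (idx < shape), axis=-1)
    clipped = np.clip(idx, 0, shape - 1)
    out = labels[clipped[..., 0], clipped[..., 1], clipped[..., 2]]
    return np.where(valid, out, fill)


# ---------------------------------------------------------------------------
# Warping


def _mapped_coords(grid: Grid, deformation) -> np.ndarray:
    """Resolve a deformation into mapped world coordinates on the grid.

    Accepts an object exposing ``mapped_coords(grid)`` (e.g. a polyrigid
    field), or an ndarray of per-voxel displacements with shape
    ``grid.shape + (3,)`` (mm, output-to-input convention).
    """
    if hasattr(deformation, "mapped_coords"):
        return deformation.mapped_coords(grid)
    disp = np.asarray(deformation, dtype=float)
    if disp.shape != grid.shape + (3,):
        raise ValueError(
            f"deformation lattice mismatch: expected {grid.shape + (3,)}, got {disp.shape}"
        )
    return grid.voxel_centers() + disp


def warp_volume(volume: Volume, deformation) -> Volume:
    """Resample ``volume`` through a deformation: output(x) = V(Phi(x)).

    ``Phi`` maps output-lattice coordinates into the input volume's world
    coordinates, so an identity field reproduces the volume exactly at voxel
    centers.
    """
    mapped = _mapped_coords(volume.grid, deformation)
    warped = sample_trilinear(volume, mapped)
    return Volume(warped, volume.affine.copy())


def warp_labelmap(lm: Labelmap, deformation) -> Labelmap:
    """Nearest-neighbour warp of a labelmap through the same convention."""
    mapped = _mapped_coords(lm.grid, deformation)
    warped = sample_nearest(lm.labels, lm.grid, mapped, fill=0)
    return Labelmap(warped.astype(lm.labels.dtype), lm.affine.copy())


# ---------------------------------------------------------------------------
# Morphology


def erode_labelmap(lm: Labelmap, radius_mm: float) -> Labelmap:
    """Erode every structure by a ball of physical radius ``radius_mm``.

    A voxel survives iff its Euclidean distance (in mm, anisotropy-aware) to
    the structure's complement exceeds the radius; radius 0 is the identity.
    Structures erased entirely are logged.
    """
    if radius_mm < 0:
        raise ValueError("erosion radius must be non-negative")
    out = np.zeros_like(lm.labels)
    spacing = lm.spacing
    for sid in lm.structure_ids():
        mask = lm.mask(sid)
        if radius_mm == 0:
            out[mask] = sid
            continue
        dist_in = ndimage.distance_transform_edt(mask, sampling=spacing)
        kept = dist_in > radius_mm
        if not kept.any():
            logger.warning("structure %d vanished after erosion by %.2f mm", sid, radius_mm)
        out[kept] = sid
    return Labelmap(out, lm.affine.copy())
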