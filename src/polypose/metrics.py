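"""Deformation-quality and overlap metrics.

Dice and HD95 quantify mask agreement (in 2D or 3D); Jacobian statistics
quantify the regularity of a deformation: ``percent_folds`` is the fraction of
interior voxels where the mapping's Jacobian determinant is non-positive
(local self-intersection), and ``sigma_log_jac`` the standard deviation of
``log |det J|`` over non-folded voxels (spread of local volume change; 0 for
any rigid motion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .camera import Camera
from .renderer import RenderConfig, render_drr
from .volume import Grid, Labelmap, Volume

__all__ = ["JacobianReport", "dice", "hd95", "jacobian_stats", "project_mask"]


@dataclass
class JacobianReport:
    percent_folds: float  # % of interior voxels with det J <= 0
    sigma_log_jac: float  # std of log|det J| over voxels with det J > 0

    def __post_init__(self):
        assert 0.0 <= self.percent_folds <= 100.0
        assert self.sigma_log_jac >= 0.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks score 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask lattices differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def hd95(a: np.ndarray, b: np.ndarray, spacing=None) -> float:
    """95th-percentile symmetric Hausdorff distance between mask boundaries (mm).

    Directed nearest-boundary distances from both masks are pooled before
    taking the (linearly interpolated) percentile.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask lattices differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("hd95 requires both masks to be non-empty")
    spacing = np.ones(a.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    pa = np.argwhere(_boundary(a)) * spacing
    pb = np.argwhere(_boundary(b)) * spacing
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def _mapped_grid(field, grid: Grid | None) -> tuple:
    """Resolve a deformation argument into (mapping grid+3, Grid)."""
    if hasattr(field, "mapped_coords"):
        return field.mapped_coords(), field.grid
    arr = np.asarray(field, dtype=float)
    if grid is None:
        raise ValueError("a Grid is required when passing a raw displacement array")
    if arr.shape != grid.shape + (3,):
        raise ValueError(f"field lattice mismatch: expected {grid.shape + (3,)}, got {arr.shape}")
    return grid.voxel_centers() + arr, grid


def jacobian_stats(field, grid: Grid | None = None) -> JacobianReport:
    """Jacobian statistics of a deformation via central finite differences.

    ``field`` is a polyrigid field or a dense displacement array (mm) with its
    ``Grid``.  The Jacobian of the world-coordinate mapping Phi is evaluated
    at interior voxels only (central differences need both neighbours).
    """
    mapped, g = _mapped_grid(field, grid)
    if min(g.shape) < 3:
        raise ValueError("jacobian_stats needs at least 3 voxels per axis")
    sp = g.spacing
    J = np.empty(mapped.shape[:-1] + (3, 3))
    for comp in range(3):
        for ax in range(3):
            J[..., comp, ax] = np.gradient(mapped[..., comp], sp[ax], axis=ax)
    interior = J[1:-1, 1:-1, 1:-1]
    det = np.linalg.det(interior)
    folds = det <= 0
    percent_folds = 100.0 * float(folds.mean())
    pos = det[~folds]
    sigma = float(np.std(np.log(pos))) if pos.size else 0.0
    return JacobianReport(percent_folds=percent_folds, sigma_log_jac=sigma)


def project_mask(
    lm: Labelmap,
    structure_id: int,
    cam: Camera,
    config: RenderConfig | None = None,
    threshold_mm: float | None = None,
) -> np.ndarray:
    """Binary 2D silhouette of a structure: ray thickness above half a voxel.

    The structure mask is rendered as a unit-attenuation volume, giving a map
    of chord length (mm) through the structure per pixel; pixels above the
    threshold (default half the smallest voxel spacing) form the silhouette.
    """
    ids = set(int(i) for i in np.unique(lm.labels))
    if int(structure_id) not in ids:
        raise ValueError(f"structure id {structure_id} not present in labelmap")
    mask = (lm.labels == structure_id).astype(float)
    thickness = render_drr(Volume(mask, lm.affine.copy()), cam, config)
    if threshold_mm is None:
        threshold_mm = 0.5 * float(lm.spacing.min())
    return thickness > threshold_mm
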