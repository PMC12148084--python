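"""Differentiable Beer-Lambert rendering of digitally reconstructed radiographs.

Each detector pixel back-projects to a ray ``r(l) = S + l (P - S)``, ``l in
[0, 1]``, from the source ``S`` to the detector point ``P``.  The pixel's
negative log-intensity is the line integral of the attenuation volume along
the ray, approximated by midpoint quadrature over trilinear samples:

    I(p) = ||P - S|| * sum_m V[r(l_m)] * dl

Rendering is linear in the (possibly warped) volume values, so for a fixed
camera the whole projection is a sparse linear operator.  :class:`Projector`
precomputes its trilinear stencil once and exposes both the forward map
(values -> image) and its exact adjoint (image gradient -> per-voxel values
gradient), which is the backbone of gradient-based registration here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .camera import Camera, pixel_to_world, source_position
from .volume import Grid, Labelmap, Volume

__all__ = ["RenderConfig", "Projector", "render_drr", "render_structure"]


@dataclass
class RenderConfig:
    """Quadrature policy for ray integrals.

    Exactly one sampling policy applies: a fixed number of samples per ray
    (``n_samples``) or a target physical step length in mm (``step_mm``).
    With neither set, the step defaults to half the smallest voxel spacing.
    With ``clip_to_volume`` (default), rays are first intersected with the
    support box of the trilinear interpolant so all samples count.
    """

    n_samples: Optional[int] = None
    step_mm: Optional[float] = None
    clip_to_volume: bool = True

    def __post_init__(self):
        if self.n_samples is not None and self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


def _support_box(grid: Grid):
    """AABB of the trilinear interpolant's support (voxel centers +/- one spacing)."""
    lo, hi = grid.bounds()
    return lo - grid.spacing, hi + grid.spacing


def _clip_to_box(S, D, lo, hi):
    """Slab-method ray/AABB intersection; returns (l0, l1) clipped to [0, 1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - S) / D
        t2 = (hi - S) / D
    tmin = np.where(np.isnan(t1), -np.inf, np.minimum(t1, t2)).max(axis=-1)
    tmax = np.where(np.isnan(t2), np.inf, np.maximum(t1, t2)).min(axis=-1)
    l0 = np.clip(tmin, 0.0, 1.0)
    l1 = np.clip(tmax, 0.0, 1.0)
    return l0, np.maximum(l0, l1)


class Projector:
    """Precomputed sparse projection operator for one (volume lattice, camera) pair.

    The stencil depends only on geometry, never on the voxel values, so one
    instance is reused across all iterations of a registration loop.
    """

    def __init__(self, grid: Grid, camera: Camera, config: RenderConfig | None = None):
        config = config or RenderConfig()
        self.grid = grid
        self.camera = camera
        self.config = config

        S = source_position(camera)
        P = pixel_to_world(camera, camera.pixel_grid())  # (rows, cols, 3)
        D = P - S
        ray_len = np.linalg.norm(D, axis=-1)  # ||P - S|| per pixel

        lo, hi = _support_box(grid)
        if np.all(S >= lo) and np.all(S <= hi):
            raise ValueError("X-ray source lies inside the volume: chord undefined")
        if config.clip_to_volume:
            l0, l1 = _clip_to_box(S, D, lo, hi)
        else:
            l0 = np.zeros_like(ray_len)
            l1 = np.ones_like(ray_len)

        chord = (l1 - l0) * ray_len
        if config.n_samples is not None:
            M = config.n_samples
        else:
            step = config.step_mm if config.step_mm is not None else 0.5 * float(grid.spacing.min())
            M = max(2, int(np.ceil(chord.max() / step)))
        self.n_samples = M

        dl = (l1 - l0) / M
        m = (np.arange(M) + 0.5)[:, None, None]
        lam = l0[None] + m * dl[None]  # (M, rows, cols)
        pts = S + lam[..., None] * D[None]  # (M, rows, cols, 3)

        # per-sample integration weight: ||P-S|| * dl
        self._sample_w = (ray_len * dl)[None].repeat(M, axis=0).reshape(M, -1)

        # precompute the trilinear stencil in flat voxel indices
        inv = grid.world_to_voxel
        coords = pts.reshape(-1, 3) @ inv[:3, :3].T + inv[:3, 3]
        shape = np.array(grid.shape)
        i0 = np.floor(coords).astype(np.int64)
        f = coords - i0
        n = coords.shape[0]
        idx = np.empty((n, 8), dtype=np.int64)
        w = np.empty((n, 8), dtype=float)
        corner = 0
        strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1 - f[:, 2]
                    c = i0 + np.array([dx, dy, dz])
                    valid = np.all((c >= 0) & (c < shape), axis=1)
                    cc = np.clip(c, 0, shape - 1)
                    idx[:, corner] = cc @ strides
                    w[:, corner] = np.where(valid, wx * wy * wz, 0.0)
                    corner += 1
        self._idx = idx
        self._w = w * self._sample_w.reshape(-1, 1)
        self._n_voxels = int(np.prod(grid.shape))

    @property
    def image_shape(self):
        return self.camera.detector_shape

    def forward(self, values: np.ndarray) -> np.ndarray:
        """Render an image from voxel values on the projector's lattice."""
        if values.shape != self.grid.shape:
            raise ValueError(f"lattice mismatch: expected {self.grid.shape}, got {values.shape}")
        flat = values.reshape(-1)
        contrib = (flat[self._idx] * self._w).sum(axis=1)
        img = contrib.reshape(self.n_samples, -1).sum(axis=0)
        return img.reshape(self.image_shape)

    def adjoint(self, image_grad: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`forward`: image-space gradient -> voxel gradient."""
        g = np.asarray(image_grad, dtype=float).reshape(-1)
        per_sample = np.tile(g, self.n_samples)
        vals = (per_sample[:, None] * self._w).ravel()
        out = np.bincount(self._idx.ravel(), weights=vals, minlength=self._n_voxels)
        return out.reshape(self.grid.shape)


def render_drr(volume: Volume, camera: Camera, config: RenderConfig | None = None) -> np.ndarray:
    """Render one digitally reconstructed radiograph (negative log-intensity).

    Non-negative for non-negative volumes and linear in the attenuation values.
    """
    proj = Projector(volume.grid, camera, config)
    return proj.forward(volume.values)


def render_structure(
    volume: Volume,
    labelmap: Labelmap,
    ids,
    camera: Camera,
    config: RenderConfig | None = None,
) -> np.ndarray:
    """Render the volume with voxels outside the selected structures zeroed."""
    ids = [int(i) for i in np.atleast_1d(ids)]
    present = set(int(i) for i in np.unique(labelmap.labels))
    for i in ids:
        if i not in present:
            raise ValueError(f"structure id {i} not present in labelmap")
    if not volume.grid.same_lattice(labelmap.grid):
        raise ValueError("volume and labelmap lattices differ")
    mask = np.isin(labelmap.labels, ids)
    masked = Volume(np.where(mask, volume.values, 0.0), volume.affine.copy())
    return render_drr(masked, camera, config)
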