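"""Synthetic phantoms and ground-truth registration cases.

The phantom is a soft-tissue ellipsoid ("body") containing K disjoint
ellipsoidal "bones" of configurable — typically unequal — volumes, stored as
linear attenuation coefficients (defaults near water, 0.02/mm, and cortical
bone, 0.06/mm).  A ground-truth case additionally samples per-bone rigid
motions, fuses them into a polyrigid deformation with the same weight field
the registration will use (so the optimum is attainable and parameter
recovery is a sharp test), places cameras equiangularly over a configurable
arc, and renders the fixed X-ray images from the warped volume.

Two acquisition regimes are covered by ``n_views`` / ``angular_span_deg``:
sparse-view (few views over a 180 degree orbit) and limited-angle (2 views
roughly 30 degrees apart).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .camera import Camera, orbit_camera
from .polyrigid import PolyrigidField, build_field, build_structure_set, build_weights
from .renderer import RenderConfig, render_drr
from .volume import Labelmap, Volume, warp_labelmap, warp_volume

__all__ = ["Ellipsoid", "PhantomConfig", "GroundTruthCase", "generate_phantom", "generate_case"]


@dataclass
class Ellipsoid:
    center_mm: tuple  # relative to the volume center
    radii_mm: tuple

    def analytic_volume(self) -> float:
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * np.pi * a * b * c


def default_bones():
    """Two bones of unequal volume, well separated in the body.

    Both ellipsoids are deliberately anisotropic (long axes differ from the
    short ones) so that their rotations are observable in projections —
    near-spherical structures would make rotational pose unidentifiable.
    """
    return [
        Ellipsoid(center_mm=(-13.0, 0.0, 0.0), radii_mm=(12.0, 7.0, 6.0)),
        Ellipsoid(center_mm=(14.0, 2.0, 2.0), radii_mm=(9.0, 4.5, 4.0)),
    ]


@dataclass
class PhantomConfig:
    grid_shape: tuple = (64, 64, 64)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    bones: Sequence[Ellipsoid] = dataclass_field(default_factory=default_bones)
    body_radii_frac: float = 0.45  # body ellipsoid radii as a fraction of the extent
    lac_soft: float = 0.02  # 1/mm, near water
    lac_bone: float = 0.06  # 1/mm, cortical-bone-like
    smooth_sigma_vox: float = 0.5  # partial-volume softening of the LAC image
    texture_amplitude: float = 0.3  # relative soft-tissue heterogeneity
    texture_sigma_vox: float = 3.0  # correlation length of the texture
    seed: int = 0

    def __post_init__(self):
        if self.lac_bone <= self.lac_soft or self.lac_soft <= 0:
            raise ValueError("need lac_bone > lac_soft > 0")


def _ellipsoid_mask(grid_centers: np.ndarray, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    rel = (grid_centers - center) / radii
    return (rel**2).sum(axis=-1) <= 1.0


def generate_phantom(cfg: PhantomConfig) -> tuple:
    """Deterministically build (Volume, Labelmap) from the configuration."""
    shape = tuple(cfg.grid_shape)
    spacing = np.asarray(cfg.spacing_mm, dtype=float)
    origin = -(np.array(shape) - 1) / 2.0 * spacing  # center the volume at the world origin
    vol = Volume.from_spacing(np.zeros(shape), spacing, origin)
    centers = vol.grid.voxel_centers()

    extent = np.array(shape) * spacing
    body = _ellipsoid_mask(centers, np.zeros(3), cfg.body_radii_frac * extent)
    values = np.where(body, cfg.lac_soft, 0.0)

    if cfg.texture_amplitude > 0:
        # smooth random soft-tissue heterogeneity: breaks the rotational
        # near-symmetry of pure ellipsoids, which real anatomy never has
        rng = np.random.default_rng(cfg.seed)
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), cfg.texture_sigma_vox)
        noise /= max(noise.std(), 1e-12)
        modulation = np.clip(1.0 + cfg.texture_amplitude * noise, 0.2, None)
        values = np.where(body, cfg.lac_soft * modulation, 0.0)

    labels = np.zeros(shape, dtype=np.int32)
    for k, bone in enumerate(cfg.bones, start=1):
        mask = _ellipsoid_mask(centers, np.asarray(bone.center_mm, float), np.asarray(bone.radii_mm, float))
        if not mask.any():
            raise ValueError(f"bone {k} produced an empty mask")
        if (labels[mask] != 0).any():
            raise ValueError(f"bone {k} overlaps another bone")
        if not body[mask].all():
            raise ValueError(f"bone {k} extends outside the soft-tissue body")
        labels[mask] = k
        values[mask] = cfg.lac_bone

    if cfg.smooth_sigma_vox > 0:
        values = ndimage.gaussian_filter(values, cfg.smooth_sigma_vox)
    return Volume(values, vol.affine), Labelmap(labels, vol.affine.copy())


@dataclass
class GroundTruthCase:
    volume: Volume  # moving volume
    labelmap: Labelmap
    gt_twists: np.ndarray  # (K, 6)
    gt_field: PolyrigidField
    cameras: list  # N cameras with ground-truth extrinsics
    images: list  # N fixed images rendered from the warped volume
    warped_volume: Volume
    warped_labelmap: Labelmap
    weights_mode: str
    epsilon: Optional[float]
    render_config: RenderConfig


def _sample_twists(rng, n, max_rot_rad, max_trans_mm):
    """Uniform random magnitude along a uniform random direction, per bone."""
    twists = np.zeros((n, 6))
    for i in range(n):
        if max_rot_rad > 0:
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            twists[i, :3] = ax * rng.uniform(0.0, max_rot_rad)
        if max_trans_mm > 0:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            twists[i, 3:] = d * rng.uniform(0.0, max_trans_mm)
    return twists


def generate_case(
    cfg: PhantomConfig,
    max_rotation_deg: float = 10.0,
    max_translation_mm: float = 10.0,
    n_views: int = 2,
    angular_span_deg: float = 30.0,
    weights_mode: str = "mass",
    epsilon: Optional[float] = None,
    detector_shape=(64, 64),
    pixel_spacing=(2.5, 2.5),
    source_to_iso: float = 500.0,
    source_to_detector: float = 1000.0,
    render_config: RenderConfig | None = None,
) -> GroundTruthCase:
    """Build a complete ground-truth registration case (seeded by cfg.seed)."""
    volume, labelmap = generate_phantom(cfg)
    ss = build_structure_set(labelmap)
    wf = build_weights(ss, weights_mode, epsilon)

    # Rejection-sample the motion: anatomy cannot interpenetrate, so draws
    # whose fused field folds (bones on colliding paths) are redrawn, as are
    # draws that push a bone out of the field of view.
    rng = np.random.default_rng(cfg.seed)
    from .metrics import jacobian_stats

    # feasibility of the bounds themselves: worst-case bone displacement must
    # not reach the volume boundary
    lo, hi = volume.grid.bounds()
    for k, bone in enumerate(cfg.bones, start=1):
        center = np.asarray(bone.center_mm, float)
        r = float(max(bone.radii_mm))
        worst = max_translation_mm + np.deg2rad(max_rotation_deg) * r
        margin = float(min((center - lo).min(), (hi - center).min()))
        if worst >= margin:
            raise ValueError(
                f"motion bounds can push bone {k} out of the field of view "
                f"(worst-case displacement {worst:.1f} mm >= boundary margin {margin:.1f} mm)"
            )

    for _attempt in range(50):
        gt_twists = _sample_twists(rng, len(cfg.bones), np.deg2rad(max_rotation_deg), max_translation_mm)
        gt_field = build_field(wf, gt_twists)
        if jacobian_stats(gt_field).percent_folds == 0:
            break
    else:
        raise ValueError("could not sample a fold-free motion within 50 draws; reduce the bounds")
    warped_labels = warp_labelmap(labelmap, gt_field)
    for k in range(1, len(cfg.bones) + 1):
        n0 = int((labelmap.labels == k).sum())
        n1 = int((warped_labels.labels == k).sum())
        if n1 < 0.5 * n0:
            raise ValueError(
                f"motion pushes bone {k} out of the field of view "
                f"({n1}/{n0} voxels remain); reduce the motion bounds"
            )
    warped = warp_volume(volume, gt_field)

    if n_views < 1:
        raise ValueError("need at least one view")
    angles = [0.0] if n_views == 1 else np.linspace(-angular_span_deg / 2, angular_span_deg / 2, n_views)
    cameras = [
        orbit_camera(
            (0.0, 0.0, 0.0), a, source_to_iso, source_to_detector, detector_shape, pixel_spacing
        )
        for a in np.atleast_1d(angles)
    ]
    render_config = render_config or RenderConfig()
    images = [render_drr(warped, cam, render_config) for cam in cameras]
    return GroundTruthCase(
        volume=volume,
        labelmap=labelmap,
        gt_twists=gt_twists,
        gt_field=gt_field,
        cameras=cameras,
        images=images,
        warped_volume=warped,
        warped_labelmap=warped_labels,
        weights_mode=weights_mode,
        epsilon=epsilon,
        render_config=render_config,
    )
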