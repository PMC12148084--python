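"""Dense per-voxel translation-field comparator.

Optimizes an independent 3-vector displacement for every voxel through the
same renderer and similarity objective as the polyrigid model, optionally
with a squared forward-difference (diffusion) smoothness penalty.  With three
parameters per voxel and only a handful of views the problem is severely
under-determined: the field can reproduce the training views while bearing
little resemblance to the true motion — which is exactly the behaviour this
comparator exists to demonstrate against the polyrigid parameterization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .camera import Camera
from .registration import AdamAscent, OptimConfig
from .renderer import Projector, RenderConfig
from .similarity import SimilarityConfig, multiscale_ncc_grad
from .volume import Volume, sample_trilinear_grad

__all__ = ["register_dense"]


def _diffusion_penalty_and_grad(u: np.ndarray):
    """Mean squared forward difference of the displacement, with gradient.

    Normalized per voxel so the smoothness weight is comparable to the
    (bounded) similarity term regardless of lattice size.
    """
    n = u[..., 0].size
    penalty = 0.0
    grad = np.zeros_like(u)
    for ax in range(3):
        d = np.diff(u, axis=ax)
        penalty += float((d * d).sum()) / n
        # adjoint of forward difference: scatter +/- 2d
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        grad[tuple(sl_lo)] -= 2.0 * d / n
        grad[tuple(sl_hi)] += 2.0 * d / n
    return penalty, grad


def register_dense(
    volume: Volume,
    images: Sequence[np.ndarray],
    cameras: Sequence[Camera],
    sim_config: SimilarityConfig | None = None,
    opt_config: OptimConfig | None = None,
    render_config: RenderConfig | None = None,
    smooth_weight: float = 0.0,
):
    """Gradient ascent over a dense per-voxel translation field.

    Maximizes mean view similarity minus ``smooth_weight`` times the diffusion
    penalty.  Returns ``(displacement, report)`` with the displacement in mm
    on the volume lattice (output-to-input convention; all zeros = identity,
    and zero iterations leave it untouched).
    """
    sim_config = sim_config or SimilarityConfig()
    opt_config = opt_config or OptimConfig()
    render_config = render_config or RenderConfig()
    if len(images) < 1:
        raise ValueError("need at least one view")
    if len(images) != len(cameras):
        raise ValueError("need one camera per image")

    shape = volume.grid.shape
    centers = volume.grid.voxel_centers()
    projectors = [Projector(volume.grid, cam, render_config) for cam in cameras]
    n_views = len(images)

    u = np.zeros(shape + (3,))
    adam = AdamAscent(np.full(u.size, opt_config.step_xyz))
    history = []
    best_u, best_val = u.copy(), -np.inf
    anchor_val, anchor_it = None, 0
    for it in range(opt_config.max_iters + 1):
        y = (centers + u).reshape(-1, 3)
        vals, grad_v = sample_trilinear_grad(volume, y)
        v_w = vals.reshape(shape)
        total = 0.0
        b = np.zeros(shape)
        for img, proj in zip(images, projectors):
            val, g_img = multiscale_ncc_grad(img, proj.forward(v_w), sim_config)
            total += val / n_views
            b += proj.adjoint(g_img) / n_views
        grad = b.reshape(-1, 1) * grad_v  # dL/du per voxel
        grad = grad.reshape(shape + (3,))
        if smooth_weight > 0:
            pen, pen_grad = _diffusion_penalty_and_grad(u)
            total -= smooth_weight * pen
            grad -= smooth_weight * pen_grad
        if not np.isfinite(total):
            raise RuntimeError(f"non-finite objective at iteration {it}")
        history.append(total)
        if total > best_val:
            best_val, best_u = total, u.copy()
        if anchor_val is None:
            anchor_val = best_val
        if it - anchor_it >= opt_config.plateau_patience:
            if best_val - anchor_val < opt_config.plateau_rel_tol * max(1.0, abs(anchor_val)):
                break
            anchor_val, anchor_it = best_val, it
        if it < opt_config.max_iters:
            u = adam.step(u.ravel(), grad.ravel()).reshape(shape + (3,))

    report = {"loss": history, "final_similarity": best_val, "smooth_weight": smooth_weight}
    return best_u, report
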