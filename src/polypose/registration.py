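"""Camera (anchor) registration and joint polyrigid pose optimization.

Both stages maximize the multiscale patchwise ZNCC between observed X-rays
and renderings of the (masked / warped) volume by gradient ascent on se(3)
twists, with Adam step sizes split between rotational (default 1e-2) and
translational (default 1.0) twist components.

The polyrigid stage uses a fully analytic gradient.  The chain, per view n
with fixed camera, is

    L = NCC(I_n, A_n v_w),     v_w[j] = V(Phi(x_j)),    Phi(x_j) = exp(eta_j) x_j,
    eta_j = sum_k W[j,k] * xi_k,

where ``A_n`` is the (pose-independent) sparse projection operator.  The
gradient pulls the NCC image gradient back through the projector adjoint to a
per-voxel sensitivity ``b_j``, multiplies by the exact trilinear spatial
gradient of ``V`` at the mapped points, contracts with the closed-form
derivative of the SE(3) exponential, and accumulates into the K x 6 twist
table through the weight matrix.  The camera stage optimizes only 6
parameters per view, where central finite differences are cheap and robust to
the moving-geometry stencil.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np

from . import se3
from .camera import Camera
from .polyrigid import PolyrigidField, build_field, build_structure_set, build_weights
from .renderer import Projector, RenderConfig
from .similarity import SimilarityConfig, multiscale_ncc_grad
from .volume import Labelmap, Volume, sample_trilinear_grad

logger = logging.getLogger(__name__)

__all__ = ["OptimConfig", "AdamAscent", "register_camera", "register_polyrigid"]


@dataclass
class OptimConfig:
    """Gradient-ascent settings shared by both registration stages."""

    step_rot: float = 1e-2  # Adam step for rotational twist components (rad)
    step_xyz: float = 1.0  # Adam step for translational components (mm)
    max_iters: int = 300
    plateau_rel_tol: float = 1e-5  # stop when the best value improves less than this ...
    plateau_patience: int = 20  # ... (relative) over this many iterations
    seed: int = 0

    def __post_init__(self):
        if self.step_rot <= 0 or self.step_xyz <= 0:
            raise ValueError("step sizes must be positive")
        if self.max_iters < 0:
            raise ValueError("max_iters must be non-negative")


class AdamAscent:
    """Adam with a per-component step size, stepping uphill."""

    def __init__(self, lr: np.ndarray, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = np.asarray(lr, dtype=float)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = np.zeros_like(self.lr)
        self.v = np.zeros_like(self.lr)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return params + self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _twist_lr(opt: OptimConfig, n_twists: int) -> np.ndarray:
    lr = np.empty((n_twists, 6))
    lr[:, :3] = opt.step_rot
    lr[:, 3:] = opt.step_xyz
    return lr


def _ascend(loss_and_grad, x0: np.ndarray, lr: np.ndarray, opt: OptimConfig):
    """Monotone-best gradient ascent with plateau stopping.

    Runs Adam, tracks the best-scoring iterate (so the sequence of accepted
    solutions is non-decreasing by construction), and stops when the best
    value has improved by less than ``plateau_rel_tol`` (relative) over
    ``plateau_patience`` iterations.
    """
    adam = AdamAscent(lr)
    x = x0.copy()
    value, grad = loss_and_grad(x)
    if not np.isfinite(value):
        raise RuntimeError("non-finite objective at initialization")
    best_value, best_x = value, x.copy()
    history = [value]
    anchor_value, anchor_iter = best_value, 0
    for it in range(1, opt.max_iters + 1):
        x = adam.step(x, grad)
        value, grad = loss_and_grad(x)
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite objective at iteration {it}")
        history.append(value)
        if value > best_value:
            best_value, best_x = value, x.copy()
        if it - anchor_iter >= opt.plateau_patience:
            if best_value - anchor_value < opt.plateau_rel_tol * max(1.0, abs(anchor_value)):
                break
            anchor_value, anchor_iter = best_value, it
    return best_x, best_value, history


# ---------------------------------------------------------------------------
# Camera (anchor) registration


def _coarse_config(sim_config: SimilarityConfig, image_shape) -> SimilarityConfig | None:
    """Heavily pooled, raw-intensity variant of a similarity config.

    Used as the first rung of coarse-to-fine camera alignment: block-mean
    pooling widens the basin of attraction well beyond the native-resolution
    capture range.  Returns None when the image is too small to pool while
    still fitting at least a few full patches.
    """
    for factor in (4, 2):
        scale = factor * min(sim_config.scales)
        if min(image_shape) // scale >= sim_config.patch_size + 4:
            return SimilarityConfig(
                patch_size=sim_config.patch_size,
                scales=(scale,),
                use_sobel=False,
                raw_weight=1.0,
            )
    return None


def register_camera(
    volume: Volume,
    labelmap: Labelmap,
    anchor_id: int,
    images: Sequence[np.ndarray],
    init_cameras: Sequence[Camera],
    sim_config: SimilarityConfig | None = None,
    opt_config: OptimConfig | None = None,
    render_config: RenderConfig | None = None,
    mask_to_anchor: bool = True,
    coarse_to_fine: bool = True,
):
    """Estimate per-view camera extrinsics by rigidly aligning an anchor structure.

    Each view is optimized independently.  Rather than re-tracing rays for a
    moving camera, the (exactly equivalent) volume-side problem is solved: the
    anchor-masked volume is rigidly transformed by ``exp(xi)`` through the same
    differentiable warp-and-render chain as the deformable stage, with a fixed
    precomputed projector; the extrinsic correction is then
    ``E_new = E_init @ exp(xi)^{-1}``.  The twist is parameterized about the
    anchor centroid and, by default, optimized coarse-to-fine (a heavily
    pooled similarity first) to widen the capture range.  Intrinsics pass
    through unchanged.  Returns (cameras, report).
    """
    sim_config = sim_config or SimilarityConfig()
    opt_config = opt_config or OptimConfig()
    render_config = render_config or RenderConfig()
    if len(images) != len(init_cameras):
        raise ValueError("need one initial camera per image")
    present = set(int(i) for i in np.unique(labelmap.labels))
    if int(anchor_id) not in present:
        raise ValueError(f"anchor structure {anchor_id} not present in labelmap")

    if mask_to_anchor:
        vals = np.where(labelmap.labels == anchor_id, volume.values, 0.0)
        render_vol = Volume(vals.astype(np.float32), volume.affine.copy())
    else:
        render_vol = Volume(volume.values.astype(np.float32), volume.affine.copy())

    # pivot the twist about the centroid of what is actually rendered:
    # the anchor when masked, the attenuation center of mass otherwise
    centers_grid = volume.grid.voxel_centers()
    if mask_to_anchor:
        pivot = centers_grid[labelmap.labels == anchor_id].mean(axis=0)
    else:
        w = volume.values / volume.values.sum()
        pivot = (centers_grid * w[..., None]).sum(axis=(0, 1, 2))
    adjoint = np.eye(6)
    adjoint[3:, :3] = se3.hat3(pivot)

    x32 = centers_grid.reshape(-1, 3).astype(np.float32)
    shape = volume.grid.shape
    stages = [sim_config]
    if coarse_to_fine:
        coarse = _coarse_config(sim_config, np.asarray(images[0]).shape)
        if coarse is not None:
            stages.insert(0, coarse)

    out_cameras = []
    report = {"loss": [], "final_similarity": [], "initial_similarity": []}
    for n, (img, cam0) in enumerate(zip(images, init_cameras)):
        proj = Projector(volume.grid, cam0, render_config)

        def make_loss(stage_cfg, _img=img, _proj=proj):
            def loss_and_grad(local: np.ndarray):
                xi = adjoint @ local
                eta = np.broadcast_to(xi.astype(np.float32), (x32.shape[0], 6))
                y, dy = se3.dexp_point(eta, x32)
                vals, grad_v = sample_trilinear_grad(render_vol, y)
                value, g_img = multiscale_ncc_grad(_img, _proj.forward(vals.reshape(shape)), stage_cfg)
                b = _proj.adjoint(g_img)
                q = b.reshape(-1, 1) * grad_v
                d_xi = np.einsum("mis,mi->s", dy, q)
                return value, adjoint.T @ d_xi

            return loss_and_grad

        local = np.zeros(6)
        histories = []
        lr = np.array([opt_config.step_rot] * 3 + [opt_config.step_xyz] * 3)
        for stage_cfg in stages:
            local, best_val, history = _ascend(make_loss(stage_cfg), local, lr, opt_config)
            histories.append(history)
        xi = adjoint @ local
        out_cameras.append(cam0.with_extrinsic(cam0.extrinsic @ se3.invert_rigid(se3.exp_se3(xi))))
        full_history = [v for h in histories for v in h]
        report["loss"].append(full_history)
        report["initial_similarity"].append(histories[-1][0])
        report["final_similarity"].append(best_val)
        logger.info("view %d: similarity %.4f -> %.4f", n, full_history[0], best_val)
    return out_cameras, report


# ---------------------------------------------------------------------------
# Joint polyrigid registration


def register_polyrigid(
    volume: Volume,
    labelmap: Labelmap,
    structure_ids: Sequence[int],
    images: Sequence[np.ndarray],
    cameras: Sequence[Camera],
    weights_mode: str = "mass",
    epsilon: Optional[float] = None,
    sim_config: SimilarityConfig | None = None,
    opt_config: OptimConfig | None = None,
    render_config: RenderConfig | None = None,
):
    """Jointly optimize the K structure poses of a polyrigid deformation.

    Maximizes the mean similarity over all views between the observed images
    and renderings of the warped volume, starting from zero twists.  Structures
    not listed in ``structure_ids`` are excluded from the weight field (and
    implicitly carry zero motion).

    Returns ``(twists, field, report)``: the optimized K x 6 twist table, the
    final polyrigid field, and a report with the per-iteration objective and
    final per-structure pose magnitudes.
    """
    sim_config = sim_config or SimilarityConfig()
    opt_config = opt_config or OptimConfig()
    render_config = render_config or RenderConfig()
    if len(images) < 1:
        raise ValueError("need at least one view")
    if len(images) != len(cameras):
        raise ValueError("need one camera per image")
    structure_ids = [int(s) for s in structure_ids]
    if len(structure_ids) == 0:
        raise ValueError("structure_ids must not be empty")

    ss = build_structure_set(labelmap, ids=structure_ids)
    wf = build_weights(ss, weights_mode, epsilon)
    W = wf.table  # (M, K)
    K = W.shape[1]
    x = volume.grid.voxel_centers().reshape(-1, 3)
    shape = volume.grid.shape
    n_views = len(images)
    projectors = [Projector(volume.grid, cam, render_config) for cam in cameras]

    # Optimize each structure's twist about its own centroid: rotations about
    # the (off-center) world origin drag a translation along, which badly
    # conditions joint gradient ascent.  The reparameterization is the constant
    # adjoint of the centroid translation, so the model itself is unchanged:
    # the world-frame twist table is Ad_k @ xi_k.
    centers_grid = volume.grid.voxel_centers()
    adjoints = np.empty((K, 6, 6))
    for k in range(K):
        c_k = centers_grid[ss.masks[k]].mean(axis=0)
        adjoints[k] = np.eye(6)
        adjoints[k][3:, :3] = se3.hat3(c_k)

    def to_world(local_flat: np.ndarray) -> np.ndarray:
        local = local_flat.reshape(K, 6)
        return np.einsum("kij,kj->ki", adjoints, local)

    # the heavy per-voxel chain runs in float32: the pose gradient needs only
    # a few significant digits, and the final field is rebuilt in float64
    W32 = W.astype(np.float32)
    x32 = x.astype(np.float32)
    vol32 = Volume(volume.values.astype(np.float32), volume.affine.copy())

    def loss_and_grad(local_flat: np.ndarray):
        twists = to_world(local_flat)
        eta = W32 @ twists.astype(np.float32)  # (M, 6) fused per-voxel twists
        y, dy = se3.dexp_point(eta, x32)  # (M, 3), (M, 3, 6)
        vals, grad_v = sample_trilinear_grad(vol32, y)
        v_w = vals.reshape(shape)
        total = 0.0
        b = np.zeros(shape)
        for img, proj in zip(images, projectors):
            rendered = proj.forward(v_w)
            val, g_img = multiscale_ncc_grad(img, rendered, sim_config)
            total += val / n_views
            b += proj.adjoint(g_img) / n_views
        q = b.reshape(-1, 1) * grad_v  # (M, 3) sensitivity of L to the mapped points
        d_eta = np.einsum("mis,mi->ms", dy, q)  # (M, 6)
        d_twists = W.T @ d_eta  # (K, 6) world-frame gradient
        d_local = np.einsum("kji,kj->ki", adjoints, d_twists)  # chain through Ad_k
        return total, d_local.ravel()

    lr = _twist_lr(opt_config, K).ravel()
    best, best_val, history = _ascend(loss_and_grad, np.zeros(K * 6), lr, opt_config)
    twists = to_world(best)
    field = build_field(wf, twists)

    report = {
        "loss": history,
        "final_similarity": best_val,
        "structure_ids": structure_ids,
        "per_structure": [
            {
                "id": sid,
                "rotation_deg": float(np.rad2deg(np.linalg.norm(t[:3]))),
                "translation_mm": float(np.linalg.norm(t[3:])),
            }
            for sid, t in zip(structure_ids, twists)
        ],
    }
    return twists, field, report
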