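"""Patch-wise zero-normalized cross-correlation image similarity.

The registration objective compares a fixed (measured) X-ray ``a`` against a
rendered X-ray ``b`` with the mean patchwise ZNCC, computed over two channels
(raw intensities and Sobel gradient magnitude) at multiple scales (block-mean
downsampling).  The score lies in [-1, 1] and is invariant to positive affine
intensity changes per patch; patches where either image has zero variance are
excluded from the mean.

Local patch statistics are computed with uniform box filters, which makes the
analytic gradient with respect to ``b`` a short chain of the same filters
(the box filter is self-adjoint with zero-padded boundaries); the Sobel
channel chains through the (anti-self-adjoint) Sobel convolution.  The
gradient is exact for the discrete objective and is verified against finite
differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["SimilarityConfig", "multiscale_ncc", "multiscale_ncc_grad"]

_VAR_TOL = 1e-12


@dataclass
class SimilarityConfig:
    """Configuration of the multiscale patchwise ZNCC.

    ``scales`` are integer block-mean downsampling factors (1 = native
    resolution); ``patch_size`` is odd, in pixels of each scale.
    """

    patch_size: int = 13
    scales: Sequence[int] = (1, 2)
    use_sobel: bool = True
    raw_weight: float = 1.0
    sobel_weight: float = 1.0

    def __post_init__(self):
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if len(self.scales) == 0:
            raise ValueError("at least one scale is required")
        if any(int(s) != s or s < 1 for s in self.scales):
            raise ValueError("scales must be positive integers (downsampling factors)")


def _boxfilter(x: np.ndarray, size: int) -> np.ndarray:
    return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0)


def _patch_zncc(a: np.ndarray, b: np.ndarray, size: int, want_grad: bool, extra_margin: int = 0):
    """Mean patchwise ZNCC of two single-channel images (+ gradient wrt b)."""
    U = lambda x: _boxfilter(x, size)
    mu_a, mu_b = U(a), U(b)
    cov = U(a * b) - mu_a * mu_b
    var_a = U(a * a) - mu_a**2
    var_b = U(b * b) - mu_b**2
    tol_a = _VAR_TOL * max(1.0, float(var_a.max(initial=0.0)))
    tol_b = _VAR_TOL * max(1.0, float(var_b.max(initial=0.0)))
    valid = (var_a > tol_a) & (var_b > tol_b)
    # only patches whose window fits fully inside the image contribute: the
    # zero-padded boundary statistics are not meaningful patch statistics
    m = size // 2 + extra_margin
    interior = np.zeros_like(valid)
    if a.shape[0] > 2 * m and a.shape[1] > 2 * m:
        interior[m : a.shape[0] - m, m : a.shape[1] - m] = True
    valid &= interior
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, (np.zeros_like(b) if want_grad else None)
    denom = np.ones_like(cov)
    denom[valid] = np.sqrt(var_a[valid] * var_b[valid])
    ncc = np.where(valid, cov / denom, 0.0)
    value = float(ncc.sum() / n_valid)
    if not want_grad:
        return value, None
    alpha = np.where(valid, 1.0 / (n_valid * denom), 0.0)
    safe_var_b = np.where(valid, var_b, 1.0)
    beta = np.where(valid, -0.5 * ncc / (n_valid * safe_var_b), 0.0)
    grad = a * U(alpha) - U(alpha * mu_a) + 2.0 * b * U(beta) - 2.0 * U(beta * mu_b)
    return value, grad


def _sobel(x: np.ndarray, axis: int) -> np.ndarray:
    return ndimage.sobel(x, axis=axis, mode="constant", cval=0.0)


def _sobel_magnitude(x: np.ndarray):
    gx = _sobel(x, 0)
    gy = _sobel(x, 1)
    m = np.sqrt(gx * gx + gy * gy + 1e-12)
    return m, gx, gy


def _sobel_magnitude_adjoint(x_gx, x_gy, grad_m, m, gx, gy):
    """Chain a gradient wrt the Sobel magnitude back to the image."""
    dgx = grad_m * gx / m
    dgy = grad_m * gy / m
    # adjoint of Sobel correlation (antisymmetric kernel) is its negative
    return -_sobel(dgx, 0) - _sobel(dgy, 1)


def _pool(x: np.ndarray, f: int) -> np.ndarray:
    """Block-mean downsampling by integer factor f (crops to a multiple of f)."""
    if f == 1:
        return x
    h, w = (x.shape[0] // f) * f, (x.shape[1] // f) * f
    return x[:h, :w].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def _pool_adjoint(g: np.ndarray, f: int, shape) -> np.ndarray:
    if f == 1:
        return g
    out = np.zeros(shape)
    up = np.repeat(np.repeat(g, f, axis=0), f, axis=1) / (f * f)
    out[: up.shape[0], : up.shape[1]] = up
    return out


def _evaluate(a: np.ndarray, b: np.ndarray, cfg: SimilarityConfig, want_grad: bool):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("images must be finite")

    channels = [("raw", cfg.raw_weight)]
    if cfg.use_sobel:
        channels.append(("sobel", cfg.sobel_weight))
    total_w = sum(w for _, w in channels) * len(cfg.scales)

    value = 0.0
    grad = np.zeros_like(b) if want_grad else None
    for f in cfg.scales:
        af, bf = _pool(a, f), _pool(b, f)
        for name, w in channels:
            if name == "raw":
                v, g = _patch_zncc(af, bf, cfg.patch_size, want_grad)
                if want_grad:
                    grad += (w / total_w) * _pool_adjoint(g, f, b.shape)
            else:
                ma, _, _ = _sobel_magnitude(af)
                mb, gx, gy = _sobel_magnitude(bf)
                # the outermost Sobel ring reflects zero padding, not data
                v, g = _patch_zncc(ma, mb, cfg.patch_size, want_grad, extra_margin=1)
                if want_grad:
                    g_img = _sobel_magnitude_adjoint(af, bf, g, mb, gx, gy)
                    grad += (w / total_w) * _pool_adjoint(g_img, f, b.shape)
            value += (w / total_w) * v
    return value, grad


def multiscale_ncc(a: np.ndarray, b: np.ndarray, cfg: SimilarityConfig | None = None) -> float:
    """Mean multiscale patchwise ZNCC between two images, in [-1, 1]."""
    cfg = cfg or SimilarityConfig()
    value, _ = _evaluate(a, b, cfg, want_grad=False)
    return value


def multiscale_ncc_grad(a: np.ndarray, b: np.ndarray, cfg: SimilarityConfig | None = None):
    """Similarity value and its exact gradient with respect to ``b``."""
    cfg = cfg or SimilarityConfig()
    return _evaluate(a, b, cfg, want_grad=True)
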