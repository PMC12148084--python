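"""Closed-form se(3) <-> SE(3) maps and their derivatives.

Twists are length-6 vectors ordered (rotation, translation): the first three
components are the axis-angle rotational tangent (radians), the last three the
translational tangent (mm).  All functions are batched: they accept arrays of
shape ``(..., 6)`` / ``(..., 4, 4)`` and vectorize over leading dimensions.

The exponential uses the Rodrigues rotation formula and the SO(3) left
Jacobian ``V(theta)`` for the translation block; the logarithm inverts both in
closed form.  Rotation angles at or above ``pi`` are rejected by ``log_se3``
(the logarithm is not unique there); small angles switch to Taylor expansions
to avoid catastrophic cancellation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hat3",
    "vee3",
    "exp_se3",
    "log_se3",
    "batch_exp",
    "is_rigid",
    "assert_rigid",
    "invert_rigid",
    "se3_right_jacobian",
    "dexp_point",
    "rotation_angle",
]

_SMALL = 1e-6
_LOG_ANGLE_TOL = 1e-7


def hat3(omega: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix (batched): hat3(w) @ x == cross(w, x)."""
    omega = np.asarray(omega)
    if not np.issubdtype(omega.dtype, np.floating):
        omega = omega.astype(float)
    out = np.zeros(omega.shape[:-1] + (3, 3), dtype=omega.dtype)
    wx, wy, wz = omega[..., 0], omega[..., 1], omega[..., 2]
    out[..., 0, 1] = -wz
    out[..., 0, 2] = wy
    out[..., 1, 0] = wz
    out[..., 1, 2] = -wx
    out[..., 2, 0] = -wy
    out[..., 2, 1] = wx
    return out


def vee3(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hat3` for (batched) skew-symmetric matrices."""
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., 2, 1], m[..., 0, 2], m[..., 1, 0]], axis=-1)


def _sincos_coeffs(theta: np.ndarray):
    """Rodrigues coefficients A=sin/t, B=(1-cos)/t^2, C=(t-sin)/t^3.

    Taylor branches below ``_SMALL`` keep the maps smooth through zero.
    """
    t2 = theta * theta
    small = theta < _SMALL
    safe = np.where(small, 1.0, theta)
    A = np.where(small, 1.0 - t2 / 6.0, np.sin(safe) / safe)
    B = np.where(small, 0.5 - t2 / 24.0, (1.0 - np.cos(safe)) / (safe * safe))
    C = np.where(small, 1.0 / 6.0 - t2 / 120.0, (safe - np.sin(safe)) / (safe**3))
    return A, B, C


def exp_se3(xi: np.ndarray) -> np.ndarray:
    """Exponential map from se(3) twists to SE(3) homogeneous matrices.

    Parameters
    ----------
    xi : array, shape (..., 6)
        Twists ordered (rot, trans).

    Returns
    -------
    array, shape (..., 4, 4)
    """
    xi = np.asarray(xi, dtype=float)
    if xi.shape[-1] != 6:
        raise ValueError(f"twist must have 6 components, got shape {xi.shape}")
    if not np.all(np.isfinite(xi)):
        raise ValueError("twist contains non-finite entries")
    omega, v = xi[..., :3], xi[..., 3:]
    theta = np.linalg.norm(omega, axis=-1)
    A, B, C = _sincos_coeffs(theta)
    W = hat3(omega)
    W2 = W @ W
    eye = np.broadcast_to(np.eye(3), W.shape)
    R = eye + A[..., None, None] * W + B[..., None, None] * W2
    V = eye + B[..., None, None] * W + C[..., None, None] * W2
    t = np.einsum("...ij,...j->...i", V, v)
    T = np.zeros(xi.shape[:-1] + (4, 4), dtype=float)
    T[..., :3, :3] = R
    T[..., :3, 3] = t
    T[..., 3, 3] = 1.0
    return T


def batch_exp(twists: np.ndarray) -> np.ndarray:
    """Vectorized exponential of a table of twists (rows of a K x 6 matrix).

    Identical to :func:`exp_se3`; provided as the named entry point for the
    vectorized forward model, where millions of per-voxel twists are
    exponentiated at once.
    """
    twists = np.asarray(twists, dtype=float)
    if twists.ndim < 2 or twists.shape[-1] != 6:
        raise ValueError(f"expected an (..., 6) table of twists, got {twists.shape}")
    return exp_se3(twists)


def is_rigid(T: np.ndarray, tol: float = 1e-9) -> bool:
    T = np.asarray(T, dtype=float)
    if T.shape[-2:] != (4, 4):
        return False
    R = T[..., :3, :3]
    ortho = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max() <= tol
    det = np.abs(np.linalg.det(R) - 1.0).max() <= tol
    bottom = np.abs(T[..., 3, :] - np.array([0.0, 0.0, 0.0, 1.0])).max() <= tol
    return bool(ortho and det and bottom)


def assert_rigid(T: np.ndarray, tol: float = 1e-8) -> None:
    if not is_rigid(T, tol=tol):
        raise ValueError("matrix is not a rigid transform (orthonormality/det/last-row check failed)")


def invert_rigid(T: np.ndarray) -> np.ndarray:
    """Inverse of (batched) rigid transforms via transpose of the rotation."""
    T = np.asarray(T, dtype=float)
    R = T[..., :3, :3]
    t = T[..., :3, 3]
    Rt = np.swapaxes(R, -1, -2)
    out = np.zeros_like(T)
    out[..., :3, :3] = Rt
    out[..., :3, 3] = -np.einsum("...ij,...j->...i", Rt, t)
    out[..., 3, 3] = 1.0
    return out


def rotation_angle(T: np.ndarray) -> np.ndarray:
    """Rotation angle (radians) of (batched) rigid transforms."""
    T = np.asarray(T, dtype=float)
    tr = np.trace(T[..., :3, :3], axis1=-2, axis2=-1)
    return np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))


def log_se3(T: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Logarithm map from SE(3) matrices to se(3) twists.

    Requires the rotation angle to be strictly below ``pi`` (where the
    logarithm is unique).  Raises ``ValueError`` for non-rigid input or
    angles within ``_LOG_ANGLE_TOL`` of ``pi``.
    """
    T = np.asarray(T, dtype=float)
    if T.shape[-2:] != (4, 4):
        raise ValueError(f"expected (..., 4, 4) matrices, got {T.shape}")
    if not np.all(np.isfinite(T)):
        raise ValueError("transform contains non-finite entries")
    assert_rigid(T, tol=tol)
    R = T[..., :3, :3]
    t = T[..., :3, 3]
    theta = rotation_angle(T)
    if np.any(theta >= np.pi - _LOG_ANGLE_TOL):
        raise ValueError("rotation angle within tolerance of pi: logarithm not unique")

    # omega = theta / (2 sin theta) * vee(R - R^T); Taylor near zero.
    small = theta < _SMALL
    safe = np.where(small, 1.0, theta)
    factor = np.where(small, 0.5 + theta**2 / 12.0, safe / (2.0 * np.sin(safe)))
    omega = factor[..., None] * vee3(R - np.swapaxes(R, -1, -2))

    # V^{-1} = I - W/2 + D W^2 with D = (1 - theta sin / (2 (1-cos))) / theta^2
    t2 = theta * theta
    with np.errstate(invalid="ignore", divide="ignore"):
        D_exact = (1.0 - safe * np.sin(safe) / (2.0 * (1.0 - np.cos(safe)))) / (safe * safe)
    D = np.where(small, 1.0 / 12.0 + t2 / 720.0, D_exact)
    W = hat3(omega)
    W2 = W @ W
    eye = np.broadcast_to(np.eye(3), W.shape)
    Vinv = eye - 0.5 * W + D[..., None, None] * W2
    v = np.einsum("...ij,...j->...i", Vinv, t)
    return np.concatenate([omega, v], axis=-1)


def _so3_left_jacobian(omega: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(omega, axis=-1)
    _, B, C = _sincos_coeffs(theta)
    W = hat3(omega)
    W2 = W @ W
    eye = np.broadcast_to(np.eye(3), W.shape)
    return eye + B[..., None, None] * W + C[..., None, None] * W2


def _se3_Q(omega: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Coupling block of the SE(3) left Jacobian (Barfoot-style Q matrix)."""
    theta = np.linalg.norm(omega, axis=-1)
    t2 = theta * theta
    small = theta < _SMALL
    safe = np.where(small, 1.0, theta)
    sin, cos = np.sin(safe), np.cos(safe)
    # series limits:  c1 -> 1/6,  c2 -> -1/24,  c3 -> -1/120 (with next-order terms)
    c1 = np.where(small, 1.0 / 6.0 - t2 / 120.0, (safe - sin) / safe**3)
    c2 = np.where(small, -1.0 / 24.0 + t2 / 720.0, (1.0 - t2 / 2.0 - cos) / safe**4)
    c3 = np.where(
        small,
        -1.0 / 120.0 + t2 / 5040.0,
        (safe - sin - safe**3 / 6.0) / safe**5,
    )
    Wo = hat3(omega)
    Wv = hat3(v)
    WoWv = Wo @ Wv
    WvWo = Wv @ Wo
    WoWvWo = WoWv @ Wo
    Q = (
        0.5 * Wv
        + c1[..., None, None] * (WoWv + WvWo + WoWvWo)
        - c2[..., None, None] * (Wo @ WoWv + WvWo @ Wo - 3.0 * WoWvWo)
        - 0.5 * (c2 - 3.0 * c3)[..., None, None] * (WoWvWo @ Wo + Wo @ WoWvWo)
    )
    return Q


def se3_left_jacobian(xi: np.ndarray) -> np.ndarray:
    """Left Jacobian of SE(3) in (rot, trans) ordering: exp(xi + d) ~= exp(J_l d) exp(xi)."""
    xi = np.asarray(xi, dtype=float)
    omega, v = xi[..., :3], xi[..., 3:]
    J = _so3_left_jacobian(omega)
    Q = _se3_Q(omega, v)
    out = np.zeros(xi.shape[:-1] + (6, 6), dtype=float)
    out[..., :3, :3] = J
    out[..., 3:, 3:] = J
    out[..., 3:, :3] = Q
    return out


def se3_right_jacobian(xi: np.ndarray) -> np.ndarray:
    """Right Jacobian: exp(xi + d) ~= exp(xi) exp(J_r d).  J_r(xi) = J_l(-xi)."""
    return se3_left_jacobian(-np.asarray(xi, dtype=float))


def dexp_point(eta: np.ndarray, x: np.ndarray):
    """Value and derivative of ``y(eta) = exp(eta) @ [x; 1]`` with respect to eta.

    Parameters
    ----------
    eta : array, shape (..., 6)
        Per-point twists.
    x : array, shape (..., 3)
        Points the transforms act on (mm).

    Returns
    -------
    y : array, shape (..., 3)
        Transformed points.
    dy_deta : array, shape (..., 3, 6)
        Exact derivative, via ``dy = R(eta) [-hat(x) | I] J_r(eta) d(eta)``.
    """
    eta64 = np.asarray(eta, dtype=float)
    dtype = np.result_type(np.asarray(eta).dtype, np.asarray(x).dtype, np.float32)
    x = np.asarray(x, dtype=dtype)

    # trigonometric coefficients always in float64: several suffer heavy
    # cancellation near theta = 0 and would lose all precision in float32
    omega64, v64 = eta64[..., :3], eta64[..., 3:]
    theta = np.linalg.norm(omega64, axis=-1)
    A, B, C = _sincos_coeffs(theta)
    t2 = theta * theta
    small = theta < _SMALL
    safe = np.where(small, 1.0, theta)
    sin = np.sin(safe)
    c1 = np.where(small, 1.0 / 6.0 - t2 / 120.0, (safe - sin) / safe**3)
    c2 = np.where(small, -1.0 / 24.0 + t2 / 720.0, (1.0 - t2 / 2.0 - np.cos(safe)) / safe**4)
    c3 = np.where(small, -1.0 / 120.0 + t2 / 5040.0, (safe - sin - safe**3 / 6.0) / safe**5)

    def coef(c):
        return c.astype(dtype)[..., None, None]

    W = hat3(omega64.astype(dtype))
    Hv = hat3(v64.astype(dtype))
    W2 = W @ W
    eye = np.eye(3, dtype=dtype)
    R = eye + coef(A) * W + coef(B) * W2
    Vmat = eye + coef(B) * W + coef(C) * W2
    t = np.einsum("...ij,...j->...i", Vmat, v64.astype(dtype))
    y = np.einsum("...ij,...j->...i", R, x) + t

    # right Jacobian J_r(eta) = J_l(-eta): SO(3) block and Q block for (-w, -v)
    J3 = eye - coef(B) * W + coef(C) * W2
    WHv = W @ Hv
    HvW = Hv @ W
    WHvW = WHv @ W
    Q = (
        -0.5 * Hv
        + coef(c1) * (WHv + HvW - WHvW)
        - coef(c2) * (-(W2 @ Hv) - HvW @ W + 3.0 * WHvW)
        - 0.5 * coef(c2 - 3.0 * c3) * (WHvW @ W + W2 @ HvW)
    )
    # dy/d(eta) = R [ -hat(x) | I ] [[J3, 0], [Q, J3]] = [ R (Q - hat(x) J3) | R J3 ]
    Hx = hat3(x)
    dy = np.concatenate([R @ (Q - Hx @ J3), R @ J3], axis=-1)
    return y, dy
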