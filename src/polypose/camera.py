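"""Pinhole X-ray camera geometry.

The projection is factored as ``Pi = K [R|t]`` with an upper-triangular
intrinsic ``K`` (focal length, pixel spacing, principal point) and a rigid
extrinsic mapping world -> camera coordinates.  The X-ray source sits at the
camera center ``S = -R^T t``; the detector plane lies at distance ``f`` (the
focal length, i.e. source-to-detector distance) along the optical axis.

Pixel coordinates are ``(u, v)`` = (column, row), with pixel centers at
integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import se3

__all__ = [
    "Camera",
    "make_camera",
    "orbit_camera",
    "source_position",
    "pixel_to_world",
    "project",
    "camera_to_dict",
    "camera_from_dict",
    "save_cameras",
    "load_cameras",
]


@dataclass
class Camera:
    intrinsic: np.ndarray  # 3x3 upper-triangular K
    extrinsic: np.ndarray  # 4x4 rigid world -> camera
    detector_shape: tuple  # (rows, cols)
    pixel_spacing: np.ndarray  # (su, sv) mm along (cols, rows)

    def __post_init__(self):
        self.intrinsic = np.asarray(self.intrinsic, dtype=float)
        self.extrinsic = np.asarray(self.extrinsic, dtype=float)
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float)
        if self.intrinsic.shape != (3, 3):
            raise ValueError("intrinsic must be 3x3")
        if np.any(np.diag(self.intrinsic) <= 0) or np.abs(np.tril(self.intrinsic, -1)).max() > 1e-12:
            raise ValueError("intrinsic must be upper-triangular with positive diagonal")
        se3.assert_rigid(self.extrinsic)
        self.detector_shape = tuple(int(s) for s in self.detector_shape)

    @property
    def focal_length(self) -> float:
        """Source-to-detector distance f (mm), recovered from K and pixel spacing."""
        return float(self.intrinsic[0, 0] * self.pixel_spacing[0])

    @property
    def rotation(self) -> np.ndarray:
        return self.extrinsic[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.extrinsic[:3, 3]

    def with_extrinsic(self, extrinsic: np.ndarray) -> "Camera":
        return Camera(self.intrinsic.copy(), np.asarray(extrinsic, float),
                      self.detector_shape, self.pixel_spacing.copy())

    def pixel_grid(self) -> np.ndarray:
        """(u, v) coordinates of all pixel centers, shape (rows, cols, 2)."""
        rows, cols = self.detector_shape
        v, u = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
        return np.stack([u, v], axis=-1)


def make_camera(
    focal_length: float,
    detector_shape=(64, 64),
    pixel_spacing=(1.0, 1.0),
    principal_point=None,
    extrinsic=None,
) -> Camera:
    """Build a camera from physical detector parameters.

    ``K = [[f/su, 0, cu], [0, f/sv, cv], [0, 0, 1]]`` with pixel spacings
    ``(su, sv)`` in mm and the principal point in pixels (defaults to the
    detector center).
    """
    rows, cols = detector_shape
    su, sv = pixel_spacing
    if principal_point is None:
        principal_point = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    cu, cv = principal_point
    K = np.array([[focal_length / su, 0.0, cu], [0.0, focal_length / sv, cv], [0.0, 0.0, 1.0]])
    if extrinsic is None:
        extrinsic = np.eye(4)
    return Camera(K, extrinsic, detector_shape, np.array([su, sv], dtype=float))


def orbit_camera(
    isocenter,
    angle_deg: float,
    source_to_iso: float = 500.0,
    source_to_detector: float = 1000.0,
    detector_shape=(64, 64),
    pixel_spacing=(2.5, 2.5),
) -> Camera:
    """Camera on a circular orbit in the world x-y plane, aimed at the isocenter.

    ``angle_deg = 0`` places the source on the +x axis; the detector "up"
    direction is the world z axis.
    """
    iso = np.asarray(isocenter, dtype=float)
    a = np.deg2rad(angle_deg)
    S = iso + source_to_iso * np.array([np.cos(a), np.sin(a), 0.0])
    z_cam = iso - S
    z_cam /= np.linalg.norm(z_cam)
    up = np.array([0.0, 0.0, 1.0])
    x_cam = np.cross(up, z_cam)
    x_cam /= np.linalg.norm(x_cam)
    y_cam = np.cross(z_cam, x_cam)
    R = np.stack([x_cam, y_cam, z_cam])
    extrinsic = np.eye(4)
    extrinsic[:3, :3] = R
    extrinsic[:3, 3] = -R @ S
    return make_camera(source_to_detector, detector_shape, pixel_spacing, extrinsic=extrinsic)


def source_position(camera: Camera) -> np.ndarray:
    """World position of the X-ray source: S = -R^T t (satisfies R S + t = 0)."""
    return -camera.rotation.T @ camera.translation


def pixel_to_world(camera: Camera, pixels: np.ndarray) -> np.ndarray:
    """World position of detector points for pixel coordinates (u, v).

    The returned points lie on the detector plane at distance ``f`` from the
    source along the optical axis; projecting them back through the camera
    recovers the pixel coordinates.
    """
    p = np.asarray(pixels, dtype=float)
    su, sv = camera.pixel_spacing
    cu = camera.intrinsic[0, 2]
    cv = camera.intrinsic[1, 2]
    f = camera.focal_length
    x_cam = np.stack(
        [(p[..., 0] - cu) * su, (p[..., 1] - cv) * sv, np.full(p.shape[:-1], f)], axis=-1
    )
    R, t = camera.rotation, camera.translation
    return (x_cam - t) @ R  # R^T (x_cam - t), batched


def project(camera: Camera, points: np.ndarray) -> np.ndarray:
    """Project world points to pixel coordinates (u, v)."""
    X = np.asarray(points, dtype=float)
    x_cam = X @ camera.rotation.T + camera.translation
    h = x_cam @ camera.intrinsic.T
    z = h[..., 2]
    if np.any(np.abs(z) < 1e-12):
        raise ValueError("point projects to infinity (zero depth)")
    return h[..., :2] / z[..., None]


# ---------------------------------------------------------------------------
# Geometry JSON


def camera_to_dict(camera: Camera) -> dict:
    return {
        "focal_length_mm": camera.focal_length,
        "pixel_spacing_mm": camera.pixel_spacing.tolist(),
        "principal_point_px": [float(camera.intrinsic[0, 2]), float(camera.intrinsic[1, 2])],
        "detector_shape_px": list(camera.detector_shape),
        "extrinsic": camera.extrinsic.ravel().tolist(),
    }


def camera_from_dict(d: dict) -> Camera:
    ext = np.asarray(d["extrinsic"], dtype=float)
    if ext.size == 6:
        ext = se3.exp_se3(ext)
    elif ext.size == 16:
        ext = ext.reshape(4, 4)
    else:
        raise ValueError("extrinsic must be a 6-twist or 16-element matrix")
    return make_camera(
        d["focal_length_mm"],
        tuple(d["detector_shape_px"]),
        tuple(d["pixel_spacing_mm"]),
        tuple(d["principal_point_px"]),
        extrinsic=ext,
    )


def save_cameras(cameras, path) -> None:
    with open(path, "w") as f:
        json.dump([camera_to_dict(c) for c in cameras], f, indent=2)


def load_cameras(path):
    with open(path) as f:
        return [camera_from_dict(d) for d in json.load(f)]
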