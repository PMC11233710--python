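"""Pinhole-with-distortion camera model, projection, undistortion, triangulation.

The distortion model uses three radial and two tangential coefficients in
OpenCV ordering ``(k1, k2, p1, p2, k3)``; the camera JSON schema stores them
split into ``radial = (k1, k2, k3)`` and ``tangential = (p1, p2)``.

Global 3D coordinates are millimetres; image coordinates are pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import assert_rotation

__all__ = [
    "CameraModel",
    "Observation2D",
    "project",
    "undistort",
    "triangulate",
    "TriangulationError",
]


class TriangulationError(ValueError):
    """Raised for under-determined or degenerate triangulation problems."""


@dataclass
class CameraModel:
    """Calibrated pinhole camera with lens distortion.

    ``rotation`` and ``translation`` map global to camera coordinates:
    ``p_cam = rotation @ p_global + translation``.
    """

    focal: np.ndarray
    principal_point: np.ndarray
    radial: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tangential: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    image_size: np.ndarray = field(default_factory=lambda: np.array([896.0, 540.0]))
    camera_id: str = "cam"

    def __post_init__(self) -> None:
        for name in ("focal", "principal_point", "radial", "tangential", "rotation", "translation", "image_size"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.focal.shape != (2,) or np.any(self.focal <= 0):
            raise ValueError("focal must be a 2-vector with positive components")
        if self.radial.shape != (3,):
            raise ValueError("radial must have 3 coefficients (k1, k2, k3)")
        if self.tangential.shape != (2,):
            raise ValueError("tangential must have 2 coefficients (p1, p2)")
        assert_rotation(self.rotation, tol=1e-9, name="camera rotation")

    # -- coordinate helpers -------------------------------------------------
    def to_camera(self, point3: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(point3, float) + self.translation

    def distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        """Apply radial + tangential distortion to normalized coordinates."""
        x, y = float(xy[0]), float(xy[1])
        k1, k2, k3 = self.radial
        p1, p2 = self.tangential
        r2 = x * x + y * y
        rad = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
        xd = x * rad + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        yd = y * rad + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        return np.array([xd, yd])

    def projection_matrix(self) -> np.ndarray:
        """Ideal (distortion-free) 3x4 projection matrix ``K [R | t]``."""
        k = np.array(
            [
                [self.focal[0], 0.0, self.principal_point[0]],
                [0.0, self.focal[1], self.principal_point[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        rt = np.hstack([self.rotation, self.translation.reshape(3, 1)])
        return k @ rt


@dataclass
class Observation2D:
    """A single 2D keypoint observation in one camera view."""

    camera_id: str
    pixel: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.pixel = np.asarray(self.pixel, dtype=float)


def project(point3: np.ndarray, cam: CameraModel, apply_distortion: bool = True) -> np.ndarray:
    """Project a global 3D point (mm) to pixel coordinates.

    Raises ``ValueError`` if the point has non-positive depth in the camera.
    """
    pc = cam.to_camera(point3)
    if pc[2] <= 0:
        raise ValueError(f"point behind camera {cam.camera_id!r} (depth {pc[2]:.6g} mm)")
    xy = pc[:2] / pc[2]
    if apply_distortion:
        xy = cam.distort_normalized(xy)
    return cam.focal * xy + cam.principal_point


def undistort(
    pixel: np.ndarray,
    cam: CameraModel,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Invert the lens distortion, returning ideal pixel coordinates.

    Fixed-point iteration in normalized coordinates; raises ``RuntimeError``
    with the residual magnitude if it fails to converge.
    """
    pixel = np.asarray(pixel, dtype=float)
    xd = (pixel - cam.principal_point) / cam.focal
    if not np.all(np.isfinite(cam.radial)) or not np.all(np.isfinite(cam.tangential)):
        raise ValueError("distortion coefficients must be finite")
    x = xd.copy()
    k1, k2, k3 = cam.radial
    p1, p2 = cam.tangential
    for _ in range(max_iter):
        r2 = x[0] * x[0] + x[1] * x[1]
        rad = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
        dx = 2.0 * p1 * x[0] * x[1] + p2 * (r2 + 2.0 * x[0] * x[0])
        dy = p1 * (r2 + 2.0 * x[1] * x[1]) + 2.0 * p2 * x[0] * x[1]
        x_new = (xd - np.array([dx, dy])) / rad
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    else:
        resid = np.max(np.abs(cam.distort_normalized(x) - xd))
        raise RuntimeError(
            f"undistortion did not converge in {max_iter} iterations "
            f"(residual {resid:.3e} in normalized coordinates)"
        )
    return cam.focal * x + cam.principal_point


def triangulate(
    observations: list[Observation2D],
    cameras: list[CameraModel],
) -> tuple[np.ndarray, float]:
    """Triangulate a 3D point (mm) from >= 2 valid observations via SVD.

    Image coordinates are undistorted internally before the homogeneous DLT
    solve. Returns ``(point3, mean_reprojection_error_px)``.
    """
    cam_by_id = {c.camera_id: c for c in cameras}
    pairs: list[tuple[Observation2D, CameraModel]] = []
    for obs in observations:
        if not obs.valid:
            continue
        if obs.camera_id not in cam_by_id:
            raise TriangulationError(f"no calibration for camera {obs.camera_id!r}")
        cam = cam_by_id[obs.camera_id]
        if np.any(obs.pixel < 0) or np.any(obs.pixel > cam.image_size):
            warnings.warn(
                f"observation in camera {obs.camera_id!r} lies outside the image bounds",
                stacklevel=2,
            )
        pairs.append((obs, cam))
    if len(pairs) < 2:
        raise TriangulationError(
            f"triangulation needs >= 2 valid observations, got {len(pairs)}"
        )
    if len({cam.camera_id for _, cam in pairs}) < 2:
        raise TriangulationError("observations must come from distinct cameras")

    rows = []
    for obs, cam in pairs:
        ideal = undistort(obs.pixel, cam)
        p = cam.projection_matrix()
        rows.append(ideal[0] * p[2] - p[0])
        rows.append(ideal[1] * p[2] - p[1])
    a = np.vstack(rows)
    _, s, vt = np.linalg.svd(a)
    if s[0] <= 0 or s[-2] / s[0] < 1e-12:
        raise TriangulationError("degenerate geometry: DLT system is rank deficient")
    x = vt[-1]
    if abs(x[3]) < 1e-15:
        raise TriangulationError("degenerate geometry: point at infinity")
    point = x[:3] / x[3]

    errs = []
    for obs, cam in pairs:
        errs.append(np.linalg.norm(project(point, cam, apply_distortion=True) - obs.pixel))
    return point, float(np.mean(errs))
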