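"""Fly-specific right-handed body coordinate system.

The frame is anchored at the posterior scutellum apex (ThAp) with the y-axis
pointing toward the left wing hinge, the x-axis anterior, and z = x cross y.
Because the wing hinges sit ventrally relative to the ThAp, the raw
ThAp-to-hinge-midpoint vector is skewed; it is de-skewed by reflecting it
across the plane spanned by the hinge axis and an anteroposterior hint vector
and averaging with its reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import apply_transform, pose_matrix, unit

__all__ = ["BodyFrame", "compute_body_frame", "to_body", "to_global"]


@dataclass(frozen=True)
class BodyFrame:
    """Right-handed orthonormal frame: origin (mm) plus unit axes."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        axes = np.column_stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-9):
            raise ValueError("body frame axes are not orthonormal within 1e-9")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-9):
            raise ValueError("body frame is not right-handed (x cross y != z)")

    @property
    def matrix(self) -> np.ndarray:
        """4x4 transform taking body coordinates to global coordinates."""
        return pose_matrix(self.x_axis, self.y_axis, self.z_axis, self.origin)

    @property
    def inverse_matrix(self) -> np.ndarray:
        m = np.eye(4)
        r = np.column_stack([self.x_axis, self.y_axis, self.z_axis])
        m[:3, :3] = r.T
        m[:3, 3] = -r.T @ self.origin
        return m


def compute_body_frame(
    ThAp: np.ndarray,
    lWH: np.ndarray,
    rWH: np.ndarray,
    anteroposterior_axis: np.ndarray = (1.0, 0.0, 0.0),
    halve_midpoints: bool = True,
) -> BodyFrame:
    """Construct the body frame from ThAp and wing-hinge landmarks.

    Parameters
    ----------
    anteroposterior_axis
        Unit hint vector ``c`` giving the approximate posterior-to-anterior
        direction in global coordinates (default: global x-axis, the
        convention of the top-camera-anchored global frame).
    halve_midpoints
        The published construction is ambiguous about halving factors in the
        midpoint-of-reflection step. ``True`` (default) uses
        ``m = ThAp + x_skewed / 2`` and ``x = (m + r / 2) - ThAp``;
        ``False`` uses the sum ``x = x_skewed + r`` directly. The two
        variants yield the same direction after normalization whenever both
        are valid; the switch exists for sensitivity checks.
    """
    thap = np.asarray(ThAp, dtype=float)
    lwh = np.asarray(lWH, dtype=float)
    rwh = np.asarray(rWH, dtype=float)
    c = np.asarray(anteroposterior_axis, dtype=float)

    y0 = lwh - rwh
    if np.linalg.norm(y0) < 1e-12:
        raise ValueError("degenerate landmarks: lWH == rWH")
    x_skewed = (rwh + y0 / 2.0) - thap
    if np.linalg.norm(np.cross(x_skewed, y0)) < 1e-12 * np.linalg.norm(y0):
        raise ValueError("degenerate landmarks: ThAp collinear with the wing-hinge segment")
    cxy = np.cross(c, y0)
    if np.linalg.norm(cxy) < 1e-12 * np.linalg.norm(y0):
        raise ValueError("anteroposterior hint is parallel to the wing-hinge axis")
    n_r = cxy / np.linalg.norm(cxy)

    # Reflect the skewed vector across the plane with normal n_r; the average
    # of the vector and its reflection lies in the plane (the desired x).
    r = x_skewed - 2.0 * np.dot(x_skewed, n_r) * n_r
    if halve_midpoints:
        m = thap + x_skewed / 2.0
        x_dir = (m + r / 2.0) - thap
    else:
        x_dir = x_skewed + r
    x_axis = unit(x_dir, "body x-axis")

    # Re-orthogonalize y against x, keeping a positive dot with the initial
    # left-pointing hinge vector; then complete the right-handed frame.
    y_axis = unit(np.cross(np.cross(x_axis, y0), x_axis), "body y-axis")
    if np.dot(y_axis, y0) < 0:
        y_axis = -y_axis
    z_axis = np.cross(x_axis, y_axis)
    return BodyFrame(origin=thap, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)


def to_body(points: np.ndarray, frame: BodyFrame) -> np.ndarray:
    """Transform global points (mm) into body coordinates."""
    return apply_transform(frame.inverse_matrix, points)


def to_global(points: np.ndarray, frame: BodyFrame) -> np.ndarray:
    """Transform body-coordinate points (mm) back to global coordinates."""
    return apply_transform(frame.matrix, points)
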