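"""Small vector/transform helpers shared across the package.

All 3D quantities are numpy float64 arrays; homogeneous transforms are 4x4.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "norm",
    "rotation_about_axis",
    "transform_about_axis",
    "pose_matrix",
    "apply_transform",
    "assert_rotation",
    "signed_angle",
]


def norm(v: np.ndarray) -> float:
    return float(np.linalg.norm(v))


def unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    """Normalize ``v``; raise for (near) zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-300:
        raise ValueError(f"cannot normalize zero-length {name}")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis`` by ``angle`` radians."""
    a = unit(axis, "rotation axis")
    k = np.array(
        [[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def transform_about_axis(axis: np.ndarray, angle: float, anchor: np.ndarray) -> np.ndarray:
    """4x4 rotation about the line through ``anchor`` with direction ``axis``."""
    r = rotation_about_axis(axis, angle)
    t = np.eye(4)
    t[:3, :3] = r
    t[:3, 3] = np.asarray(anchor, float) - r @ np.asarray(anchor, float)
    return t


def pose_matrix(x: np.ndarray, y: np.ndarray, z: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Homogeneous pose with columns ``x, y, z`` and translation ``origin``."""
    m = np.eye(4)
    m[:3, 0] = x
    m[:3, 1] = y
    m[:3, 2] = z
    m[:3, 3] = origin
    return m


def apply_transform(m: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 transform to one point or an (n, 3) stack of points."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    out = p @ m[:3, :3].T + m[:3, 3]
    return out[0] if single else out


def assert_rotation(r: np.ndarray, tol: float = 1e-9, name: str = "rotation") -> None:
    """Validate that ``r`` is orthonormal with determinant +1."""
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3, got {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise ValueError(f"{name} is not orthonormal within {tol}")
    if abs(np.linalg.det(r) - 1.0) > tol:
        raise ValueError(f"{name} does not have determinant +1 within {tol}")


def signed_angle(v_from: np.ndarray, v_to: np.ndarray, about: np.ndarray) -> float:
    """Signed angle (radians) from ``v_from`` to ``v_to`` about unit axis ``about``.

    Both vectors are projected onto the plane perpendicular to ``about`` first.
    """
    a = unit(about, "reference axis")
    u = np.asarray(v_from, float) - np.dot(v_from, a) * a
    w = np.asarray(v_to, float) - np.dot(v_to, a) * a
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < 1e-12 or nw < 1e-12:
        raise ValueError("vector is (nearly) parallel to the rotation axis")
    return float(np.arctan2(np.dot(np.cross(u, w), a), np.dot(u, w)))
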