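"""Independent oracles used to cross-check the package implementations.

These deliberately avoid the code paths they validate: forward kinematics by
direct sequential Rodrigues rotations about reference axes, lens distortion
by a literal polynomial transcription, and sphere fitting by plain
unpenalized least squares.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def fk_sequential_oracle(chain, angles_deg: dict) -> dict:
    """Forward kinematics as a proximal-to-distal product of rotations about
    the reference-posture DOF axes (anchored at the joint centers)."""
    values = {d.name: 0.0 for d in chain.dofs}
    values.update(angles_deg)
    pts = dict(chain.joint_centers)
    pts["Tar"] = chain.tarsus_tip_ref
    kp_after = {
        "ThCx-roll": "CxTr",
        "CxTr-roll": "TrFe",
        "TrFe-roll": "FeTi",
        "FeTi-roll": "TiTar",
        "TiTar-pitch": "Tar",
    }
    rot = np.eye(3)
    trans = np.zeros(3)
    out = {"ThCx": pts["ThCx"].copy()}
    for dof in chain.dofs:
        r = rodrigues(dof.axis, np.radians(values[dof.name]))
        t = dof.center - r @ dof.center
        rot, trans = rot @ r, rot @ t + trans
        kp = kp_after.get(dof.name)
        if kp is not None:
            out[kp] = rot @ pts[kp] + trans
    return out


def distort_oracle(xn: float, yn: float, k1, k2, k3, p1, p2) -> tuple[float, float]:
    """Literal 3-radial + 2-tangential polynomial distortion."""
    r2 = xn**2 + yn**2
    radial = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn**2)
    yd = yn * radial + p1 * (r2 + 2 * yn**2) + 2 * p2 * xn * yn
    return xd, yd


def sphere_center_oracle(points: np.ndarray, radius: float, x0: np.ndarray) -> np.ndarray:
    """Unpenalized least-squares sphere-center fit at fixed radius."""
    pts = np.asarray(points, float)
    sol = least_squares(lambda c: np.linalg.norm(pts - c, axis=1) - radius, x0, method="lm")
    return sol.x


def simpson_oracle(y: np.ndarray) -> float:
    """Closed-form composite Simpson + 3/8 tail on a uniform [0, 1] grid,
    written independently from the package implementation."""
    y = np.asarray(y, float)
    n = len(y)
    h = 1.0 / (n - 1)
    if (n - 1) % 2 == 0:
        total = 0.0
        for i in range(0, n - 2, 2):
            total += h / 3 * (y[i] + 4 * y[i + 1] + y[i + 2])
        return total
    total = 0.0
    for i in range(0, n - 5, 2):
        total += h / 3 * (y[i] + 4 * y[i + 1] + y[i + 2])
    total += 3 * h / 8 * (y[n - 4] + 3 * y[n - 3] + 3 * y[n - 2] + y[n - 1])
    return total
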