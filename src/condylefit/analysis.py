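"""Derived joint-kinematics quantities.

Model error time courses (summed keypoint distance, reported in micrometres),
Simpson-rule AUC of phase-normalized series, solver-angle post-processing and
left/right mirroring, per-DOF range of motion, femur-tibia plane rotation,
and the DOF-ablation (selective angle update) experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body import BodyFrame, to_global
from .ik import TARGET_KEYPOINTS
from .model import KinematicChain, forward_kinematics

__all__ = [
    "PhaseNormalizedSeries",
    "RomSummary",
    "model_error",
    "auc_simpson",
    "mirror_angle_signs",
    "postprocess_angles",
    "rom",
    "femur_tibia_plane_rotation",
    "dof_ablation",
]

#: yaw DOFs whose solver angles are shifted by +180 degrees so that 0 means
#: fully flexed and 180 fully extended
_SHIFTED_DOFS = ("CxTr-yaw", "FeTi-yaw")


@dataclass
class PhaseNormalizedSeries:
    """Phase-normalized step series: (n_steps, 100) values plus aggregates."""

    phase: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) if len(self.values) > 1 else np.zeros(self.values.shape[1])


@dataclass
class RomSummary:
    """Per-DOF range of motion, per fly and pooled."""

    per_fly: pd.DataFrame  # columns: fly, dof, min_deg, max_deg, range_deg
    pooled: pd.DataFrame  # columns: dof, mean_range_deg, sd_range_deg, n_flies


def model_error(
    fit_positions: np.ndarray,
    tracked_positions: np.ndarray,
    body_frame: BodyFrame | None = None,
) -> np.ndarray:
    """Per-frame summed keypoint distance in micrometres.

    Both inputs are (n_frames, 5, 3) stacks, ordered CxTr, TrFe, FeTi,
    TiTar, Tar. If a body frame is given, positions are converted to global
    metric coordinates first (a rigid transform, so distances are unchanged;
    conversion is kept for interface parity). Frames with missing keypoints
    yield NaN.
    """
    fit = np.asarray(fit_positions, dtype=float)
    trk = np.asarray(tracked_positions, dtype=float)
    if fit.shape != trk.shape or fit.ndim != 3 or fit.shape[1:] != (len(TARGET_KEYPOINTS), 3):
        raise ValueError(f"expected matching (n, 5, 3) stacks, got {fit.shape} and {trk.shape}")
    if body_frame is not None:
        fit = np.stack([to_global(f, body_frame) for f in fit])
        trk = np.stack([to_global(t, body_frame) for t in trk])
    dists = np.linalg.norm(fit - trk, axis=2)
    return dists.sum(axis=1) * 1000.0


def auc_simpson(series: np.ndarray) -> float:
    """Composite Simpson integral of a uniformly sampled series on [0, 1].

    For an even number of samples (odd interval count, e.g. the 100-point
    phase grid) the final three intervals are handled with the 3/8 rule.
    Exact for cubics on the grid.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("series must be a 1-D array with at least 3 samples")
    if np.any(~np.isfinite(y)):
        raise ValueError("series contains NaN or infinite values")
    n = len(y)
    h = 1.0 / (n - 1)
    intervals = n - 1
    if intervals % 2 == 0:
        return float(h / 3.0 * (y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-2:2].sum()))
    head = y[: n - 3]  # even interval count over the first n-4 intervals
    total = 0.0
    if len(head) >= 3:
        total += h / 3.0 * (head[0] + head[-1] + 4.0 * head[1:-1:2].sum() + 2.0 * head[2:-2:2].sum())
    tail = y[n - 4 :]
    total += 3.0 * h / 8.0 * (tail[0] + 3.0 * tail[1] + 3.0 * tail[2] + tail[3])
    return float(total)


def mirror_angle_signs(angles: pd.DataFrame) -> pd.DataFrame:
    """Invert the signs of yaw and roll DOF angles (pitch untouched).

    Used to combine time courses of contralateral legs; applying it twice is
    the identity.
    """
    out = angles.copy()
    for col in out.columns:
        if "-" not in col:
            raise ValueError(f"unknown DOF column {col!r}")
        kind = col.split("-", 1)[1]
        if kind not in ("yaw", "pitch", "roll"):
            raise ValueError(f"unknown DOF column {col!r}")
        if kind in ("yaw", "roll"):
            out[col] = -out[col]
    return out


def postprocess_angles(angles: pd.DataFrame, leg: str) -> pd.DataFrame:
    """Post-process solver angles for reporting.

    ``angles`` has one column per DOF name (degrees, solver convention:
    0 = straightened posture). For left legs the signs of yaw and roll DOF
    angles are inverted (pitch untouched); then CxTr-yaw and FeTi-yaw are
    shifted by +180 degrees so 0 means fully flexed and 180 fully extended.
    """
    if not (leg.startswith("R") or leg.startswith("L")):
        raise ValueError(f"invalid leg id {leg!r}")
    for col in angles.columns:
        if "-" not in col or col.split("-", 1)[1] not in ("yaw", "pitch", "roll"):
            raise ValueError(f"unknown DOF column {col!r}")
    out = mirror_angle_signs(angles) if leg.startswith("L") else angles.copy()
    for col in _SHIFTED_DOFS:
        if col in out.columns:
            out[col] = out[col] + 180.0
    return out


def rom(angles_by_fly: dict[str, pd.DataFrame]) -> RomSummary:
    """Range of motion (max - min observed angle) per DOF, per fly and pooled.

    ``angles_by_fly`` maps fly id to a frame-by-DOF angle table in degrees.
    Pooled statistics are the mean and SD of the per-fly ranges.
    """
    if not angles_by_fly:
        raise ValueError("empty grouping: no flies given")
    rows = []
    for fly, table in angles_by_fly.items():
        if len(table) < 1:
            raise ValueError(f"fly {fly!r} has no frames")
        for dof in table.columns:
            vals = np.asarray(table[dof], dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "fly": fly,
                    "dof": dof,
                    "min_deg": float(vals.min()),
                    "max_deg": float(vals.max()),
                    "range_deg": float(vals.max() - vals.min()),
                }
            )
    per_fly = pd.DataFrame(rows)
    pooled = (
        per_fly.groupby("dof")["range_deg"]
        .agg(mean_range_deg="mean", sd_range_deg="std", n_flies="count")
        .reset_index()
    )
    return RomSummary(per_fly=per_fly, pooled=pooled)


def _plane_normals(trfe: np.ndarray, feti: np.ndarray, titar: np.ndarray) -> np.ndarray:
    femur = feti - trfe
    tibia = titar - feti
    normals = np.cross(femur, tibia)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms < 1e-9 * np.linalg.norm(femur, axis=1)):
        raise ValueError("degenerate posture: femur and tibia are (near) collinear")
    normals = normals / norms[:, None]
    # fix the normal sign by continuity to avoid spurious 180-degree jumps
    for i in range(1, len(normals)):
        if np.dot(normals[i], normals[i - 1]) < 0:
            normals[i] = -normals[i]
    return normals


def femur_tibia_plane_rotation(
    positions: np.ndarray,
    interval: tuple[int, int] | None = None,
) -> float:
    """Rotation range (degrees) of the femur-tibia plane over a step interval.

    ``positions`` is an (n_frames, 3, 3) stack of TrFe, FeTi and TiTar
    positions. The plane normal is femur x tibia; the range is the angle
    between the normals of the first and last posture of the interval.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[1:] != (3, 3):
        raise ValueError(f"positions must be (n, 3, 3), got {pos.shape}")
    if interval is not None:
        pos = pos[interval[0] : interval[1]]
    if len(pos) < 1:
        raise ValueError("empty interval")
    normals = _plane_normals(pos[:, 0], pos[:, 1], pos[:, 2])
    cosang = float(np.clip(np.dot(normals[0], normals[-1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def dof_ablation(
    chain: KinematicChain,
    full_angles: pd.DataFrame,
    active_subset: list[str],
    interval: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Selective-DOF update experiment on a fitted step interval.

    The first frame is posed with all fitted DOF angles; for the remaining
    frames only the DOFs in ``active_subset`` are updated while the others
    stay frozen at their first-frame values. Returns the femur-tibia
    plane-rotation range of the ablated trajectory and its difference to the
    full-model range (ablated minus full).
    """
    mobile = set(chain.mobile_dofs)
    unknown = [d for d in active_subset if d not in mobile]
    if unknown:
        raise ValueError(f"subset names immobile or unknown DOFs: {unknown}")
    table = full_angles if interval is None else full_angles.iloc[interval[0] : interval[1]]
    if len(table) < 1:
        raise ValueError("empty interval")

    def positions(angles_rows: pd.DataFrame) -> np.ndarray:
        out = []
        for _, row in angles_rows.iterrows():
            pos = forward_kinematics(chain, row.to_dict())
            out.append(np.vstack([pos["TrFe"], pos["FeTi"], pos["TiTar"]]))
        return np.stack(out)

    full_pos = positions(table)
    full_range = femur_tibia_plane_rotation(full_pos)

    frozen = table.iloc[0]
    ablated = table.copy()
    for col in ablated.columns:
        if col not in active_subset:
            ablated[col] = frozen[col]
    ablated.iloc[0] = table.iloc[0]
    ablated_range = femur_tibia_plane_rotation(positions(ablated))
    return ablated_range, ablated_range - full_range
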