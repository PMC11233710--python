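"""Constrained inverse-kinematic fitting of leg chains to tracked postures.

Each frame is fitted by bounded, weighted nonlinear least squares
(trust-region reflective): the cost is the sum over the CxTr, TrFe, FeTi,
TiTar and Tar keypoints of the squared weighted Euclidean distance between
the model and the tracked position. Termination uses 1e-3 for the relative
cost change, the step norm and the gradient norm, and at most 100 iterations
per mobile DOF. The first frame of a sequence is initialized by optimizing
each joint in isolation, proximal to distal; subsequent frames are
warm-started from the previous solution.

Weights multiply the residual distances before squaring. The default
keypoint weights are 1; the front and middle legs up-weight TrFe/FeTi/TiTar
to (1.5, 2.0, 1.5) and (1.25, 1.5, 1.25) respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import leg_pair
from .model import KinematicChain, forward_kinematics, set_tarsus_length

__all__ = [
    "TARGET_KEYPOINTS",
    "JointAngleFrame",
    "FrameFit",
    "FitResult",
    "default_weights",
    "fit_frame",
    "init_angles_per_joint",
    "fit_sequence",
]

#: keypoints entering the cost function, in order
TARGET_KEYPOINTS = ("CxTr", "TrFe", "FeTi", "TiTar", "Tar")

#: keypoint most directly moved by each joint (used for isolated initialization)
_JOINT_TARGET = {"ThCx": "CxTr", "CxTr": "TrFe", "TrFe": "FeTi", "FeTi": "TiTar", "TiTar": "Tar"}

_PAIR_WEIGHTS = {
    "front": (1.0, 1.5, 2.0, 1.5, 1.0),
    "middle": (1.0, 1.25, 1.5, 1.25, 1.0),
    "hind": (1.0, 1.0, 1.0, 1.0, 1.0),
}


@dataclass
class JointAngleFrame:
    """Per-frame DOF angles in degrees (mobile DOFs only)."""

    angles: dict[str, float]
    frame: int = 0


@dataclass
class FrameFit:
    """Fit outcome for a single frame."""

    frame: int
    angles: JointAngleFrame
    residuals_um: dict[str, float]
    error_um: float
    cost: float  # 0.5 * sum of squared weighted residuals, micrometre scale
    iterations: int
    converged: bool
    valid: bool = True
    active_bounds: dict[str, str] = field(default_factory=dict)  # dof -> "lower"/"upper"
    tarsus_length_mm: float = float("nan")


@dataclass
class FitResult:
    """Fit outcomes for a sequence of frames."""

    leg: str
    frames: list[FrameFit]

    @property
    def angles_deg(self) -> np.ndarray:
        """(n_frames, n_mobile) array of fitted angles; NaN for invalid frames."""
        names = self.dof_names
        out = np.full((len(self.frames), len(names)), np.nan)
        for i, f in enumerate(self.frames):
            if f.valid:
                out[i] = [f.angles.angles[n] for n in names]
        return out

    @property
    def dof_names(self) -> list[str]:
        for f in self.frames:
            if f.valid:
                return list(f.angles.angles)
        raise ValueError("no valid frames in fit result")

    @property
    def errors_um(self) -> np.ndarray:
        return np.array([f.error_um if f.valid else np.nan for f in self.frames])


def default_weights(leg: str) -> np.ndarray:
    """Per-keypoint fit weights for a leg (order: CxTr, TrFe, FeTi, TiTar, Tar)."""
    return np.array(_PAIR_WEIGHTS[leg_pair(leg)])


def _prepare(chain: KinematicChain, weights, bounds_deg):
    names = chain.mobile_dofs
    if not names:
        raise ValueError("chain has no mobile DOFs to fit")
    if bounds_deg is None:
        bounds_deg = chain.bounds_deg_array(names)
    bounds_rad = np.radians(np.asarray(bounds_deg, dtype=float))
    w = np.ones(len(TARGET_KEYPOINTS)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(TARGET_KEYPOINTS),):
        raise ValueError(f"weights must have length {len(TARGET_KEYPOINTS)}")
    return names, bounds_rad, w


def _clip_interior(x: np.ndarray, bounds_rad: np.ndarray) -> np.ndarray:
    """Clip a start strictly inside the box; starts exactly on a bound stall
    the trust-region scaled-gradient test."""
    eps = np.minimum(1e-3, 0.01 * (bounds_rad[:, 1] - bounds_rad[:, 0]))
    return np.clip(x, bounds_rad[:, 0] + eps, bounds_rad[:, 1] - eps)


_FD_STEP_RAD = 1e-6


def _make_fd_jacobian(fun):
    """Forward finite differences with a fixed absolute step of 1e-6 rad.

    A relative step (scipy's ``diff_step``) collapses for angles near zero,
    freezing those DOFs; an absolute step keeps every column informative.
    """

    def jac(x, *args):
        f0 = fun(x)
        cols = []
        for i in range(len(x)):
            xi = x.copy()
            xi[i] += _FD_STEP_RAD
            cols.append((fun(xi) - f0) / _FD_STEP_RAD)
        return np.column_stack(cols)

    return jac


def _residuals(chain: KinematicChain, x_rad: np.ndarray, targets: np.ndarray, w: np.ndarray) -> np.ndarray:
    # residuals in micrometres so the 1e-3 termination thresholds are
    # meaningful at the scale the error metrics are reported in
    pos = forward_kinematics(chain, np.degrees(x_rad))
    diffs = np.vstack([pos[k] for k in TARGET_KEYPOINTS]) - targets
    return (diffs * w[:, None]).ravel() * 1000.0


def _frame_fit_from_solution(chain, names, x_rad, targets, bounds_rad, result, frame_idx) -> FrameFit:
    pos = forward_kinematics(chain, np.degrees(x_rad))
    dists_um = {
        k: float(np.linalg.norm(pos[k] - targets[i]) * 1000.0)
        for i, k in enumerate(TARGET_KEYPOINTS)
    }
    # the solver keeps iterates strictly feasible, so "active" means within
    # the termination resolution (xtol-scale) of a bound
    active = {}
    for n, xi, (lo, hi) in zip(names, x_rad, bounds_rad):
        if xi - lo < 1e-3:
            active[n] = "lower"
        elif hi - xi < 1e-3:
            active[n] = "upper"
    return FrameFit(
        frame=frame_idx,
        angles=JointAngleFrame(
            angles={n: float(np.degrees(a)) for n, a in zip(names, x_rad)}, frame=frame_idx
        ),
        residuals_um=dists_um,
        error_um=float(sum(dists_um.values())),
        cost=float(result.cost) if result is not None else float("nan"),
        iterations=int(result.nfev) if result is not None else 0,
        converged=bool(result.status > 0) if result is not None else False,
        active_bounds=active,
        tarsus_length_mm=chain.tarsus_length,
    )


def fit_frame(
    chain: KinematicChain,
    targets: np.ndarray,
    init: JointAngleFrame | dict | np.ndarray | None = None,
    weights: np.ndarray | None = None,
    bounds_deg: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter_per_dof: int = 100,
    frame_idx: int = 0,
) -> FrameFit:
    """Fit the chain's mobile DOF angles to one frame of 5 target keypoints.

    ``targets`` is a (5, 3) array in body coordinates (mm), ordered CxTr,
    TrFe, FeTi, TiTar, Tar. Frames containing NaN targets are flagged
    invalid and not fitted.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (len(TARGET_KEYPOINTS), 3):
        raise ValueError(f"targets must be (5, 3), got {targets.shape}")
    names, bounds_rad, w = _prepare(chain, weights, bounds_deg)
    if np.any(~np.isfinite(targets)):
        return FrameFit(
            frame=frame_idx,
            angles=JointAngleFrame({n: float("nan") for n in names}, frame_idx),
            residuals_um={k: float("nan") for k in TARGET_KEYPOINTS},
            error_um=float("nan"),
            cost=float("nan"),
            iterations=0,
            converged=False,
            valid=False,
        )
    if init is None:
        x0 = np.zeros(len(names))
    elif isinstance(init, JointAngleFrame):
        x0 = np.radians([init.angles[n] for n in names])
    elif isinstance(init, dict):
        x0 = np.radians([init.get(n, 0.0) for n in names])
    else:
        x0 = np.radians(np.asarray(init, dtype=float))
    x0 = _clip_interior(x0, bounds_rad)

    fun = lambda x: _residuals(chain, x, targets, w)  # noqa: E731
    result = least_squares(
        fun,
        x0,
        jac=_make_fd_jacobian(fun),
        bounds=(bounds_rad[:, 0], bounds_rad[:, 1]),
        method="trf",
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter_per_dof * len(names),
    )
    return _frame_fit_from_solution(chain, names, result.x, targets, bounds_rad, result, frame_idx)


def init_angles_per_joint(
    chain: KinematicChain,
    targets: np.ndarray,
    bounds_deg: np.ndarray | None = None,
    tol: float = 1e-3,
) -> JointAngleFrame:
    """Estimate starting angles by optimizing each joint in isolation.

    Proceeding proximal to distal, each joint's mobile DOF angles are fitted
    against the keypoint the joint moves most directly (its distal
    neighbour), with all other joints held at their current values.
    """
    targets = np.asarray(targets, dtype=float)
    names, bounds_rad, _ = _prepare(chain, None, bounds_deg)
    current = np.zeros(len(names))
    target_by_kp = dict(zip(TARGET_KEYPOINTS, targets))
    for joint in ("ThCx", "CxTr", "TrFe", "FeTi", "TiTar"):
        idx = [i for i, n in enumerate(names) if n.startswith(joint + "-")]
        if not idx:
            continue
        kp = _JOINT_TARGET[joint]
        goal = target_by_kp[kp]

        def res(sub):
            x = current.copy()
            x[idx] = sub
            pos = forward_kinematics(chain, np.degrees(x))
            return (pos[kp] - goal) * 1000.0

        sub0 = _clip_interior(current[idx], bounds_rad[idx])
        sol = least_squares(
            res,
            sub0,
            jac=_make_fd_jacobian(res),
            bounds=(bounds_rad[idx, 0], bounds_rad[idx, 1]),
            method="trf",
            ftol=tol,
            xtol=tol,
            gtol=tol,
            max_nfev=100 * len(idx),
        )
        current[idx] = sol.x
    current = np.clip(current, bounds_rad[:, 0], bounds_rad[:, 1])
    return JointAngleFrame({n: float(np.degrees(a)) for n, a in zip(names, current)}, frame=0)


def fit_sequence(
    chain: KinematicChain,
    target_frames: np.ndarray,
    weights: np.ndarray | None = None,
    bounds_deg: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter_per_dof: int = 100,
    update_tarsus: bool = True,
) -> FitResult:
    """Fit a sequence of (n_frames, 5, 3) target postures frame by frame.

    The tarsus length is set per frame from the tracked TiTar-to-Tar
    distance before fitting. Invalid (NaN) frames are skipped with the warm
    start carried across the gap.
    """
    target_frames = np.asarray(target_frames, dtype=float)
    if target_frames.ndim != 3 or target_frames.shape[1:] != (5, 3):
        raise ValueError(f"target_frames must be (n, 5, 3), got {target_frames.shape}")
    if len(target_frames) == 0:
        raise ValueError("empty target sequence")
    if np.all(~np.isfinite(target_frames.reshape(len(target_frames), -1)).all(axis=1)):
        raise ValueError("all frames in the sequence are invalid (contain NaNs)")
    if weights is None:
        weights = default_weights(chain.leg)

    fits: list[FrameFit] = []
    warm: JointAngleFrame | None = None
    for i, targets in enumerate(target_frames):
        if np.any(~np.isfinite(targets)):
            fit = fit_frame(chain, targets, warm, weights, bounds_deg, tol, max_iter_per_dof, i)
            fits.append(fit)
            continue
        if update_tarsus:
            tarsus = float(np.linalg.norm(targets[4] - targets[3]))
            set_tarsus_length(chain, tarsus)
        init = warm if warm is not None else init_angles_per_joint(chain, targets, bounds_deg, tol)
        fit = fit_frame(chain, targets, init, weights, bounds_deg, tol, max_iter_per_dof, i)
        fits.append(fit)
        warm = fit.angles
    return FitResult(leg=chain.leg, frames=fits)
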