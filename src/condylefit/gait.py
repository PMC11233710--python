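"""Treadmill-ball estimation and swing/stance segmentation.

During stance the distance between a tarsus tip and the treadmill-ball
center equals the ball radius (3 mm); lifted legs are farther away. The
ball center is fitted by penalized least squares (tips inside the sphere are
penalized 100-fold), and per-frame phase labels follow from thresholding the
tip-to-center distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

__all__ = [
    "DEFAULT_BALL_RADIUS_MM",
    "StepPhases",
    "estimate_ball_center",
    "detect_phases",
    "phase_intervals",
    "normalize_phase",
]

DEFAULT_BALL_RADIUS_MM = 3.0
INSIDE_PENALTY = 100.0


@dataclass
class StepPhases:
    """Per-leg swing/stance labels and lift-off/touchdown events."""

    ball_center: np.ndarray
    ball_radius: float
    thresholds: dict[str, float]
    labels: dict[str, np.ndarray]  # leg -> bool array, True = stance
    liftoffs: dict[str, np.ndarray] = field(default_factory=dict)
    touchdowns: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def legs(self) -> list[str]:
        return list(self.labels)


def _penalized_residuals(center: np.ndarray, points: np.ndarray, radius: float) -> np.ndarray:
    d = np.linalg.norm(points - center, axis=1)
    w = np.where(d < radius, INSIDE_PENALTY, 1.0)
    return np.sqrt(w) * (d - radius)


def estimate_ball_center(
    tarsus_tips: np.ndarray,
    radius: float = DEFAULT_BALL_RADIUS_MM,
    down: np.ndarray = (0.0, 0.0, -1.0),
) -> np.ndarray:
    """Fit the ball center to tarsus-tip positions of all legs and frames.

    Minimizes ``sum_i w_i (||p_i - c|| - radius)^2`` with ``w_i = 100`` for
    tips inside the sphere and 1 otherwise, keeping tips outside the fitted
    ball. ``tarsus_tips`` is an (n, 3) stack (mm). Multi-start from the tip
    centroid displaced by one radius along ``down`` and from the centroid.
    """
    pts = np.asarray(tarsus_tips, dtype=float).reshape(-1, 3)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < 4:
        raise ValueError("need at least 4 finite tarsus-tip points to fit the ball")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise ValueError("tarsus tips are (near) coplanar; ball center is unidentifiable")
    centroid = pts.mean(axis=0)
    starts = [centroid + radius * np.asarray(down, float), centroid]
    best = None
    for x0 in starts:
        sol = least_squares(_penalized_residuals, x0, args=(pts, radius), method="trf")
        cost = float(np.sum(_penalized_residuals(sol.x, pts, radius) ** 2))
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    # polish with a derivative-free step in case the penalty kink stalled trf
    nm = minimize(
        lambda c: float(np.sum(_penalized_residuals(c, pts, radius) ** 2)),
        best[1],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    if nm.fun < best[0]:
        return np.asarray(nm.x, dtype=float)
    return np.asarray(best[1], dtype=float)


def _events(stance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(stance.astype(int)))
    touchdowns = change[stance[change + 1]] + 1  # swing -> stance
    liftoffs = change[~stance[change + 1]] + 1  # stance -> swing
    return liftoffs, touchdowns


def _debounce(stance: np.ndarray, min_frames: int) -> np.ndarray:
    if min_frames <= 1:
        return stance
    out = stance.copy()
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        # flip interior runs shorter than the minimum duration
        if j - i < min_frames and i > 0 and j < n:
            out[i:j] = out[i - 1]
        i = j
    return out


def detect_phases(
    tarsus_tips: dict[str, np.ndarray],
    center: np.ndarray,
    radius: float = DEFAULT_BALL_RADIUS_MM,
    thresholds: dict[str, float] | float | None = None,
    min_phase_frames: int = 0,
) -> StepPhases:
    """Classify each frame of each leg as swing or stance.

    ``tarsus_tips`` maps leg id to an (n_frames, 3) trajectory. A frame is
    stance iff the tip-to-center distance is <= the leg's threshold
    (default: radius + 0.05 mm). ``min_phase_frames`` > 1 enables label
    debouncing of short interior runs.
    """
    center = np.asarray(center, dtype=float)
    default_thr = radius + 0.05
    if thresholds is None:
        thr = {leg: default_thr for leg in tarsus_tips}
    elif np.isscalar(thresholds):
        thr = {leg: float(thresholds) for leg in tarsus_tips}
    else:
        thr = {leg: float(thresholds.get(leg, default_thr)) for leg in tarsus_tips}
    for leg, t in thr.items():
        if t < radius:
            raise ValueError(f"threshold for {leg} ({t}) must be >= the ball radius ({radius})")
    labels, liftoffs, touchdowns = {}, {}, {}
    for leg, tips in tarsus_tips.items():
        tips = np.asarray(tips, dtype=float)
        d = np.linalg.norm(tips - center, axis=1)
        stance = d <= thr[leg]
        stance = _debounce(stance, min_phase_frames)
        labels[leg] = stance
        liftoffs[leg], touchdowns[leg] = _events(stance)
    return StepPhases(
        ball_center=center,
        ball_radius=float(radius),
        thresholds=thr,
        labels=labels,
        liftoffs=liftoffs,
        touchdowns=touchdowns,
    )


def phase_intervals(phases: StepPhases, leg: str, complete_only: bool = True):
    """List ``(phase_name, start, stop)`` runs for a leg (stop exclusive).

    With ``complete_only`` the runs touching the sequence boundaries are
    dropped, leaving only intervals bounded by events on both sides.
    """
    stance = phases.labels[leg]
    n = len(stance)
    edges = np.flatnonzero(np.diff(stance.astype(int))) + 1
    bounds = np.concatenate([[0], edges, [n]])
    runs = [
        ("stance" if stance[a] else "swing", int(a), int(b))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    if complete_only:
        runs = [r for r in runs if r[1] != 0 and r[2] != n]
    return runs


def normalize_phase(
    series: np.ndarray,
    phases: StepPhases,
    leg: str,
    n_samples: int = 100,
) -> dict[str, np.ndarray]:
    """Resample a per-frame series onto ``n_samples`` per step-phase interval.

    Each complete swing and stance interval is linearly interpolated onto a
    normalized time base of 0 to 1; incomplete boundary intervals are
    dropped. Returns ``{"swing": (n_steps, n_samples), "stance": ...}``
    (empty arrays when no complete interval exists).
    """
    series = np.asarray(series, dtype=float)
    out: dict[str, list[np.ndarray]] = {"swing": [], "stance": []}
    for name, a, b in phase_intervals(phases, leg, complete_only=True):
        if b - a < 2:
            warnings.warn(
                f"dropping {name} interval [{a}, {b}) of leg {leg}: fewer than 2 frames",
                stacklevel=2,
            )
            continue
        seg = series[a:b]
        xi = np.linspace(0.0, b - a - 1.0, n_samples)
        out[name].append(np.interp(xi, np.arange(b - a, dtype=float), seg))
    return {
        k: (np.vstack(v) if v else np.empty((0, n_samples)))
        for k, v in out.items()
    }
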