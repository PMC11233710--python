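"""Condyle-based kinematic leg chains with Denavit-Hartenberg forward kinematics.

A leg is a serial chain of five joints (ThCx, CxTr, TrFe, FeTi, TiTar) joined
by rigid segments, ending at the tarsus tip (Tar). Every joint carries a yaw
DOF about its condyle-to-condyle axis, a roll DOF about the leg segment it
controls, and a pitch DOF about their cross product; the TiTar joint has no
roll DOF. Each DOF can be mobile or fixed; fixed DOFs are held at the
straightened reference posture (angle zero).

All chain geometry lives in body coordinates (mm); angles are degrees at the
public interface and radians internally.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from ._geometry import (
    apply_transform,
    assert_rotation,
    pose_matrix,
    rotation_about_axis,
    signed_angle,
    transform_about_axis,
    unit,
)
from .body import BodyFrame, compute_body_frame, to_body

__all__ = [
    "JOINTS",
    "KEYPOINTS",
    "SEGMENTS",
    "DOF_NAMES",
    "JointLandmarks",
    "LegLandmarks",
    "CondyleLandmarkSet",
    "DOFSpec",
    "KinematicChain",
    "build_chain",
    "straighten_initial_posture",
    "build_dh",
    "forward_kinematics",
    "scale_to_fly",
    "set_tarsus_length",
    "orthogonalize",
    "mirror_leg_landmarks",
    "dh_matrix",
]

JOINTS = ("ThCx", "CxTr", "TrFe", "FeTi", "TiTar")
KEYPOINTS = ("ThCx", "CxTr", "TrFe", "FeTi", "TiTar", "Tar")
#: segment name -> (proximal keypoint, distal keypoint)
SEGMENTS = {
    "coxa": ("ThCx", "CxTr"),
    "trochanter": ("CxTr", "TrFe"),
    "femur": ("TrFe", "FeTi"),
    "tibia": ("FeTi", "TiTar"),
    "tarsus": ("TiTar", "Tar"),
}
_JOINT_KINDS = {j: ("yaw", "pitch", "roll") if j != "TiTar" else ("yaw", "pitch") for j in JOINTS}
DOF_NAMES = tuple(f"{j}-{k}" for j in JOINTS for k in _JOINT_KINDS[j])
#: keypoint -> index of the chain frame the keypoint is rigidly attached to
_KEYPOINT_FRAME = {"CxTr": 3, "TrFe": 6, "FeTi": 9, "TiTar": 12, "Tar": 14}
#: segment whose direction defines each joint's roll axis
_ROLL_SEGMENT = {"ThCx": "coxa", "CxTr": "trochanter", "TrFe": "femur", "FeTi": "tibia", "TiTar": "tarsus"}


# ---------------------------------------------------------------------------
# landmark containers
# ---------------------------------------------------------------------------


@dataclass
class JointLandmarks:
    """Two condyle positions and the joint center, in one coordinate frame."""

    condyle_a: np.ndarray
    condyle_b: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.condyle_a = np.asarray(self.condyle_a, dtype=float)
        self.condyle_b = np.asarray(self.condyle_b, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if np.linalg.norm(self.condyle_b - self.condyle_a) < 1e-12:
            raise ValueError("joint condyles coincide")


@dataclass
class LegLandmarks:
    """Per-leg joint landmarks plus the tarsus tip."""

    joints: dict[str, JointLandmarks]
    tarsus_tip: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        self.tarsus_tip = np.asarray(self.tarsus_tip, dtype=float)
        missing = [j for j in JOINTS if j not in self.joints]
        if missing:
            raise ValueError(f"missing joint landmarks: {missing}")
        centers = [self.joints[j].center for j in JOINTS] + [self.tarsus_tip]
        for i in range(len(centers) - 1):
            if np.linalg.norm(centers[i + 1] - centers[i]) < 1e-12:
                raise ValueError("consecutive joint centers coincide")


@dataclass
class CondyleLandmarkSet:
    """Landmarks for all six legs plus the body reference keypoints."""

    legs: dict[str, LegLandmarks]
    ThAp: np.ndarray
    lWH: np.ndarray
    rWH: np.ndarray

    def __post_init__(self) -> None:
        self.ThAp = np.asarray(self.ThAp, dtype=float)
        self.lWH = np.asarray(self.lWH, dtype=float)
        self.rWH = np.asarray(self.rWH, dtype=float)

    def body_frame(self, anteroposterior_axis=(1.0, 0.0, 0.0)) -> BodyFrame:
        return compute_body_frame(self.ThAp, self.lWH, self.rWH, anteroposterior_axis)


def mirror_leg_landmarks(landmarks: CondyleLandmarkSet, leg: str) -> LegLandmarks:
    """Reflect a leg's landmarks across the body sagittal plane.

    Returns the contralateral leg's landmark set (global coordinates). The
    condyle labels are kept as stored, so yaw-angle signs of mirrored legs
    follow the documented sign convention.
    """
    frame = landmarks.body_frame()
    src = landmarks.legs[leg]

    def refl(p: np.ndarray) -> np.ndarray:
        b = to_body(p, frame)
        b = np.array([b[0], -b[1], b[2]])
        return apply_transform(frame.matrix, b)

    joints = {
        j: JointLandmarks(refl(jl.condyle_a), refl(jl.condyle_b), refl(jl.center))
        for j, jl in src.joints.items()
    }
    side = "left" if src.side == "right" else "right"
    return LegLandmarks(joints=joints, tarsus_tip=refl(src.tarsus_tip), side=side)


# ---------------------------------------------------------------------------
# chain types
# ---------------------------------------------------------------------------


@dataclass
class DOFSpec:
    """One rotational degree of freedom of a joint."""

    name: str
    joint: str
    kind: str  # yaw | pitch | roll
    axis: np.ndarray  # unit vector, body coordinates
    center: np.ndarray  # anchor point of the rotation axis
    mobile: bool = False
    bounds_deg: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError(f"DOF {self.name}: axis must be unit length")
        if self.mobile and self.bounds_deg is None:
            raise ValueError(f"mobile DOF {self.name} requires angle bounds")
        if self.bounds_deg is not None and not self.bounds_deg[0] < self.bounds_deg[1]:
            raise ValueError(f"DOF {self.name}: bounds min must be < max")


@dataclass
class KinematicChain:
    """A single leg's kinematic chain in body coordinates.

    ``frames_ref`` holds the 15 reference local coordinate systems (one per
    DOF plus the end effector) as 4x4 poses; ``link_ref[i]`` maps frame
    ``i+1`` coordinates into frame ``i`` at the reference posture, and
    ``dh_params[i]`` stores the equivalent ``(theta0, alpha, d, r)`` when the
    link is expressible in the four standard parameters (the end-effector
    link with its duplicated frame generally is not).
    """

    leg: str
    side: str
    landmarks: LegLandmarks  # reference (straightened) landmarks, body coords
    dofs: list[DOFSpec]
    tarsus_length: float
    straightened: bool = False
    yaw_adjustments_deg: dict[str, float] = field(default_factory=dict)
    body_x_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    # body landmarks of the source landmark set, in body coordinates
    model_rWH: np.ndarray = field(default_factory=lambda: np.zeros(3))
    model_lWH: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # populated by build_dh / _finalize
    frames_ref: list[np.ndarray] = field(default_factory=list, repr=False)
    link_ref: list[np.ndarray] = field(default_factory=list, repr=False)
    dh_params: list[tuple[float, float, float, float] | None] = field(default_factory=list, repr=False)
    keypoint_local: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    # -- convenience views --------------------------------------------------
    @property
    def dof_names(self) -> list[str]:
        return [d.name for d in self.dofs]

    @property
    def mobile_dofs(self) -> list[str]:
        return [d.name for d in self.dofs if d.mobile]

    @property
    def joint_centers(self) -> dict[str, np.ndarray]:
        return {j: self.landmarks.joints[j].center for j in JOINTS}

    @property
    def tarsus_tip_ref(self) -> np.ndarray:
        centers = self.joint_centers
        direction = unit(self.landmarks.tarsus_tip - centers["TiTar"], "tarsus direction")
        return centers["TiTar"] + self.tarsus_length * direction

    @property
    def segment_lengths(self) -> dict[str, float]:
        pts = dict(self.joint_centers)
        pts["Tar"] = self.tarsus_tip_ref
        return {
            seg: float(np.linalg.norm(pts[b] - pts[a]))
            for seg, (a, b) in SEGMENTS.items()
        }

    @property
    def scale(self) -> float:
        """Characteristic chain scale: summed reference segment lengths."""
        return float(sum(self.segment_lengths.values()))

    @property
    def base_transform(self) -> np.ndarray:
        """``B_ThCx``: pose of the first DOF's LCS in body coordinates."""
        if not self.frames_ref:
            raise RuntimeError("chain has no frames; call build_dh first")
        return self.frames_ref[0]

    def dof(self, name: str) -> DOFSpec:
        for d in self.dofs:
            if d.name == name:
                return d
        raise KeyError(f"unknown DOF {name!r}; valid names: {DOF_NAMES}")

    def bounds_deg_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.mobile_dofs
        return np.array([self.dof(n).bounds_deg for n in names], dtype=float)

    def with_mobility(self, mobility: dict[str, bool]) -> "KinematicChain":
        """Return a copy with some DOFs' mobility flags replaced."""
        chain = copy.deepcopy(self)
        for name, flag in mobility.items():
            d = chain.dof(name)
            if flag and d.bounds_deg is None:
                raise ValueError(f"cannot mobilize DOF {name} without bounds")
            d.mobile = bool(flag)
        return chain


# ---------------------------------------------------------------------------
# axis construction
# ---------------------------------------------------------------------------


def _segment_direction(leg: LegLandmarks, joint: str, tarsus_length: float | None = None) -> np.ndarray:
    seg = _ROLL_SEGMENT[joint]
    a, b = SEGMENTS[seg]
    start = leg.joints[a].center
    end = leg.tarsus_tip if b == "Tar" else leg.joints[b].center
    return unit(end - start, f"{seg} segment")


def _make_dofs(leg_landmarks: LegLandmarks, leg: str) -> list[DOFSpec]:
    dofs: list[DOFSpec] = []
    for joint in JOINTS:
        jl = leg_landmarks.joints[joint]
        yaw_axis = unit(jl.condyle_b - jl.condyle_a, f"{joint} condyle axis")
        roll_axis = _segment_direction(leg_landmarks, joint)
        cr = np.cross(yaw_axis, roll_axis)
        if np.linalg.norm(cr) < 1e-6:
            raise ValueError(
                f"{leg}/{joint}: yaw axis is (near) parallel to the controlled segment"
            )
        pitch_axis = unit(cr, f"{joint} pitch axis")
        axes = {"yaw": yaw_axis, "pitch": pitch_axis, "roll": roll_axis}
        for kind in _JOINT_KINDS[joint]:
            dofs.append(
                DOFSpec(
                    name=f"{joint}-{kind}",
                    joint=joint,
                    kind=kind,
                    axis=axes[kind],
                    center=jl.center.copy(),
                )
            )
    return dofs


def _apply_dof_config(dofs: list[DOFSpec], dof_config: dict | None) -> None:
    if dof_config is None:
        return
    valid = set(DOF_NAMES)
    for name, entry in dof_config.items():
        if name not in valid:
            raise ValueError(f"unknown DOF {name!r} in config; valid names: {sorted(valid)}")
        spec = next(d for d in dofs if d.name == name)
        if isinstance(entry, dict):
            if "bounds" in entry and entry["bounds"] is not None:
                spec.bounds_deg = (float(entry["bounds"][0]), float(entry["bounds"][1]))
            spec.mobile = bool(entry.get("mobile", spec.mobile))
        else:
            spec.mobile = bool(entry)
        if spec.mobile and spec.bounds_deg is None:
            raise ValueError(f"mobile DOF {name} requires bounds in the config")


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------


def build_chain(
    landmarks: CondyleLandmarkSet,
    leg: str,
    dof_config: dict | None = None,
    anteroposterior_axis=(1.0, 0.0, 0.0),
) -> KinematicChain:
    """Build a leg's kinematic chain from condyle landmarks.

    Landmarks are transformed into the body coordinate system derived from
    the set's ThAp/lWH/rWH. Yaw axes follow ``condyle_b - condyle_a``; roll
    axes follow the controlled segment; pitch = yaw x roll. The returned
    chain is not yet straightened; the raw scan posture is its reference.
    """
    if leg not in landmarks.legs:
        raise ValueError(f"landmark set has no leg {leg!r}; available: {sorted(landmarks.legs)}")
    frame = landmarks.body_frame(anteroposterior_axis)
    src = landmarks.legs[leg]
    joints = {
        j: JointLandmarks(
            to_body(jl.condyle_a, frame), to_body(jl.condyle_b, frame), to_body(jl.center, frame)
        )
        for j, jl in src.joints.items()
    }
    leg_body = LegLandmarks(joints=joints, tarsus_tip=to_body(src.tarsus_tip, frame), side=src.side)
    tarsus_length = float(
        np.linalg.norm(leg_body.tarsus_tip - leg_body.joints["TiTar"].center)
    )
    dofs = _make_dofs(leg_body, leg)
    _apply_dof_config(dofs, dof_config)
    chain = KinematicChain(
        leg=leg,
        side=src.side,
        landmarks=leg_body,
        dofs=dofs,
        tarsus_length=tarsus_length,
        model_rWH=to_body(landmarks.rWH, frame),
        model_lWH=to_body(landmarks.lWH, frame),
    )
    return build_dh(chain)


def _rebuild(chain: KinematicChain, leg_landmarks: LegLandmarks, **updates) -> KinematicChain:
    """Re-derive DOF axes and frames after the reference landmarks changed."""
    dofs = _make_dofs(leg_landmarks, chain.leg)
    for old, new in zip(chain.dofs, dofs):
        new.mobile = old.mobile
        new.bounds_deg = old.bounds_deg
    tarsus_length = float(
        np.linalg.norm(leg_landmarks.tarsus_tip - leg_landmarks.joints["TiTar"].center)
    )
    out = replace(
        chain,
        landmarks=leg_landmarks,
        dofs=dofs,
        tarsus_length=tarsus_length,
        frames_ref=[],
        link_ref=[],
        dh_params=[],
        keypoint_local={},
        **updates,
    )
    return build_dh(out)


def straighten_initial_posture(chain: KinematicChain) -> KinematicChain:
    """Extend the leg by adjusting yaw-DOF angles only.

    Proceeding proximal to distal, the geometry distal to each joint is
    rotated about the joint's yaw axis so that the outgoing segment is as
    collinear as possible with the incoming one (the component of the bend
    perpendicular to the yaw axis is removed exactly, in closed form). The
    resulting condyle positions become the new reference; thereafter
    all-zero angles denote this extended posture.
    """
    leg = copy.deepcopy(chain.landmarks)
    adjustments: dict[str, float] = {}
    order = [("CxTr", "ThCx", "TrFe"), ("TrFe", "CxTr", "FeTi"), ("FeTi", "TrFe", "TiTar"), ("TiTar", "FeTi", "Tar")]
    for joint, prev, nxt in order:
        jl = leg.joints[joint]
        axis = unit(jl.condyle_b - jl.condyle_a, f"{joint} yaw axis")
        u = jl.center - leg.joints[prev].center
        v = (leg.tarsus_tip if nxt == "Tar" else leg.joints[nxt].center) - jl.center
        try:
            phi = signed_angle(v, u, axis)
        except ValueError as err:
            raise ValueError(
                f"cannot straighten at {joint}: yaw axis parallel to both segments"
            ) from err
        t = transform_about_axis(axis, phi, jl.center)
        distal = JOINTS[JOINTS.index(joint) + 1 :]
        for dj in distal:
            d = leg.joints[dj]
            d.condyle_a = apply_transform(t, d.condyle_a)
            d.condyle_b = apply_transform(t, d.condyle_b)
            d.center = apply_transform(t, d.center)
        leg.tarsus_tip = apply_transform(t, leg.tarsus_tip)
        adjustments[f"{joint}-yaw"] = float(np.degrees(phi))
    return _rebuild(chain, leg, straightened=True, yaw_adjustments_deg=adjustments)


# ---------------------------------------------------------------------------
# Denavit-Hartenberg construction
# ---------------------------------------------------------------------------


def dh_matrix(theta: float, alpha: float, d: float, r: float) -> np.ndarray:
    """Standard D-H transform ``Rz(theta) Tz(d) Tx(r) Rx(alpha)``."""
    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(alpha), np.sin(alpha)
    return np.array(
        [
            [ct, -st * ca, st * sa, r * ct],
            [st, ct * ca, -ct * sa, r * st],
            [0.0, sa, ca, d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def _line_closest_points(p1, z1, p2, z2) -> tuple[np.ndarray, np.ndarray]:
    """Closest points between two (non-parallel) lines ``p + t z``."""
    w0 = p1 - p2
    a = np.dot(z1, z1)
    b = np.dot(z1, z2)
    c = np.dot(z2, z2)
    d = np.dot(z1, w0)
    e = np.dot(z2, w0)
    den = a * c - b * b
    s = (b * e - c * d) / den
    t = (a * e - b * d) / den
    return p1 + s * z1, p2 + t * z2


def _next_frame(origin_n, x_n, z_n, dof_next: DOFSpec, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Origin and x-axis of the next LCS per the three D-H cases."""
    z_next = dof_next.axis
    c_next = dof_next.center
    cr = np.cross(z_n, z_next)
    if np.linalg.norm(cr) < 1e-9:
        # case (c): parallel axes; common normal through the DOF's joint center
        foot = origin_n + np.dot(c_next - origin_n, z_n) * z_n
        offset = c_next - foot
        if np.linalg.norm(offset) < 1e-9 * scale:
            return c_next, x_n  # coincident axes: carry the x-axis over
        return c_next, unit(offset)
    p_on_zn, p_on_znext = _line_closest_points(origin_n, z_n, c_next, z_next)
    if np.linalg.norm(p_on_znext - p_on_zn) < 1e-9 * scale:
        # case (b): intersecting axes; x is the normal of their common plane
        mid = 0.5 * (p_on_zn + p_on_znext)
        return mid, unit(cr)
    # case (a): skew axes; x along the common normal, origin at its foot on z_next
    return p_on_znext, unit(p_on_znext - p_on_zn)


def _dh_from_frames(f_n: np.ndarray, f_next: np.ndarray, dof_n_center, scale: float):
    """``(theta0, alpha, d, r)`` linking two LCS poses, or None if inexpressible."""
    x_n, z_n, o_n = f_n[:3, 0], f_n[:3, 2], f_n[:3, 3]
    x_m, z_m, o_m = f_next[:3, 0], f_next[:3, 2], f_next[:3, 3]
    theta = np.arctan2(np.dot(np.cross(x_n, x_m), z_n), np.dot(x_n, x_m))
    alpha = np.arctan2(np.dot(np.cross(z_n, z_m), x_m), np.dot(z_n, z_m))
    cr = np.cross(z_n, z_m)
    if np.linalg.norm(cr) < 1e-9:
        foot = o_n + np.dot(o_m - o_n, z_n) * z_n
        d = float(np.dot(foot - o_n, z_n))
        r = float(np.dot(o_m - foot, x_m))
    else:
        p_zn, p_zm = _line_closest_points(o_n, z_n, o_m, z_m)
        d = float(np.dot(p_zn - o_n, z_n))
        r = float(np.dot(p_zm - p_zn, x_m))
    params = (float(theta), float(alpha), d, r)
    t_rel = np.linalg.inv(f_n) @ f_next
    if np.max(np.abs(dh_matrix(*params) - t_rel)) > 1e-9 * max(1.0, scale):
        return None
    return params


def build_dh(chain: KinematicChain) -> KinematicChain:
    """Construct local coordinate systems and D-H parameters for the chain.

    The z-axis of each LCS is its DOF's rotational axis; origin and x-axis
    follow the skew / intersecting / parallel case rules. The first DOF's
    x-axis is the cross product of its z-axis with the body-frame x-axis,
    anchored at the ThCx. The end-effector LCS duplicates the last TiTar
    frame with its origin translated to the tarsus tip; its link transform
    is stored as a full matrix because a duplicated frame is generally not
    expressible in the four D-H parameters.
    """
    scale = chain.scale
    frames: list[np.ndarray] = []
    first = chain.dofs[0]
    x0 = np.cross(first.axis, chain.body_x_axis)
    if np.linalg.norm(x0) < 1e-9:
        raise ValueError("ThCx yaw axis is parallel to the body x-axis")
    x0 = unit(x0)
    frames.append(pose_matrix(x0, np.cross(first.axis, x0), first.axis, first.center))
    for dof in chain.dofs[1:]:
        prev = frames[-1]
        origin, x_axis = _next_frame(prev[:3, 3], prev[:3, 0], prev[:3, 2], dof, scale)
        z_axis = dof.axis
        x_axis = unit(x_axis - np.dot(x_axis, z_axis) * z_axis)  # guard tiny drift
        frames.append(pose_matrix(x_axis, np.cross(z_axis, x_axis), z_axis, origin))
    last = frames[-1]
    ee = last.copy()
    ee[:3, 3] = chain.tarsus_tip_ref
    frames.append(ee)

    for f in frames:
        assert_rotation(f[:3, :3], tol=1e-9, name="LCS rotation")

    links = [np.linalg.inv(frames[i]) @ frames[i + 1] for i in range(len(frames) - 1)]
    params = [
        _dh_from_frames(frames[i], frames[i + 1], chain.dofs[i].center, scale)
        for i in range(len(frames) - 1)
    ]

    pts = dict(chain.joint_centers)
    pts["Tar"] = chain.tarsus_tip_ref
    keypoint_local = {
        kp: apply_transform(np.linalg.inv(frames[idx]), pts[kp])
        for kp, idx in _KEYPOINT_FRAME.items()
    }

    chain.frames_ref = frames
    chain.link_ref = links
    chain.dh_params = params
    chain.keypoint_local = keypoint_local
    return chain


def _rebuild_ee(chain: KinematicChain) -> None:
    """Refresh the end-effector frame/link after a tarsus-length change."""
    ee = chain.frames_ref[-2].copy()
    ee[:3, 3] = chain.tarsus_tip_ref
    chain.frames_ref[-1] = ee
    chain.link_ref[-1] = np.linalg.inv(chain.frames_ref[-2]) @ ee
    chain.dh_params[-1] = _dh_from_frames(chain.frames_ref[-2], ee, chain.dofs[-1].center, chain.scale)
    chain.keypoint_local["Tar"] = apply_transform(np.linalg.inv(ee), chain.tarsus_tip_ref)


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


def _angles_to_vector(chain: KinematicChain, angles) -> np.ndarray:
    """Full 14-vector of DOF angles in radians from degrees input."""
    vec = np.zeros(len(chain.dofs))
    if angles is None:
        return vec
    if isinstance(angles, dict):
        names = chain.dof_names
        for name, value in angles.items():
            if name not in names:
                raise KeyError(f"unknown DOF {name!r}")
            vec[names.index(name)] = np.radians(float(value))
    else:
        arr = np.asarray(angles, dtype=float)
        mobile_idx = [i for i, d in enumerate(chain.dofs) if d.mobile]
        if arr.shape != (len(mobile_idx),):
            raise ValueError(
                f"angle array must match the {len(mobile_idx)} mobile DOFs, got shape {arr.shape}"
            )
        vec[mobile_idx] = np.radians(arr)
    if np.any(np.abs(vec) > 2.0 * np.pi + 1e-12):
        raise ValueError("angle outside the +/-360 degree sanity bound")
    return vec


def forward_kinematics(chain: KinematicChain, angles=None) -> dict[str, np.ndarray]:
    """Keypoint positions (body coordinates, mm) for a set of DOF angles.

    ``angles`` may be a mapping of DOF name to degrees (unspecified DOFs stay
    at zero) or an array over the chain's mobile DOFs in chain order.
    """
    if not chain.frames_ref:
        raise RuntimeError("chain has no D-H frames; call build_dh first")
    vec = _angles_to_vector(chain, angles)
    out = {"ThCx": chain.landmarks.joints["ThCx"].center.copy()}
    frame_to_kp = {idx: kp for kp, idx in _KEYPOINT_FRAME.items()}
    m = chain.frames_ref[0]
    for i in range(len(chain.link_ref)):
        params = chain.dh_params[i]
        if params is not None:
            theta0, alpha, d, r = params
            t = dh_matrix(theta0 + vec[i], alpha, d, r)
        else:
            t = dh_matrix(vec[i], 0.0, 0.0, 0.0) @ chain.link_ref[i]
        m = m @ t
        kp = frame_to_kp.get(i + 1)
        if kp is not None:
            out[kp] = apply_transform(m, chain.keypoint_local[kp])
    return out


def keypoint_array(positions: dict[str, np.ndarray], names=KEYPOINTS) -> np.ndarray:
    """Stack a keypoint dict into an ``(len(names), 3)`` array."""
    return np.vstack([positions[n] for n in names])


# ---------------------------------------------------------------------------
# per-fly adaptation
# ---------------------------------------------------------------------------


def _similarity_from_triangles(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares similarity (scale, rotation, translation) mapping
    the three ``src`` points onto ``dst`` (Umeyama)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    if np.linalg.matrix_rank(xd, tol=1e-9 * np.abs(xd).max()) < 2:
        raise ValueError("degenerate reference triangle (collinear points)")
    cov = xd.T @ xs / src.shape[0]
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, sign])
    rot = u @ diag @ vt
    var_s = (xs**2).sum() / src.shape[0]
    scale = np.trace(np.diag(s) @ diag) / var_s
    t = np.eye(4)
    t[:3, :3] = scale * rot
    t[:3, 3] = mu_d - scale * rot @ mu_s
    return t


def scale_to_fly(
    chain: KinematicChain,
    fly_ThCx: np.ndarray,
    fly_rWH: np.ndarray,
    fly_lWH: np.ndarray,
    median_segment_lengths: dict[str, float],
    model_rWH: np.ndarray | None = None,
    model_lWH: np.ndarray | None = None,
) -> KinematicChain:
    """Adapt the model chain to an individual fly.

    A similarity transform mapping the model's ThCx/rWH/lWH reference
    triangle onto the fly's is applied to all condyle positions; afterwards
    every segment except the tarsus is rescaled to the median tracked length
    by translating the distal joint's condyles along the segment. Axis
    directions within each segment are preserved by the rescaling step.

    ``model_rWH``/``model_lWH`` default to the wing-hinge positions stored on
    the chain at construction time (in body coordinates).
    """
    for seg, value in median_segment_lengths.items():
        if seg not in SEGMENTS:
            raise ValueError(f"unknown segment {seg!r}")
        if value <= 0:
            raise ValueError(f"median length for {seg} must be > 0")
    src = np.vstack(
        [
            chain.joint_centers["ThCx"],
            model_rWH if model_rWH is not None else chain.model_rWH,
            model_lWH if model_lWH is not None else chain.model_lWH,
        ]
    )
    dst = np.vstack([np.asarray(fly_ThCx, float), np.asarray(fly_rWH, float), np.asarray(fly_lWH, float)])
    t = _similarity_from_triangles(src, dst)

    leg = copy.deepcopy(chain.landmarks)
    for jl in leg.joints.values():
        jl.condyle_a = apply_transform(t, jl.condyle_a)
        jl.condyle_b = apply_transform(t, jl.condyle_b)
        jl.center = apply_transform(t, jl.center)
    leg.tarsus_tip = apply_transform(t, leg.tarsus_tip)

    # per-segment rescale: translate each distal joint (and everything beyond)
    order = [("coxa", "ThCx", "CxTr"), ("trochanter", "CxTr", "TrFe"), ("femur", "TrFe", "FeTi"), ("tibia", "FeTi", "TiTar")]
    for seg, prox, dist in order:
        target = median_segment_lengths.get(seg)
        if target is None:
            continue
        p = leg.joints[prox].center
        q = leg.joints[dist].center
        shift = (p + unit(q - p) * float(target)) - q
        for dj in JOINTS[JOINTS.index(dist) :]:
            d = leg.joints[dj]
            d.condyle_a = d.condyle_a + shift
            d.condyle_b = d.condyle_b + shift
            d.center = d.center + shift
        leg.tarsus_tip = leg.tarsus_tip + shift
    return _rebuild(chain, leg)


def set_tarsus_length(chain: KinematicChain, length: float) -> KinematicChain:
    """Set the freely adjustable tarsus length (mm) in place."""
    if not np.isfinite(length) or length <= 0:
        raise ValueError(f"tarsus length must be positive, got {length}")
    chain.tarsus_length = float(length)
    if chain.frames_ref:
        _rebuild_ee(chain)
    return chain


# ---------------------------------------------------------------------------
# orthogonalized variant
# ---------------------------------------------------------------------------

#: tie-break preference when several body axes are equally close to a yaw axis
_BODY_AXIS_ORDER = (1, 2, 0)  # y, z, x


def orthogonalize(chain: KinematicChain, dof_config: dict | None = None) -> KinematicChain:
    """Derive the orthogonalized model variant from a condyle-based chain.

    Each yaw axis is replaced by the (signed) body axis with the largest
    absolute cosine to it, new condyles are placed at the joint center plus
    or minus that axis, and the leg is linearized so the segments point
    straight down (-z) from the ThCx with their original lengths. Exact ties
    between body axes are broken preferring y, then z, then x.
    """
    leg = copy.deepcopy(chain.landmarks)
    lengths = chain.segment_lengths
    eye = np.eye(3)
    for joint in JOINTS:
        jl = leg.joints[joint]
        axis = unit(jl.condyle_b - jl.condyle_a)
        cosines = np.abs(eye @ axis)
        best = max(_BODY_AXIS_ORDER, key=lambda i: (cosines[i], -_BODY_AXIS_ORDER.index(i)))
        new_axis = eye[best] if np.dot(eye[best], axis) >= 0 else -eye[best]
        half = 0.5 * float(np.linalg.norm(jl.condyle_b - jl.condyle_a))
        jl.condyle_a = jl.center - half * new_axis
        jl.condyle_b = jl.center + half * new_axis
    down = np.array([0.0, 0.0, -1.0])
    order = [("coxa", "ThCx", "CxTr"), ("trochanter", "CxTr", "TrFe"), ("femur", "TrFe", "FeTi"), ("tibia", "FeTi", "TiTar")]
    for seg, prox, dist in order:
        new_center = leg.joints[prox].center + lengths[seg] * down
        shift = new_center - leg.joints[dist].center
        jl = leg.joints[dist]
        jl.condyle_a = jl.condyle_a + shift
        jl.condyle_b = jl.condyle_b + shift
        jl.center = jl.center + shift
    leg.tarsus_tip = leg.joints["TiTar"].center + lengths["tarsus"] * down
    out = _rebuild(chain, leg)
    if dof_config is not None:
        _apply_dof_config(out.dofs, dof_config)
    return out
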