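"""Ground-truth synthetic flies, gait simulation and camera rendering.

Everything needed to exercise the pipeline without external data: a
six-legged bilaterally symmetric condyle landmark set with configurable
joint-axis obliquity, smooth periodic joint-angle trajectories producing
swing/stance cycles on a treadmill ball, per-frame tarsus-length modulation
that keeps stance tips exactly on the ball sphere, and multi-camera 2D
renderings with Gaussian pixel noise.

Default geometry matches the experimental scale: leg span around 2 mm,
ball radius 3 mm, 400 Hz frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import apply_transform, transform_about_axis, unit
from .camera import CameraModel, project
from .config import leg_pair, make_dof_config
from .gait import DEFAULT_BALL_RADIUS_MM
from .model import (
    JOINTS,
    KEYPOINTS,
    CondyleLandmarkSet,
    JointLandmarks,
    KinematicChain,
    LegLandmarks,
    build_chain,
    forward_kinematics,
    keypoint_array,
    set_tarsus_length,
)

__all__ = [
    "SyntheticScenario",
    "make_synthetic_fly",
    "default_waveforms",
    "simulate_walking",
    "simulate_fly_walking",
    "make_camera_rig",
    "render_observations",
]

#: default segment lengths (mm) at scale 1: coxa, trochanter, femur, tibia, tarsus
_SEGMENT_LENGTHS = (0.35, 0.18, 0.55, 0.5, 0.55)
#: ThCx root positions (mm) of the right legs at scale 1
_THCX_ROOTS = {"R1": (0.25, -0.18, -0.05), "R2": (0.0, -0.22, -0.05), "R3": (-0.25, -0.2, -0.05)}

#: default sinusoid (mean, amplitude) in degrees per DOF; CxTr-yaw and
#: FeTi-yaw are leg-pair specific to respect the angle-constraint tables
_WAVE_DEFAULTS = {
    "ThCx-yaw": (0.0, 4.0),
    "ThCx-pitch": (10.0, 5.0),
    "ThCx-roll": (0.0, 3.0),
    "CxTr-yaw": {"front": (-14.0, 4.0), "middle": (-25.0, 5.0), "hind": (-25.0, 5.0)},
    "CxTr-pitch": (5.0, 4.0),
    "CxTr-roll": (0.0, 4.0),
    "TrFe-yaw": (0.0, 4.0),
    "TrFe-pitch": (0.0, 4.0),
    "TrFe-roll": (0.0, 4.0),
    "FeTi-yaw": {"front": (40.0, 7.0), "middle": (40.0, 7.0), "hind": (40.0, 7.0)},
    "FeTi-pitch": (0.0, 4.0),
    "FeTi-roll": (0.0, 4.0),
    "TiTar-yaw": (15.0, 5.0),
    "TiTar-pitch": (0.0, 4.0),
}


@dataclass
class SyntheticScenario:
    """One leg's simulated walking sequence with full ground truth."""

    seed: int
    leg: str
    frame_rate_hz: float
    ball_radius_mm: float
    ball_center: np.ndarray
    times: np.ndarray
    angles_deg: pd.DataFrame  # frames x mobile DOFs, ground truth
    tarsus_lengths_mm: np.ndarray
    stance: np.ndarray  # bool, ground-truth phase labels
    keypoints_true: np.ndarray  # (n_frames, 6, 3), body coordinates, mm
    keypoints: np.ndarray  # noisy copy
    noise_um: float
    extras: dict = field(default_factory=dict)


def make_synthetic_fly(
    seed: int = 0,
    scale: float = 1.0,
    obliquity_deg: float = 0.0,
    condyle_spacing: float = 0.05,
    segment_lengths=None,
    bend_deg: dict[str, float] | None = None,
) -> CondyleLandmarkSet:
    """Generate a six-legged bilaterally symmetric condyle landmark set.

    Right legs hang straight down from their ThCx roots with yaw axes along
    the body y-axis tilted out of the segment-normal plane by
    ``obliquity_deg`` (with deterministic per-joint jitter proportional to
    the obliquity; 0 means exactly orthogonal axes). Left legs are exact
    sagittal reflections. ``bend_deg`` optionally bends each named joint
    about its yaw axis (applied proximal to distal) so the straightening
    step has work to do.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(segment_lengths if segment_lengths is not None else _SEGMENT_LENGTHS, float) * scale
    thap = np.array([-0.5, 0.0, 0.1]) * scale
    lwh = np.array([0.0, 0.25, 0.0]) * scale
    rwh = np.array([0.0, -0.25, 0.0]) * scale
    down = np.array([0.0, 0.0, -1.0])
    half = 0.5 * condyle_spacing * scale

    legs: dict[str, LegLandmarks] = {}
    for right_leg, root in _THCX_ROOTS.items():
        root = np.asarray(root, float) * scale
        centers = [root]
        for seg_len in lengths[:-1]:
            centers.append(centers[-1] + seg_len * down)
        tip = centers[-1] + lengths[-1] * down
        joints: dict[str, JointLandmarks] = {}
        for j, joint in enumerate(JOINTS):
            tilt = np.radians(obliquity_deg) * (1.0 + 0.3 * rng.standard_normal())
            swing = np.radians(obliquity_deg) * 0.3 * rng.standard_normal()
            axis = np.array([0.0, 1.0, 0.0])
            rx = transform_about_axis(np.array([1.0, 0.0, 0.0]), tilt, np.zeros(3))[:3, :3]
            rz = transform_about_axis(np.array([0.0, 0.0, 1.0]), swing, np.zeros(3))[:3, :3]
            axis = rz @ rx @ axis
            joints[joint] = JointLandmarks(
                condyle_a=centers[j] - half * axis,
                condyle_b=centers[j] + half * axis,
                center=centers[j],
            )
        leg = LegLandmarks(joints=joints, tarsus_tip=tip, side="right")
        if bend_deg:
            _bend_leg(leg, bend_deg)
        legs[right_leg] = leg
        legs["L" + right_leg[1]] = _reflect_leg(leg)
    return CondyleLandmarkSet(legs=legs, ThAp=thap, lWH=lwh, rWH=rwh)


def _bend_leg(leg: LegLandmarks, bend_deg: dict[str, float]) -> None:
    for joint, angle in bend_deg.items():
        if joint not in JOINTS:
            raise ValueError(f"unknown joint {joint!r}")
        jl = leg.joints[joint]
        axis = unit(jl.condyle_b - jl.condyle_a)
        t = transform_about_axis(axis, np.radians(angle), jl.center)
        for dj in JOINTS[JOINTS.index(joint) + 1 :]:
            d = leg.joints[dj]
            d.condyle_a = apply_transform(t, d.condyle_a)
            d.condyle_b = apply_transform(t, d.condyle_b)
            d.center = apply_transform(t, d.center)
        leg.tarsus_tip = apply_transform(t, leg.tarsus_tip)


def _reflect_leg(leg: LegLandmarks) -> LegLandmarks:
    refl = np.array([1.0, -1.0, 1.0])
    joints = {
        j: JointLandmarks(jl.condyle_a * refl, jl.condyle_b * refl, jl.center * refl)
        for j, jl in leg.joints.items()
    }
    return LegLandmarks(joints=joints, tarsus_tip=leg.tarsus_tip * refl, side="left")


def default_waveforms(chain: KinematicChain) -> dict[str, tuple[float, float]]:
    """Default (mean, amplitude) in degrees for each mobile DOF of a chain.

    Yaw and roll entries are sign-flipped for left legs (matching the
    sign-inverted constraint tables); amplitudes are shrunk if needed so the
    waveform stays strictly inside the DOF bounds.
    """
    pair = leg_pair(chain.leg)
    left = chain.leg.startswith("L")
    waves = {}
    for name in chain.mobile_dofs:
        entry = _WAVE_DEFAULTS[name]
        mean, amp = entry[pair] if isinstance(entry, dict) else entry
        kind = name.split("-")[1]
        if left and kind in ("yaw", "roll"):
            mean = -mean
        lo, hi = chain.dof(name).bounds_deg
        margin = 1.0
        amp = min(amp, max(0.0, mean - lo - margin), max(0.0, hi - mean - margin))
        waves[name] = (mean, amp)
    return waves


def _nominal_angles(chain, waves, psi):
    """Evaluate sinusoidal DOF trajectories over normalized phase ``psi``."""
    names = chain.mobile_dofs
    cols = {}
    for k, name in enumerate(names):
        mean, amp = waves[name]
        phase = 2.0 * np.pi * (0.382 * k)  # deterministic spread of phases
        cols[name] = mean + amp * np.sin(2.0 * np.pi * psi + phase)
    table = pd.DataFrame(cols)
    bounds = chain.bounds_deg_array(names)
    for i, name in enumerate(names):
        if table[name].min() < bounds[i, 0] or table[name].max() > bounds[i, 1]:
            raise ValueError(f"waveform for {name} violates the angle bounds {tuple(bounds[i])}")
    return table


def simulate_walking(
    chain: KinematicChain,
    n_steps: int = 3,
    cadence_hz: float = 2.0,
    seed: int = 0,
    noise_um: float = 0.0,
    frame_rate_hz: float = 400.0,
    duty: float = 0.5,
    phase_offset: float = 0.0,
    ball_radius_mm: float = DEFAULT_BALL_RADIUS_MM,
    ball_center: np.ndarray | None = None,
    lift_mm: float = 0.3,
    waveforms: dict[str, tuple[float, float]] | None = None,
) -> SyntheticScenario:
    """Simulate a walking sequence for one leg with full ground truth.

    Smooth periodic sinusoids drive the mobile DOFs; during ground-truth
    stance frames the tarsus length is solved so the tip lies exactly on the
    ball sphere, and during swing the tarsus is retracted by ``lift_mm``
    along its ray so the tip clears the sphere (emulating tarsus bending).
    Gaussian keypoint noise of ``noise_um`` micrometres is added to a copy;
    the noiseless keypoints, generating angles, tarsus lengths and phase
    labels are all retained.
    """
    if not chain.mobile_dofs:
        raise ValueError("chain has no mobile DOFs to drive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(n_steps * frame_rate_hz / cadence_hz))
    times = np.arange(n_frames) / frame_rate_hz
    psi = np.mod(cadence_hz * times + phase_offset, 1.0)
    stance = psi < duty
    waves = waveforms if waveforms is not None else default_waveforms(chain)
    angles = _nominal_angles(chain, waves, psi)

    nominal_length = chain.tarsus_length
    nominal = [forward_kinematics(chain, row.to_dict()) for _, row in angles.iterrows()]
    if ball_center is None:
        stance_tips = np.array([keypoint_array(nominal[i])[5] for i in np.flatnonzero(stance)])
        ball_center = _fit_sphere_center(stance_tips, ball_radius_mm)
    ball_center = np.asarray(ball_center, dtype=float)

    tarsus_lengths = np.empty(n_frames)
    keypoints = np.empty((n_frames, len(KEYPOINTS), 3))
    for i in range(n_frames):
        q = nominal[i]["TiTar"]
        u = unit(nominal[i]["Tar"] - q)
        length = _ray_sphere_length(q, u, ball_center, ball_radius_mm, nominal_length)
        if not stance[i]:
            length = length - lift_mm
        if length <= 0.1 * nominal_length:
            raise ValueError("tarsus retraction collapsed the tarsus; reduce lift_mm")
        tarsus_lengths[i] = length
        set_tarsus_length(chain, length)
        keypoints[i] = keypoint_array(forward_kinematics(chain, angles.iloc[i].to_dict()))
    set_tarsus_length(chain, nominal_length)

    dist = np.linalg.norm(keypoints[:, 5] - ball_center, axis=1)
    if np.max(np.abs(dist[stance] - ball_radius_mm)) > 1e-9:
        raise ValueError("internal error: stance tips not on the ball sphere")
    clearance = dist[~stance] - ball_radius_mm if np.any(~stance) else np.array([np.inf])
    if np.min(clearance) < 0.08:
        raise ValueError(
            f"swing clearance {np.min(clearance):.3f} mm too small; increase lift_mm"
        )

    noisy = keypoints + rng.normal(0.0, noise_um / 1000.0, size=keypoints.shape)
    return SyntheticScenario(
        seed=seed,
        leg=chain.leg,
        frame_rate_hz=frame_rate_hz,
        ball_radius_mm=ball_radius_mm,
        ball_center=ball_center,
        times=times,
        angles_deg=angles,
        tarsus_lengths_mm=tarsus_lengths,
        stance=stance,
        keypoints_true=keypoints,
        keypoints=noisy,
        noise_um=float(noise_um),
        extras={"duty": duty, "cadence_hz": cadence_hz, "phase_offset": phase_offset},
    )


def _fit_sphere_center(points: np.ndarray, radius: float) -> np.ndarray:
    """Ball placement for the generator: center on the vertical axis through
    the stance-tip centroid, depth fitted so tips sit near the sphere."""
    from scipy.optimize import least_squares

    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)

    def residuals(cz):
        c = np.array([centroid[0], centroid[1], cz[0]])
        return np.linalg.norm(pts - c, axis=1) - radius

    sol = least_squares(residuals, np.array([centroid[2] - radius]), method="lm")
    return np.array([centroid[0], centroid[1], float(sol.x[0])])


def _ray_sphere_length(q, u, center, radius, nominal) -> float:
    w = q - center
    b = float(np.dot(u, w))
    disc = b * b - (float(np.dot(w, w)) - radius * radius)
    if disc < 0 or b >= 0:
        raise ValueError(
            "tarsus ray misses the ball sphere; adjust waveforms or ball placement"
        )
    length = -b - np.sqrt(disc)
    if not 0.4 * nominal <= length <= 1.8 * nominal:
        raise ValueError(
            f"ball-contact tarsus length {length:.3f} mm is implausible "
            f"(nominal {nominal:.3f} mm)"
        )
    return float(length)


#: tripod gait phase offsets
_TRIPOD_OFFSETS = {"R1": 0.0, "L2": 0.0, "R3": 0.0, "L1": 0.5, "R2": 0.5, "L3": 0.5}


def simulate_fly_walking(
    landmarks: CondyleLandmarkSet,
    n_steps: int = 3,
    cadence_hz: float = 2.0,
    seed: int = 0,
    noise_um: float = 0.0,
    mobility: dict[str, bool] | str | None = None,
    model: str = "oblique",
    **kwargs,
) -> dict[str, SyntheticScenario]:
    """Simulate all six legs in a tripod gait sharing one ball.

    Per-leg chains are built from the landmark set (straightening included
    implicitly: the generated reference is already extended); a shared ball
    center is fitted to the pooled nominal stance tips, then each leg is
    simulated against it with its tripod phase offset.
    """
    chains = {}
    for leg in landmarks.legs:
        cfg = make_dof_config(leg, model=model, mobility=mobility)
        chains[leg] = build_chain(landmarks, leg, cfg)
    # first pass: nominal stance tips of every leg at zero lift
    pooled = []
    frame_rate = kwargs.get("frame_rate_hz", 400.0)
    duty = kwargs.get("duty", 0.5)
    n_frames = int(round(n_steps * frame_rate / cadence_hz))
    times = np.arange(n_frames) / frame_rate
    for leg, chain in chains.items():
        psi = np.mod(cadence_hz * times + _TRIPOD_OFFSETS[leg], 1.0)
        angles = _nominal_angles(chain, default_waveforms(chain), psi)
        tips = np.array(
            [
                keypoint_array(forward_kinematics(chain, row.to_dict()))[5]
                for _, row in angles.iterrows()
            ]
        )
        pooled.append(tips[psi < duty])
    center = _fit_sphere_center(np.vstack(pooled), DEFAULT_BALL_RADIUS_MM)

    scenarios = {}
    for i, (leg, chain) in enumerate(chains.items()):
        scenarios[leg] = simulate_walking(
            chain,
            n_steps=n_steps,
            cadence_hz=cadence_hz,
            seed=seed + i,
            noise_um=noise_um,
            phase_offset=_TRIPOD_OFFSETS[leg],
            ball_center=center,
            **kwargs,
        )
    return scenarios


def make_camera_rig(
    n_cameras: int = 6,
    distance_mm: float = 50.0,
    focal_px: float = 8500.0,
    image_size=(896, 540),
    distortion: bool = True,
    target=(0.0, 0.0, -1.0),
) -> list[CameraModel]:
    """Build a synthetic multi-camera rig surrounding the fly.

    Cameras are spread over azimuth at alternating elevations, all aimed at
    ``target`` (mm). The geometry mimics the experimental scale (about
    6 micrometres per pixel at the working distance).
    """
    if n_cameras < 2:
        raise ValueError("a rig needs at least 2 cameras")
    target = np.asarray(target, float)
    cams = []
    for i in range(n_cameras):
        az = 2.0 * np.pi * i / n_cameras + 0.3
        el = np.radians(15.0 if i % 2 else -10.0)
        pos = target + distance_mm * np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )
        z = unit(target - pos)
        up = np.array([0.0, 0.0, 1.0])
        x = unit(np.cross(z, up))
        y = np.cross(z, x)
        rot = np.vstack([x, y, z])
        cams.append(
            CameraModel(
                focal=(focal_px, focal_px),
                principal_point=(image_size[0] / 2.0, image_size[1] / 2.0),
                radial=(-0.25, 0.12, 0.0) if distortion else (0.0, 0.0, 0.0),
                tangential=(1.5e-4, -1.0e-4) if distortion else (0.0, 0.0),
                rotation=rot,
                translation=-rot @ pos,
                image_size=image_size,
                camera_id=f"cam{i}",
            )
        )
    return cams


def render_observations(
    keypoints3d: np.ndarray,
    rig: list[CameraModel],
    pixel_noise_sigma: float = 0.0,
    seed: int = 0,
    keypoint_names=KEYPOINTS,
) -> pd.DataFrame:
    """Project 3D keypoints into every camera of a rig.

    ``keypoints3d`` is (n_frames, n_keypoints, 3) in global mm. Returns a
    table with columns frame, camera_id, keypoint_name, x_px, y_px, valid.
    No occlusion model: every projection is marked valid.
    """
    kp = np.asarray(keypoints3d, dtype=float)
    if kp.ndim != 3 or kp.shape[2] != 3:
        raise ValueError(f"keypoints3d must be (n_frames, n_keypoints, 3), got {kp.shape}")
    if len(rig) < 2:
        raise ValueError("rendering requires at least 2 cameras")
    if kp.shape[1] != len(keypoint_names):
        raise ValueError("keypoint_names must match the keypoint axis")
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(kp.shape[0]):
        for k, name in enumerate(keypoint_names):
            for cam in rig:
                px = project(kp[f, k], cam, apply_distortion=True)
                if pixel_noise_sigma > 0:
                    px = px + rng.normal(0.0, pixel_noise_sigma, size=2)
                rows.append(
                    {
                        "frame": f,
                        "camera_id": cam.camera_id,
                        "keypoint_name": name,
                        "x_px": px[0],
                        "y_px": px[1],
                        "valid": True,
                    }
                )
    return pd.DataFrame(rows)
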