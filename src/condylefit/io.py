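"""File formats: landmark JSON, camera JSON, keypoint/observation tables.

Keypoint and observation tables are pandas DataFrames stored as CSV or HDF5
depending on the file suffix (.h5/.hdf5 uses h5py, everything else CSV).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .camera import CameraModel
from .model import KEYPOINTS, CondyleLandmarkSet, JointLandmarks, LegLandmarks

__all__ = [
    "save_landmarks",
    "load_landmarks",
    "save_cameras",
    "load_cameras",
    "save_keypoints",
    "load_keypoints",
    "keypoints_to_table",
    "table_to_keypoints",
    "load_dof_config",
    "save_fit_result",
]


# -- landmark JSON ----------------------------------------------------------


def save_landmarks(landmarks: CondyleLandmarkSet, path) -> None:
    doc = {
        "legs": {
            leg: {
                "side": ll.side,
                "joints": {
                    j: {
                        "condyle_a": jl.condyle_a.tolist(),
                        "condyle_b": jl.condyle_b.tolist(),
                        "center": jl.center.tolist(),
                    }
                    for j, jl in ll.joints.items()
                },
                "tarsus_tip": ll.tarsus_tip.tolist(),
            }
            for leg, ll in landmarks.legs.items()
        },
        "body": {
            "ThAp": landmarks.ThAp.tolist(),
            "lWH": landmarks.lWH.tolist(),
            "rWH": landmarks.rWH.tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_landmarks(path) -> CondyleLandmarkSet:
    doc = json.loads(Path(path).read_text())
    legs = {}
    for leg, entry in doc["legs"].items():
        joints = {
            j: JointLandmarks(v["condyle_a"], v["condyle_b"], v["center"])
            for j, v in entry["joints"].items()
        }
        legs[leg] = LegLandmarks(
            joints=joints,
            tarsus_tip=entry["tarsus_tip"],
            side=entry.get("side", "left" if leg.startswith("L") else "right"),
        )
    body = doc["body"]
    return CondyleLandmarkSet(legs=legs, ThAp=body["ThAp"], lWH=body["lWH"], rWH=body["rWH"])


# -- camera JSON ------------------------------------------------------------


def save_cameras(cameras: list[CameraModel], path) -> None:
    doc = [
        {
            "camera_id": c.camera_id,
            "focal": c.focal.tolist(),
            "principal_point": c.principal_point.tolist(),
            "radial": c.radial.tolist(),
            "tangential": c.tangential.tolist(),
            "rotation": c.rotation.tolist(),
            "translation": c.translation.tolist(),
            "image_size": c.image_size.tolist(),
        }
        for c in cameras
    ]
    Path(path).write_text(json.dumps(doc, indent=2))


def load_cameras(path) -> list[CameraModel]:
    doc = json.loads(Path(path).read_text())
    return [CameraModel(**entry) for entry in doc]


# -- tabular keypoints ------------------------------------------------------


def keypoints_to_table(keypoints: np.ndarray, leg: str, keypoint_names=KEYPOINTS) -> pd.DataFrame:
    kp = np.asarray(keypoints, dtype=float)
    rows = []
    for f in range(kp.shape[0]):
        for k, name in enumerate(keypoint_names):
            rows.append(
                {
                    "frame": f,
                    "leg": leg,
                    "keypoint": name,
                    "x_mm": kp[f, k, 0],
                    "y_mm": kp[f, k, 1],
                    "z_mm": kp[f, k, 2],
                }
            )
    return pd.DataFrame(rows)


def table_to_keypoints(table: pd.DataFrame, leg: str, keypoint_names=KEYPOINTS) -> np.ndarray:
    sub = table[table["leg"] == leg]
    if sub.empty:
        raise ValueError(f"no rows for leg {leg!r}")
    frames = np.sort(sub["frame"].unique())
    out = np.full((len(frames), len(keypoint_names), 3), np.nan)
    index = {(int(r.frame), r.keypoint): (r.x_mm, r.y_mm, r.z_mm) for r in sub.itertuples()}
    for i, f in enumerate(frames):
        for k, name in enumerate(keypoint_names):
            if (int(f), name) in index:
                out[i, k] = index[(int(f), name)]
    return out


def _is_hdf(path) -> bool:
    return str(path).lower().endswith((".h5", ".hdf5"))


def save_keypoints(table: pd.DataFrame, path) -> None:
    if _is_hdf(path):
        import h5py

        with h5py.File(path, "w") as fh:
            for col in table.columns:
                data = table[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                fh.create_dataset(col, data=data)
    else:
        table.to_csv(path, index=False)


def load_keypoints(path) -> pd.DataFrame:
    if _is_hdf(path):
        import h5py

        with h5py.File(path, "r") as fh:
            cols = {}
            for key in fh:
                data = fh[key][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[key] = data
        return pd.DataFrame(cols)
    return pd.read_csv(path)


# -- configs and results ----------------------------------------------------


def load_dof_config(path) -> dict:
    """Load a per-leg DOF config YAML: ``{leg: {dof: {mobile, bounds}}}``."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_fit_result(result, path) -> None:
    """Write a fit result as a long table: frame, leg, dof, angle_deg, ..."""
    rows = []
    for f in result.frames:
        if not f.valid:
            rows.append(
                {
                    "frame": f.frame,
                    "leg": result.leg,
                    "dof": "",
                    "angle_deg": np.nan,
                    "error_um": np.nan,
                    "converged": False,
                    "valid": False,
                }
            )
            continue
        for dof, angle in f.angles.angles.items():
            rows.append(
                {
                    "frame": f.frame,
                    "leg": result.leg,
                    "dof": dof,
                    "angle_deg": angle,
                    "error_um": f.error_um,
                    "converged": f.converged,
                    "valid": True,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
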