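"""DOF mobility configurations and angle-bound tables.

Bundled YAML data files carry the default angle constraints for both model
variants; mobility presets cover the reference configuration (ball-and-socket
ThCx, hinge CxTr/FeTi, fixed TrFe, two-DOF TiTar), the final front-leg
configuration with an added TrFe-roll, and all DOF-set variations of the
configuration-comparison experiment.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .model import DOF_NAMES

__all__ = [
    "leg_pair",
    "load_bounds",
    "REFERENCE_MOBILITY",
    "FINAL_FRONT_MOBILITY",
    "TABLE2_MOBILITY_VARIANTS",
    "make_dof_config",
]

_PAIR = {"1": "front", "2": "middle", "3": "hind"}

#: reference-model mobility: all three ThCx DOFs, CxTr/FeTi yaw, TiTar yaw+pitch
REFERENCE_MOBILITY: dict[str, bool] = {
    name: name
    in {
        "ThCx-yaw",
        "ThCx-pitch",
        "ThCx-roll",
        "CxTr-yaw",
        "FeTi-yaw",
        "TiTar-yaw",
        "TiTar-pitch",
    }
    for name in DOF_NAMES
}

#: final front-leg configuration: reference plus a mobile TrFe-roll
FINAL_FRONT_MOBILITY: dict[str, bool] = {**REFERENCE_MOBILITY, "TrFe-roll": True}

#: DOF-set variations (overrides relative to the reference mobility) of the
#: configuration-comparison experiment: ThCx yaw/pitch/roll presence, plus
#: optional CxTr-roll and TrFe yaw/pitch/roll additions. The first entry is
#: the reference configuration itself.
_T2 = [
    # (ThCx-yaw, ThCx-pitch, ThCx-roll, CxTr-roll, TrFe-yaw, TrFe-pitch, TrFe-roll)
    (1, 1, 1, 0, 0, 0, 0),
    (1, 0, 0, 0, 0, 0, 0),
    (0, 1, 0, 0, 0, 0, 0),
    (0, 0, 1, 0, 0, 0, 0),
    (1, 1, 0, 0, 0, 0, 0),
    (1, 0, 1, 0, 0, 0, 0),
    (0, 1, 1, 0, 0, 0, 0),
    (1, 1, 1, 0, 1, 0, 0),
    (1, 1, 1, 0, 0, 1, 0),
    (1, 1, 1, 0, 0, 0, 1),
    (1, 1, 1, 0, 1, 0, 1),
    (1, 1, 1, 0, 0, 1, 1),
    (1, 1, 1, 0, 1, 1, 0),
    (1, 1, 1, 1, 0, 0, 0),
]
_T2_NAMES = ("ThCx-yaw", "ThCx-pitch", "ThCx-roll", "CxTr-roll", "TrFe-yaw", "TrFe-pitch", "TrFe-roll")

TABLE2_MOBILITY_VARIANTS: list[dict[str, bool]] = [
    {**REFERENCE_MOBILITY, **{n: bool(v) for n, v in zip(_T2_NAMES, row)}} for row in _T2
]


def leg_pair(leg: str) -> str:
    """Map a leg id (R1..L3) to its pair name (front/middle/hind)."""
    if len(leg) != 2 or leg[0] not in "RL" or leg[1] not in _PAIR:
        raise ValueError(f"invalid leg id {leg!r}; expected one of R1,L1,R2,L2,R3,L3")
    return _PAIR[leg[1]]


def load_bounds(model: str = "oblique") -> dict:
    """Load the bundled default angle-constraint table for a model variant."""
    if model not in ("oblique", "orthogonalized"):
        raise ValueError(f"unknown model variant {model!r}")
    ref = resources.files("condylefit.data") / f"table1_{model}.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def make_dof_config(
    leg: str,
    model: str = "oblique",
    mobility: dict[str, bool] | None = None,
    bounds: dict | None = None,
) -> dict:
    """Build a per-DOF config ``{name: {mobile, bounds}}`` for one leg.

    Bounds come from the bundled constraint table (or ``bounds``, same
    layout) for the leg's pair; for left legs the yaw and roll bounds are
    sign-inverted. ``mobility`` defaults to the reference configuration
    (with the TrFe-roll added for front legs when ``mobility`` is the
    string ``"final"``).
    """
    pair = leg_pair(leg)
    table = (bounds or load_bounds(model))[pair]
    if mobility == "final":
        mobility = FINAL_FRONT_MOBILITY if pair == "front" else REFERENCE_MOBILITY
    elif mobility is None:
        mobility = REFERENCE_MOBILITY
    left = leg.startswith("L")
    config: dict[str, dict] = {}
    for name in DOF_NAMES:
        joint, kind = name.split("-")
        lo, hi = (float(v) for v in table[joint][kind])
        if left and kind in ("yaw", "roll"):
            lo, hi = -hi, -lo
        config[name] = {"mobile": bool(mobility.get(name, False)), "bounds": [lo, hi]}
    return config
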