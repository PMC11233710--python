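import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import condylefit as cf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fly_oblique():
    """Synthetic fly with clearly oblique joint axes."""
    return cf.make_synthetic_fly(seed=11, obliquity_deg=12.0)


@pytest.fixture(scope="session")
def fly_orthogonal():
    """Synthetic fly with joint axes exactly along body y."""
    return cf.make_synthetic_fly(seed=11, obliquity_deg=0.0)


def build(fly, leg, mobility=None, model="oblique"):
    return cf.build_chain(fly, leg, cf.make_dof_config(leg, model=model, mobility=mobility))


@pytest.fixture
def chain_r2(fly_oblique):
    """Fresh middle-leg chain with the reference mobility."""
    return build(fly_oblique, "R2")


@pytest.fixture(scope="session")
def walking_scenario(fly_oblique):
    """One simulated noiseless middle-leg walking sequence (read-only)."""
    chain = build(fly_oblique, "R2")
    return cf.simulate_walking(chain, n_steps=2, cadence_hz=2.0, seed=21, noise_um=0.0)


@pytest.fixture(scope="session")
def fly_scenarios(fly_oblique):
    """All six legs walking on a shared ball, noiseless (read-only)."""
    return cf.simulate_fly_walking(fly_oblique, n_steps=2, seed=31, noise_um=0.0)


@pytest.fixture(scope="session")
def camera_rig():
    return cf.make_camera_rig(n_cameras=6)
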