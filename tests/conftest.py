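import numpy as np
import pytest

from ethospan._alphabet import NODE_NAMES
from ethospan.preprocess import PoseSequence
from ethospan.synth import (SynthConfig, default_archetypes, render_pose)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def quiet_config():
    """Corruption-free generator config for deterministic kinematic checks."""
    return SynthConfig(missing_rate=0.0, edge_bout_rate=0.0, noise_sd_mm=0.0, seed=0)


@pytest.fixture
def static_pose():
    """A fully observed, stationary pose (template at the arena center)."""
    cfg = SynthConfig(missing_rate=0.0, edge_bout_rate=0.0, noise_sd_mm=0.0)
    states = np.full(200, "idle", dtype="U20")
    arch = default_archetypes()
    pose = render_pose(states, arch, cfg, seed=0)
    # make the proboscis observed so the pose is complete
    pose.missing[:] = False
    pose.coords[:, NODE_NAMES.index("proboscis"), :] = \
        pose.coords[:, NODE_NAMES.index("head"), :] + np.array([0.5 * cfg.px_per_mm, 0.0])
    return pose


def make_pose(coords, missing=None, fps=100.0, px_per_mm=1.0):
    coords = np.asarray(coords, dtype=float)
    if missing is None:
        missing = np.zeros(coords.shape[:2], dtype=bool)
    return PoseSequence(coords=coords, missing=missing, fps=fps, px_per_mm=px_per_mm)
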