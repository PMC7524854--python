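"""Shared fixtures. Expensive scene/observation fixtures are session-scoped."""

import numpy as np
import pytest

from lapreg.gate import gate_points
from lapreg.scene import look_at_pose, make_scene, observe
from lapreg.stereo import default_rig
from lapreg.transforms import RigidTransform


def random_rigid_transform(rng, max_trans_mm=50.0):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    return RigidTransform(R, rng.uniform(-max_trans_mm, max_trans_mm, size=3))


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def front_pose():
    """Camera 320 mm in front of the origin, looking at it, z-up roll hint."""
    return look_at_pose((0.0, -320.0, 0.0), (0.0, 0.0, 0.0), up=(0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def plain_scene():
    """Distractor-free scene at a known non-identity pose (zero-noise source)."""
    true_pose = RigidTransform.from_euler_deg(3.0, -4.0, 5.0, (8.0, -6.0, 4.0))
    return make_scene(3, distractor_spec=None, n_landmarks=4, subdivisions=3,
                      true_pose=true_pose)


@pytest.fixture(scope="session")
def plain_cloud(plain_scene, rig, front_pose):
    """Noiseless gated reconstruction of plain_scene (1000 liver points)."""
    obs = observe(plain_scene, rig, front_pose, n_points=1000, noise_sd_px=0.0, seed=3)
    cloud, dropped = obs.reconstruct()
    assert dropped == 0
    return gate_points(cloud, 0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
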