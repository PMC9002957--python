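import pytest

from mvkin.cameras import make_rig
from mvkin.model import default_model
from mvkin.simulate import CorruptionSpec, MotionSpec, generate_motion, observe
from mvkin.triangulate import triangulate_sequence


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def rig8():
    return make_rig(8, 4.0)


@pytest.fixture(scope="session")
def walking_truth(model):
    """Small deterministic walking trial (3 cycles, 90 frames)."""
    return generate_motion(MotionSpec(n_cycles=3, seed=11), model)


@pytest.fixture(scope="session")
def clean_observations(walking_truth, rig8):
    return observe(walking_truth, rig8, CorruptionSpec())


@pytest.fixture(scope="session")
def clean_trajectory(clean_observations, rig8):
    return triangulate_sequence(clean_observations, rig8)
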