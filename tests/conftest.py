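import numpy as np
import pytest

from endofuse.camera import default_endoscope
from endofuse.geometry import RigidTransform, axis_angle_to_matrix


def random_rigid(rng: np.random.Generator, source="b", target="a", trans_scale=50.0):
    """A random well-conditioned rigid transform for property tests."""
    axis = rng.standard_normal(3)
    angle = rng.uniform(0.1, np.pi - 0.1)
    return RigidTransform(
        axis_angle_to_matrix(axis, angle),
        rng.uniform(-trans_scale, trans_scale, size=3),
        source=source,
        target=target,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cam():
    """Quarter-resolution simulated endoscope (648x486)."""
    return default_endoscope(0.25)


@pytest.fixture(scope="session")
def tiny_run():
    """A small zero-noise protocol run shared across tests (no rendering)."""
    from endofuse.simulator import run_accuracy_protocol

    return run_accuracy_protocol(
        distances=(10.0, 20.0, 30.0), positions_per_distance=12, render=False, seed=7
    )
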