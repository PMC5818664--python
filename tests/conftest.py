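import numpy as np
import pytest

from permeon.channel import default_system
from permeon.trajectory import Trajectory, make_particles


@pytest.fixture(scope="session")
def system():
    return default_system()


@pytest.fixture(scope="session")
def lower_geometry(system):
    return system.channels["lower"]


def build_trajectory(particle_rows, positions, times=None, box=(40.0, 40.0, 160.0)):
    """Hand-build a trajectory from particle row dicts and a position array."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None, :, :]
    if times is None:
        times = np.arange(positions.shape[0]) * 100.0
    return Trajectory(
        particles=make_particles(particle_rows),
        times=np.asarray(times, dtype=float),
        box=np.asarray(box, dtype=float),
        positions=positions,
    )


@pytest.fixture()
def make_traj():
    return build_trajectory
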