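import numpy as np
import pytest

from groupmotion import SimulationConfig, TrajectorySet, compute_velocity
from groupmotion import simulate_rotation, simulate_tag


def build_traj(positions, dt=0.05, with_velocity=True, ids=None):
    """TrajectorySet from an (N, T, 2) array, velocities filled by default."""
    positions = np.asarray(positions, dtype=float)
    ids = ids or [f"c{k + 1}" for k in range(positions.shape[0])]
    traj = TrajectorySet(frame_interval=dt, individuals=ids, positions=positions)
    return compute_velocity(traj) if with_velocity else traj


def random_traj(rng, n=5, t=100, dt=0.05, scale=400.0):
    """Random-walk trajectory set for oracle comparisons."""
    steps = rng.normal(0, 10, size=(n, t, 2))
    pos = np.cumsum(steps, axis=1) + rng.uniform(100, scale, size=(n, 1, 2))
    return build_traj(pos, dt=dt)


@pytest.fixture(scope="session")
def rotation_session():
    traj, truth = simulate_rotation(SimulationConfig(n_agents=11, duration=40.0, seed=11))
    return compute_velocity(traj), truth


@pytest.fixture(scope="session")
def tag_session():
    traj, truth = simulate_tag(SimulationConfig(n_agents=12, duration=40.0, seed=12))
    return compute_velocity(traj), truth
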