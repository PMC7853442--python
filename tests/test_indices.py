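"""Movement indices against closed forms and brute-force oracles."""

import numpy as np
import pytest

from groupmotion import (
    activity_amount,
    angular_momentum,
    group_angular_momentum,
    pair_angle,
    pair_distance,
    static_group_center,
)

from conftest import build_traj, random_traj


def brute_force_distance(pos, i, j):
    return np.sqrt(((pos[i] - pos[j]) ** 2).sum(axis=1))


def brute_force_center(pos):
    n, t, _ = pos.shape
    acc = np.zeros(2)
    for frame in range(t):
        frame_mean = np.zeros(2)
        for k in range(n):
            frame_mean += pos[k, frame]
        acc += frame_mean / n
    return acc / t


def brute_force_momentum(pos, vel, center):
    n, t, _ = pos.shape
    out = np.full((n, t), np.nan)
    for k in range(n):
        for frame in range(t):
            v = vel[k, frame]
            if np.isnan(v).any():
                continue
            a = pos[k, frame] - center
            ra, rv = np.linalg.norm(a), np.linalg.norm(v)
            if ra == 0 or rv == 0:
                continue
            ua, uv = a / ra, v / rv
            out[k, frame] = abs(ua[0] * uv[1] - ua[1] * uv[0])
    return out


# ---------------------------------------------------------------------------
# Pairwise distance


def test_distance_345_triangle():
    pos = np.zeros((2, 5, 2))
    pos[1, :] = [300.0, 400.0]
    d = pair_distance(build_traj(pos, with_velocity=False))
    np.testing.assert_allclose(d.get("c1", "c2"), 500.0)
    np.testing.assert_allclose(d.get("c2", "c1"), 500.0)  # symmetric lookup


def test_distance_coincident_is_zero():
    pos = np.full((2, 3, 2), 7.0)
    d = pair_distance(build_traj(pos, with_velocity=False))
    np.testing.assert_allclose(d.get("c1", "c2"), 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_distance_matches_brute_force(seed):
    traj = random_traj(np.random.default_rng(seed), n=5, t=50)
    d = pair_distance(traj)
    for a in range(5):
        for b in range(a + 1, 5):
            np.testing.assert_allclose(
                d.get(f"c{a + 1}", f"c{b + 1}"),
                brute_force_distance(traj.positions, a, b),
                atol=1e-9,
            )


# ---------------------------------------------------------------------------
# Heading angle


def _two_agent_angle(velocity, offset):
    """theta_12 at frame 1 for agent 1 moving with `velocity`, agent 2 at `offset`."""
    dt = 0.05
    pos = np.zeros((2, 2, 2))
    pos[0, 0] = -np.asarray(velocity) * dt  # backward difference gives `velocity`
    pos[1, :] = offset
    ang = pair_angle(build_traj(pos, dt=dt))
    assert ang.get_valid("c1", "c2")[1]
    return ang.get("c1", "c2")[1]


def test_angle_head_on_perpendicular_away():
    assert _two_agent_angle((1, 0), (5, 0)) == pytest.approx(0.0, abs=1e-9)
    assert _two_agent_angle((1, 0), (0, 3)) == pytest.approx(90.0, abs=1e-9)
    assert _two_agent_angle((1, 0), (-2, 0)) == pytest.approx(180.0, abs=1e-9)


def test_angle_reversed_velocity_complements():
    """theta with velocity v plus theta with -v equals 180 at every valid frame."""
    traj = random_traj(np.random.default_rng(42), n=4, t=60)
    rev = build_traj(traj.positions, with_velocity=False)
    rev.velocities = -traj.velocities
    a1, a2 = pair_angle(traj), pair_angle(rev)
    mask = a1.valid & a2.valid
    np.testing.assert_allclose((a1.values + a2.values)[mask], 180.0, atol=1e-9)


def test_angle_masks_zero_speed_and_coincident():
    pos = np.zeros((2, 4, 2))
    pos[1, :] = [10.0, 0.0]
    ang = pair_angle(build_traj(pos))  # both stationary
    assert not ang.valid.any()


# ---------------------------------------------------------------------------
# Static group centre


def test_center_two_stationary_agents():
    pos = np.zeros((2, 6, 2))
    pos[1, :] = [100.0, 0.0]
    np.testing.assert_allclose(
        static_group_center(build_traj(pos, with_velocity=False)), [50.0, 0.0]
    )


def test_center_full_circle_symmetry():
    t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    pos = np.stack([np.column_stack([200 + 80 * np.cos(t), 300 + 80 * np.sin(t)])])
    c = static_group_center(build_traj(pos, with_velocity=False))
    np.testing.assert_allclose(c, [200.0, 300.0], atol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_center_matches_brute_force(seed):
    traj = random_traj(np.random.default_rng(seed), n=3, t=40)
    np.testing.assert_allclose(
        static_group_center(traj), brute_force_center(traj.positions), atol=1e-9
    )


# ---------------------------------------------------------------------------
# Angular momentum


def _single_agent_momentum(radial, velocity):
    """m at frame 1 for an agent at center+radial moving with `velocity`."""
    dt = 0.05
    pos = np.zeros((1, 2, 2))
    pos[0, 1] = radial
    pos[0, 0] = np.asarray(radial, dtype=float) - np.asarray(velocity) * dt
    mom = angular_momentum(build_traj(pos, dt=dt), center=(0.0, 0.0))
    return mom.values[0, 1]


def test_momentum_tangential_radial_diagonal():
    assert _single_agent_momentum((100, 0), (0, 50)) == pytest.approx(1.0, abs=1e-12)
    assert _single_agent_momentum((100, 0), (70, 0)) == pytest.approx(0.0, abs=1e-12)
    assert _single_agent_momentum((100, 0), (50, 50)) == pytest.approx(
        np.sqrt(2) / 2, abs=1e-12
    )


def test_momentum_speed_rescaling_invariance():
    """m uses unit vectors only: scaling all speeds leaves it unchanged."""
    traj = random_traj(np.random.default_rng(1), n=4, t=50)
    scaled = build_traj(traj.positions, with_velocity=False)
    scaled.velocities = 3.7 * traj.velocities
    m1 = angular_momentum(traj)
    m2 = angular_momentum(scaled, center=m1.group_center)
    np.testing.assert_allclose(m1.values[m1.valid], m2.values[m2.valid], atol=1e-9)


def test_momentum_rigid_motion_invariance():
    """Global rotation + translation (centre recomputed) leaves m unchanged."""
    traj = random_traj(np.random.default_rng(2), n=4, t=50)
    ang = 0.77
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    moved = build_traj(traj.positions @ rot.T + np.array([123.0, -45.0]))
    m1, m2 = angular_momentum(traj), angular_momentum(moved)
    assert (m1.valid == m2.valid).all()
    np.testing.assert_allclose(m1.values[m1.valid], m2.values[m2.valid], atol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_momentum_matches_brute_force(seed):
    traj = random_traj(np.random.default_rng(seed), n=5, t=50)
    mom = angular_momentum(traj)
    ref = brute_force_momentum(traj.positions, traj.velocities, mom.group_center)
    np.testing.assert_allclose(mom.values[mom.valid], ref[mom.valid], atol=1e-9)
    assert np.isnan(ref[~mom.valid]).all()


# ---------------------------------------------------------------------------
# Summaries


def test_activity_amount_uniform_and_stationary():
    t = np.arange(10) * 0.05
    pos = np.stack(
        [np.column_stack([100 * t, np.zeros(10)]), np.zeros((10, 2))]
    )
    amounts = activity_amount(build_traj(pos))
    assert amounts["c1"] == pytest.approx(100.0)
    assert amounts["c2"] == pytest.approx(0.0)


def test_activity_amount_piecewise_mean():
    """Speeds 50 then 150 over equal frame counts average to 100."""
    dt = 0.05
    x = np.concatenate([[0], np.cumsum([50 * dt] * 10 + [150 * dt] * 10)])
    pos = np.stack([np.column_stack([x, np.zeros(len(x))])])
    assert activity_amount(build_traj(pos, dt=dt))["c1"] == pytest.approx(100.0)


def test_group_momentum_means_and_oracle():
    traj = random_traj(np.random.default_rng(8), n=4, t=30)
    mom = angular_momentum(traj)
    g = group_angular_momentum(mom)
    for frame in range(traj.n_frames):
        vals = [
            mom.values[k, frame] for k in range(4) if mom.valid[k, frame]
        ]
        if vals:
            assert g[frame] == pytest.approx(np.mean(vals), abs=1e-9)
        else:
            assert np.isnan(g[frame])


def test_group_momentum_half_tangential_half_radial():
    dt = 0.05
    pos = np.zeros((2, 2, 2))
    pos[0, 1] = [100, 0]
    pos[0, 0] = [100, -50 * dt]  # tangential
    pos[1, 1] = [0, 100]
    pos[1, 0] = [0, 100 - 50 * dt]  # radial
    mom = angular_momentum(build_traj(pos, dt=dt), center=(0.0, 0.0))
    g = group_angular_momentum(mom)
    assert g[1] == pytest.approx(0.5, abs=1e-12)
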