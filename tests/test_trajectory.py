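"""Ingestion: CSV round trips, homography calibration, resampling, velocity."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from groupmotion.trajectory import (
    CalibrationError,
    ParseError,
    RawDigitization,
    compute_velocity,
    fit_projective_transform,
    read_session,
    read_trajectory,
    resample_spline,
    write_session,
    write_trajectory,
)

from conftest import build_traj


# ---------------------------------------------------------------------------
# CSV reading and writing


def test_read_session_identity(tmp_path):
    """A complete 3-row, 2-individual CSV reads back exactly."""
    p = tmp_path / "s.csv"
    p.write_text(
        "time,a_x,a_y,b_x,b_y\n0.0,1.0,2.0,3.0,4.0\n0.2,1.5,2.5,3.5,4.5\n0.4,2.0,3.0,4.0,5.0\n"
    )
    raw = read_session(p)
    assert raw.individuals == ["a", "b"]
    assert raw.sample_interval == pytest.approx(0.2)
    np.testing.assert_allclose(raw.positions["a"], [[1, 2], [1.5, 2.5], [2, 3]])
    np.testing.assert_allclose(raw.positions["b"][:, 0], [3, 3.5, 4])


def test_read_session_preserves_gap(tmp_path):
    """An empty x cell becomes an explicit NaN gap, never a zero."""
    p = tmp_path / "s.csv"
    p.write_text("time,a_x,a_y\n0.0,1.0,2.0\n0.2,,2.5\n0.4,2.0,3.0\n")
    raw = read_session(p)
    assert np.isnan(raw.positions["a"][1, 0])
    assert raw.positions["a"][1, 1] == 2.5


def test_read_session_rejects_non_monotone_time(tmp_path):
    p = tmp_path / "s.csv"
    p.write_text("time,a_x,a_y\n0.0,1,1\n0.4,2,2\n0.2,3,3\n")
    with pytest.raises(ParseError, match="increasing"):
        read_session(p)


def test_read_session_names_bad_row(tmp_path):
    p = tmp_path / "s.csv"
    p.write_text("time,a_x,a_y\n0.0,1,1\n0.2,oops,2\n")
    with pytest.raises(ParseError, match="row 3"):
        read_session(p)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_ind=hst.integers(1, 4),
    n_samp=hst.integers(2, 12),
    seed=hst.integers(0, 10_000),
)
def test_session_round_trip(tmp_path_factory, n_ind, n_samp, seed):
    """write_session then read_session reproduces values to 1e-9."""
    rng = np.random.default_rng(seed)
    times = np.cumsum(rng.uniform(0.05, 0.5, n_samp))
    positions = {
        f"kid{k}": rng.uniform(-1000, 1000, size=(n_samp, 2)) for k in range(n_ind)
    }
    raw = RawDigitization(sample_interval=0.2, times=times, positions=positions)
    path = tmp_path_factory.mktemp("rt") / "s.csv"
    write_session(raw, path)
    back = read_session(path)
    np.testing.assert_allclose(back.times, times, atol=1e-9)
    for k in positions:
        np.testing.assert_allclose(back.positions[k], positions[k], atol=1e-9)


def test_trajectory_round_trip(tmp_path):
    traj = build_traj(np.random.default_rng(0).uniform(0, 900, (3, 20, 2)))
    path = tmp_path / "t.csv"
    write_trajectory(traj, path, include_velocity=True)
    back = read_trajectory(path)
    assert back.individuals == traj.individuals
    np.testing.assert_allclose(back.positions, traj.positions, atol=1e-6)


# ---------------------------------------------------------------------------
# Projective calibration


SQUARE = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 80.0], [0.0, 80.0]])


def test_homography_identity():
    cmap = fit_projective_transform(SQUARE, SQUARE)
    m = cmap.matrix / cmap.matrix[2, 2]
    np.testing.assert_allclose(m, np.eye(3), atol=1e-9)


def test_homography_translation():
    cmap = fit_projective_transform(SQUARE, SQUARE + [10.0, -5.0])
    m = cmap.matrix / cmap.matrix[2, 2]
    np.testing.assert_allclose(m[:2, 2], [10.0, -5.0], atol=1e-8)
    np.testing.assert_allclose(m[:2, :2], np.eye(2), atol=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_homography_synthesize_then_recover(seed):
    """A random non-degenerate homography is recovered up to scale."""
    rng = np.random.default_rng(seed)
    true = np.eye(3) + rng.uniform(-0.2, 0.2, (3, 3))
    true[2, 2] = 1.0
    src = SQUARE + rng.uniform(-5, 5, SQUARE.shape)
    homo = np.column_stack([src, np.ones(4)]) @ true.T
    dst = homo[:, :2] / homo[:, 2:3]
    cmap = fit_projective_transform(src, dst)
    np.testing.assert_allclose(
        cmap.matrix / cmap.matrix[2, 2], true / true[2, 2], atol=1e-6
    )


def test_homography_degenerate_rejected():
    collinear = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 5.0]])
    with pytest.raises(CalibrationError):
        fit_projective_transform(collinear, SQUARE)


def test_homography_round_trip():
    """matrix then inverse returns the pixel points within 1e-6."""
    rng = np.random.default_rng(3)
    dst = SQUARE * 8.7 + rng.uniform(-3, 3, SQUARE.shape)
    cmap = fit_projective_transform(SQUARE, dst)
    pts = rng.uniform(0, 100, (20, 2))
    np.testing.assert_allclose(cmap.to_image(cmap.to_floor(pts)), pts, atol=1e-6)


# ---------------------------------------------------------------------------
# Spline resampling


def _raw_from_fn(fn, t_end=2.0, dt=0.2):
    times = np.arange(0, t_end + 1e-9, dt)
    return RawDigitization(
        sample_interval=dt, times=times, positions={"a": fn(times)}
    )


def test_resample_linear_invariance():
    """Straight-line constant-speed samples resample onto the same line."""
    raw = _raw_from_fn(lambda t: np.column_stack([100 * t, 50 * t + 7]))
    traj = resample_spline(raw, frame_interval=0.05)
    t = traj.times
    np.testing.assert_allclose(traj.positions[0, :, 0], 100 * t, atol=1e-9)
    np.testing.assert_allclose(traj.positions[0, :, 1], 50 * t + 7, atol=1e-9)


def test_resample_parabola_exact():
    """A cubic spline reproduces a degree-2 polynomial at off-sample times."""
    raw = _raw_from_fn(lambda t: np.column_stack([3 * t**2 - 2 * t + 1, -t**2 + 4]))
    traj = resample_spline(raw, frame_interval=0.05)
    t = traj.times
    np.testing.assert_allclose(traj.positions[0, :, 0], 3 * t**2 - 2 * t + 1, atol=1e-9)
    np.testing.assert_allclose(traj.positions[0, :, 1], -(t**2) + 4, atol=1e-9)


def test_resample_passes_through_samples():
    """The interpolant hits the raw samples exactly at their times."""
    rng = np.random.default_rng(5)
    raw = _raw_from_fn(lambda t: rng.uniform(0, 800, (len(t), 2)))
    traj = resample_spline(raw, frame_interval=0.05)
    raw_idx = (raw.times / 0.05).round().astype(int)
    np.testing.assert_allclose(traj.positions[0, raw_idx], raw.positions["a"], atol=1e-9)


def test_resample_sinusoid_close_to_dense_reference():
    """0.2 s samples of a sinusoidal path stay near the true curve.

    Tolerance from the cubic-interpolation error bound (5/384) h^4 max|f''''|
    on interior intervals; end intervals are covered by a dense numerical
    reference evaluation.
    """
    omega = 2 * np.pi / 1.6
    fn = lambda t: np.column_stack([200 * np.cos(omega * t), 120 * np.sin(omega * t)])
    raw = _raw_from_fn(fn, t_end=4.0)
    traj = resample_spline(raw, frame_interval=0.05)
    truth = fn(traj.times)
    max_dev = np.abs(traj.positions[0] - truth).max()
    bound = (5 / 384) * 0.2**4 * 200 * omega**4 * 3  # slack for end conditions
    assert max_dev < bound


def test_resample_excludes_short_tracks(caplog):
    """Individuals with < 4 valid samples are dropped with a logged warning."""
    times = np.arange(0, 1.01, 0.2)
    good = np.column_stack([times * 10, times * 5])
    bad = good.copy()
    bad[2:, :] = np.nan  # only 2 valid samples
    raw = RawDigitization(
        sample_interval=0.2, times=times, positions={"ok": good, "short": bad}
    )
    with caplog.at_level(logging.WARNING):
        traj = resample_spline(raw)
    assert traj.individuals == ["ok"]
    assert any("short" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# Velocity


def test_velocity_stationary_and_uniform():
    stat = build_traj(np.zeros((1, 10, 2)))
    np.testing.assert_allclose(stat.velocities[0, 1:], 0.0)
    t = np.arange(10) * 0.05
    uni = build_traj(np.stack([np.column_stack([100 * t, np.zeros(10)])]))
    np.testing.assert_allclose(uni.velocities[0, 1:, 0], 100.0, atol=1e-9)
    np.testing.assert_allclose(uni.velocities[0, 1:, 1], 0.0, atol=1e-9)
    assert np.isnan(uni.velocities[0, 0]).all()  # backward scheme: no first-frame v


def test_velocity_circular_speed_bound():
    """Backward-difference speed on a circle is Rw within 0.5*R*w^2*dt."""
    R, omega, dt = 150.0, 1.3, 0.05
    t = np.arange(0, 3, dt)
    pos = np.stack([np.column_stack([R * np.cos(omega * t), R * np.sin(omega * t)])])
    traj = build_traj(pos, dt=dt)
    speed = traj.speed()[0, 1:]
    assert np.abs(speed - R * omega).max() <= 0.5 * R * omega**2 * dt


def test_velocity_time_reversal():
    """Reversing time negates the (reversed) velocity sequence."""
    rng = np.random.default_rng(9)
    pos = np.cumsum(rng.normal(0, 5, (2, 30, 2)), axis=1)
    fwd = build_traj(pos)
    rev = build_traj(pos[:, ::-1])
    v_rev_expected = -fwd.velocities[:, ::-1][:, :-1]
    np.testing.assert_allclose(rev.velocities[:, 1:], v_rev_expected, atol=1e-9)
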