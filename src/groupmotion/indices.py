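"""Movement indices of collective free-running activity.

Three per-frame indices summarise how a group of N individuals moves:

* pairwise distance ``|d_ij(t)|`` (cm), symmetric;
* heading angle ``theta_ij(t)`` (degrees, [0, 180]): the angle between
  individual i's velocity and the line of sight from i to j — 0 means i is
  running straight at j;
* angular momentum ``m_i(t)`` in [0, 1]: the magnitude of the 2-D cross
  product of the unit radial vector (from the static group centre to i) and
  i's unit velocity — 1 is pure rotation around the centre, 0 pure radial
  motion.

The static group centre is the time-average over the session of the
per-frame centroid of all individuals.  Frames where a unit vector is
undefined (zero speed, individual at the centre, no velocity at the first
frame) are masked invalid rather than assigned a value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import TrajectorySet

__all__ = [
    "PairSeries",
    "AngularMomentumSet",
    "pair_distance",
    "pair_angle",
    "static_group_center",
    "angular_momentum",
    "activity_amount",
    "group_angular_momentum",
    "pair_series_frame",
]


@dataclass
class PairSeries:
    """Per-frame values for pairs of individuals.

    ``kind`` is ``"distance"`` (unordered pairs, cm) or ``"angle"`` (ordered
    pairs, degrees in [0, 180]).  ``values`` and ``valid`` are ``(P, T)``
    aligned with ``pairs``.
    """

    kind: str
    individuals: list[str]
    pairs: list[tuple[str, str]]
    values: np.ndarray
    valid: np.ndarray
    frame_interval: float
    _lookup: dict[tuple[str, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.shape[0] != len(self.pairs):
            raise ValueError("values/valid must be (n_pairs, n_frames)")
        self._lookup = {p: k for k, p in enumerate(self.pairs)}
        if self.kind == "distance":
            for (i, j), k in list(self._lookup.items()):
                self._lookup.setdefault((j, i), k)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def get(self, i: str, j: str) -> np.ndarray:
        """Value series for pair (i, j); symmetric lookup for distances."""
        return self.values[self._lookup[(i, j)]]

    def get_valid(self, i: str, j: str) -> np.ndarray:
        return self.valid[self._lookup[(i, j)]]

    def has(self, i: str, j: str) -> bool:
        return (i, j) in self._lookup

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: ``frame, time, i, j, value, valid``."""
        frames = np.arange(self.n_frames)
        rows = []
        for k, (i, j) in enumerate(self.pairs):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "time": frames * self.frame_interval,
                        "i": i,
                        "j": j,
                        "value": self.values[k],
                        "valid": self.valid[k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class AngularMomentumSet:
    """Per-individual angular momentum m_i(t) about the static group centre."""

    individuals: list[str]
    values: np.ndarray  # (N, T) in [0, 1] where valid
    valid: np.ndarray  # (N, T)
    group_center: np.ndarray  # (2,) static centre, cm
    frame_interval: float

    def get(self, i: str) -> np.ndarray:
        return self.values[self.individuals.index(i)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: ``frame, time, i, value, valid``."""
        frames = np.arange(self.values.shape[1])
        rows = []
        for k, i in enumerate(self.individuals):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "time": frames * self.frame_interval,
                        "i": i,
                        "value": self.values[k],
                        "valid": self.valid[k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def pair_distance(traj: TrajectorySet) -> PairSeries:
    """Euclidean distance per frame for every unordered pair."""
    if traj.n_individuals < 2:
        raise ValueError("need at least two individuals for pairwise indices")
    pos = traj.positions
    n = traj.n_individuals
    pairs: list[tuple[str, str]] = []
    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            pairs.append((traj.individuals[a], traj.individuals[b]))
            rows.append(np.linalg.norm(pos[a] - pos[b], axis=1))
    values = np.stack(rows)
    return PairSeries(
        kind="distance",
        individuals=list(traj.individuals),
        pairs=pairs,
        values=values,
        valid=np.ones_like(values, dtype=bool),
        frame_interval=traj.frame_interval,
    )


def pair_angle(traj: TrajectorySet) -> PairSeries:
    """Heading angle theta_ij per frame for every ordered pair.

    theta_ij = arccos( v_i . (c_j - c_i) / (|v_i| |c_j - c_i|) ) in degrees,
    with the cosine clipped to [-1, 1]; frames with zero speed, coincident
    positions, or undefined velocity are masked.
    """
    if traj.velocities is None:
        raise ValueError("velocities required; call compute_velocity first")
    pos, vel = traj.positions, traj.velocities
    vel_ok = traj.velocity_valid()
    speed = np.linalg.norm(np.nan_to_num(vel), axis=2)
    n = traj.n_individuals
    pairs: list[tuple[str, str]] = []
    vals, valids = [], []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            los = pos[b] - pos[a]
            sep = np.linalg.norm(los, axis=1)
            ok = vel_ok[a] & (speed[a] > 0) & (sep > 0)
            cosang = np.zeros(traj.n_frames)
            np.divide(
                np.einsum("tk,tk->t", np.nan_to_num(vel[a]), los),
                speed[a] * sep,
                out=cosang,
                where=ok,
            )
            theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            theta[~ok] = np.nan
            pairs.append((traj.individuals[a], traj.individuals[b]))
            vals.append(theta)
            valids.append(ok)
    return PairSeries(
        kind="angle",
        individuals=list(traj.individuals),
        pairs=pairs,
        values=np.stack(vals),
        valid=np.stack(valids),
        frame_interval=traj.frame_interval,
    )


def static_group_center(traj: TrajectorySet) -> np.ndarray:
    """Time-mean over the session of the per-frame centroid of all individuals."""
    return traj.positions.mean(axis=(0, 1))


def angular_momentum(
    traj: TrajectorySet, center: np.ndarray | None = None
) -> AngularMomentumSet:
    """m_i(t) = |u_a x u_v|, the 2-D cross-product magnitude of unit vectors.

    u_a points from the static group centre to the individual, u_v along its
    velocity; m_i equals |sin phi| for phi the angle between them.
    """
    if traj.velocities is None:
        raise ValueError("velocities required; call compute_velocity first")
    if center is None:
        center = static_group_center(traj)
    center = np.asarray(center, dtype=float)
    rel = traj.positions - center
    radius = np.linalg.norm(rel, axis=2)
    vel = np.nan_to_num(traj.velocities)
    speed = np.linalg.norm(vel, axis=2)
    valid = traj.velocity_valid() & (speed > 0) & (radius > 0)
    denom = np.where(valid, radius * speed, 1.0)
    cross = np.abs(rel[:, :, 0] * vel[:, :, 1] - rel[:, :, 1] * vel[:, :, 0]) / denom
    values = np.clip(cross, 0.0, 1.0)
    values[~valid] = np.nan
    return AngularMomentumSet(
        individuals=list(traj.individuals),
        values=values,
        valid=valid,
        group_center=center,
        frame_interval=traj.frame_interval,
    )


def activity_amount(traj: TrajectorySet) -> pd.Series:
    """Mean speed per individual (cm/s) over frames with a defined velocity."""
    speed = traj.speed()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(speed, axis=1)
    return pd.Series(means, index=traj.individuals, name="mean_speed_cm_s")


def group_angular_momentum(momentum: AngularMomentumSet) -> np.ndarray:
    """Per-frame mean of m_i over individuals valid at that frame.

    Frames with no valid individual are NaN.
    """
    counts = momentum.valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(np.where(momentum.valid, momentum.values, 0.0), axis=0)
    out = np.full(momentum.values.shape[1], np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


def pair_series_frame(series: PairSeries) -> pd.DataFrame:
    """Convenience alias for :meth:`PairSeries.to_frame`."""
    return series.to_frame()
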