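"""Reading, calibration, resampling and differentiation of position tracks.

Raw tracks are digitized from overhead video at a coarse cadence (0.2 s in the
study design this package supports), mapped from image pixels to floor
centimetres with a projective (homography) transform, spline-interpolated to a
uniform 0.05 s frame grid, and differentiated to velocities.  The resulting
:class:`TrajectorySet` is the substrate of every downstream index.

CSV layout is wide: one ``time`` column (seconds) plus ``<id>_x``/``<id>_y``
columns in floor centimetres.  Missing samples are empty cells and stay NaN in
memory; they are never silently zero-filled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline
from skimage.transform import ProjectiveTransform

__all__ = [
    "CalibrationError",
    "ParseError",
    "CsvDialect",
    "SessionMeta",
    "CalibrationMap",
    "RawDigitization",
    "TrajectorySet",
    "read_session",
    "write_session",
    "fit_projective_transform",
    "load_calibration",
    "apply_calibration",
    "resample_spline",
    "compute_velocity",
    "read_trajectory",
    "write_trajectory",
    "DEFAULT_FRAME_INTERVAL",
    "DEFAULT_ARENA",
    "VELOCITY_SCHEME",
]

logger = logging.getLogger(__name__)

#: target frame interval of analysis-ready trajectories, seconds
DEFAULT_FRAME_INTERVAL = 0.05
#: arena bounding box (width, height) in cm: 10 m x 8.5 m hall
DEFAULT_ARENA = (1000.0, 850.0)
#: declared finite-difference scheme for velocities ("backward" or "central")
VELOCITY_SCHEME = "backward"
#: individuals missing more than this fraction of raw samples are dropped
MAX_MISSING_FRACTION = 0.10


class ParseError(ValueError):
    """Malformed input file."""


class CalibrationError(ValueError):
    """Degenerate or inconsistent point correspondence."""


@dataclass(frozen=True)
class CsvDialect:
    """Column layout of a wide position CSV.

    ``time_column`` holds seconds; each individual ``<id>`` contributes
    ``<id><x_suffix>`` and ``<id><y_suffix>`` columns in centimetres.
    """

    time_column: str = "time"
    x_suffix: str = "_x"
    y_suffix: str = "_y"


@dataclass(frozen=True)
class SessionMeta:
    """Descriptive metadata of one recorded session."""

    class_label: str = ""
    mean_age: float | None = None
    session_date: str | None = None
    duration: float | None = None
    participant_count: int | None = None


@dataclass(frozen=True)
class CalibrationMap:
    """Projective map from image pixels to floor centimetres.

    ``matrix`` is the 3x3 homography taking homogeneous image points to
    homogeneous floor points; it maps each of the four calibration
    correspondences exactly (within 1e-6 cm) and is invertible.
    """

    image_points: np.ndarray
    floor_points: np.ndarray
    matrix: np.ndarray

    def to_floor(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` pixel coordinates to floor cm."""
        return _apply_homography(self.matrix, np.asarray(points, dtype=float))

    def to_image(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` floor coordinates back to pixels."""
        return _apply_homography(
            np.linalg.inv(self.matrix), np.asarray(points, dtype=float)
        )


@dataclass
class RawDigitization:
    """Per-individual positions at the raw digitization cadence.

    ``positions[id]`` is ``(n, 2)`` aligned with the shared ``times`` vector;
    missing samples are NaN rows (explicit gaps).
    """

    sample_interval: float
    times: np.ndarray
    positions: dict[str, np.ndarray]
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ParseError("time vector must be 1-D and non-empty")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise ParseError(f"times not strictly increasing at sample {bad}")
        for ident, xy in self.positions.items():
            xy = np.asarray(xy, dtype=float)
            if xy.shape != (len(self.times), 2):
                raise ParseError(
                    f"individual {ident!r}: positions shape {xy.shape} does not "
                    f"match {len(self.times)} time samples"
                )
            self.positions[ident] = xy

    @property
    def individuals(self) -> list[str]:
        return list(self.positions)


@dataclass
class TrajectorySet:
    """Analysis-ready positions (and optionally velocities) on a uniform grid.

    ``positions`` is ``(N, T, 2)`` in cm, row order matching ``individuals``.
    ``velocities`` is ``(N, T, 2)`` in cm/s or ``None``; frames without a
    defined velocity under the declared differencing scheme are NaN.
    """

    frame_interval: float
    individuals: list[str]
    positions: np.ndarray
    velocities: np.ndarray | None = None
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.individuals)
        if self.positions.ndim != 3 or self.positions.shape[0] != n or self.positions.shape[2] != 2:
            raise ValueError(
                f"positions must have shape (n_individuals, n_frames, 2); got {self.positions.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def speed(self) -> np.ndarray:
        """``(N, T)`` speed in cm/s (NaN where velocity is undefined)."""
        if self.velocities is None:
            raise ValueError("velocities not computed; call compute_velocity first")
        return np.linalg.norm(self.velocities, axis=2)

    def velocity_valid(self) -> np.ndarray:
        """``(N, T)`` bool mask of frames with a defined velocity."""
        if self.velocities is None:
            raise ValueError("velocities not computed; call compute_velocity first")
        return ~np.isnan(self.velocities).any(axis=2)

    def index_of(self, individual: str) -> int:
        return self.individuals.index(individual)


# ---------------------------------------------------------------------------
# CSV input / output


def _numeric_column(df: pd.DataFrame, name: str, path: str) -> np.ndarray:
    col = df[name]
    try:
        return pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        coerced = pd.to_numeric(col, errors="coerce")
        bad = coerced.isna() & col.notna()
        row = int(np.argmax(bad.to_numpy())) + 2  # header is row 1
        raise ParseError(
            f"{path}: non-numeric value {col[bad.idxmax()]!r} in column "
            f"{name!r} at row {row}"
        ) from None


def read_session(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    meta: SessionMeta | None = None,
) -> RawDigitization:
    """Read a wide position CSV into a :class:`RawDigitization`.

    Empty cells become explicit NaN gaps.  Raises :class:`ParseError` for
    malformed cells (naming the row) or a non-monotone time column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if dialect.time_column not in df.columns:
        raise ParseError(f"{path}: missing time column {dialect.time_column!r}")
    times = _numeric_column(df, dialect.time_column, str(path))
    ids = []
    for col in df.columns:
        if col.endswith(dialect.x_suffix):
            ident = col[: -len(dialect.x_suffix)]
            if ident + dialect.y_suffix in df.columns:
                ids.append(ident)
    if not ids:
        raise ParseError(f"{path}: no <id>{dialect.x_suffix}/<id>{dialect.y_suffix} column pairs")
    positions = {}
    for ident in ids:
        x = _numeric_column(df, ident + dialect.x_suffix, str(path))
        y = _numeric_column(df, ident + dialect.y_suffix, str(path))
        positions[ident] = np.column_stack([x, y])
    interval = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    return RawDigitization(
        sample_interval=interval,
        times=times,
        positions=positions,
        meta=meta or SessionMeta(),
    )


def write_session(
    raw: RawDigitization, path: str | Path, dialect: CsvDialect = CsvDialect()
) -> None:
    """Write a :class:`RawDigitization` back to the wide CSV layout."""
    data: dict[str, np.ndarray] = {dialect.time_column: raw.times}
    for ident, xy in raw.positions.items():
        data[ident + dialect.x_suffix] = xy[:, 0]
        data[ident + dialect.y_suffix] = xy[:, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_trajectory(
    traj: TrajectorySet,
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    include_velocity: bool = False,
) -> None:
    """Write an analysis-ready trajectory to the wide CSV layout.

    With ``include_velocity``, appends ``<id>_vx``/``<id>_vy`` columns.
    """
    data: dict[str, np.ndarray] = {dialect.time_column: traj.times}
    for k, ident in enumerate(traj.individuals):
        data[ident + dialect.x_suffix] = traj.positions[k, :, 0]
        data[ident + dialect.y_suffix] = traj.positions[k, :, 1]
    if include_velocity:
        if traj.velocities is None:
            raise ValueError("trajectory has no velocities")
        for k, ident in enumerate(traj.individuals):
            data[ident + "_vx"] = traj.velocities[k, :, 0]
            data[ident + "_vy"] = traj.velocities[k, :, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_trajectory(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    meta: SessionMeta | None = None,
) -> TrajectorySet:
    """Read a uniform-grid trajectory CSV (velocity columns are ignored)."""
    raw = read_session(path, dialect=dialect, meta=meta)
    # velocity columns round-trip as individuals named "<id>_v"; drop them
    ids = [i for i in raw.individuals if not i.endswith("_v")]
    diffs = np.diff(raw.times)
    if len(diffs) and not np.allclose(diffs, diffs[0], rtol=0, atol=1e-9):
        raise ParseError(f"{path}: frame grid is not uniform")
    positions = np.stack([raw.positions[i] for i in ids])
    return TrajectorySet(
        frame_interval=float(diffs[0]) if len(diffs) else DEFAULT_FRAME_INTERVAL,
        individuals=ids,
        positions=positions,
        meta=meta or raw.meta,
    )


# ---------------------------------------------------------------------------
# Projective calibration


def _apply_homography(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(points)
    homo = np.column_stack([pts, np.ones(len(pts))]) @ matrix.T
    out = homo[:, :2] / homo[:, 2:3]
    return out.reshape(np.shape(points))


def fit_projective_transform(
    image_points: np.ndarray, floor_points: np.ndarray
) -> CalibrationMap:
    """Fit the homography taking four pixel points to four floor points.

    Raises :class:`CalibrationError` when any three points are collinear or
    the fit does not reproduce the correspondences to 1e-6 cm.
    """
    image_points = np.asarray(image_points, dtype=float)
    floor_points = np.asarray(floor_points, dtype=float)
    if image_points.shape != (4, 2) or floor_points.shape != (4, 2):
        raise CalibrationError("calibration needs exactly four 2-D point pairs")
    for pts in (image_points, floor_points):
        for drop in range(4):
            tri = np.delete(pts, drop, axis=0)
            u, v = tri[1] - tri[0], tri[2] - tri[0]
            area = u[0] * v[1] - u[1] * v[0]
            if abs(area) < 1e-9:
                raise CalibrationError("three calibration points are collinear")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(image_points, floor_points)
        if not tf:
            raise CalibrationError("homography estimation failed")
    else:  # scikit-image < 0.26
        tf = ProjectiveTransform()
        if not tf.estimate(image_points, floor_points):
            raise CalibrationError("homography estimation failed")
    matrix = np.asarray(tf.params, dtype=float)
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise CalibrationError("homography is singular")
    mapped = _apply_homography(matrix, image_points)
    err = np.abs(mapped - floor_points).max()
    if err > 1e-6:
        raise CalibrationError(f"homography residual {err:.2e} cm exceeds 1e-6")
    return CalibrationMap(image_points=image_points, floor_points=floor_points, matrix=matrix)


def load_calibration(path: str | Path) -> CalibrationMap:
    """Load a YAML/JSON file with ``image_points`` and ``floor_points``."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return fit_projective_transform(
        np.asarray(data["image_points"], dtype=float),
        np.asarray(data["floor_points"], dtype=float),
    )


def apply_calibration(raw: RawDigitization, cmap: CalibrationMap) -> RawDigitization:
    """Map every raw position from image pixels to floor centimetres."""
    out = {}
    for ident, xy in raw.positions.items():
        mapped = np.full_like(xy, np.nan)
        ok = ~np.isnan(xy).any(axis=1)
        if ok.any():
            mapped[ok] = cmap.to_floor(xy[ok])
        out[ident] = mapped
    return replace(raw, positions=out)


# ---------------------------------------------------------------------------
# Resampling and differentiation


def resample_spline(
    raw: RawDigitization,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    bc_type: str = "not-a-knot",
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> TrajectorySet:
    """Cubic-spline interpolate raw samples onto a uniform frame grid.

    The interpolant passes through the raw samples exactly at their times.
    Individuals with fewer than four valid samples (cubic support) or missing
    more than ``max_missing_fraction`` of samples are excluded with a logged
    warning, never silently.
    """
    t0, t1 = raw.times[0], raw.times[-1]
    n_frames = int(round((t1 - t0) / frame_interval)) + 1
    grid = t0 + np.arange(n_frames) * frame_interval
    kept: list[str] = []
    tracks: list[np.ndarray] = []
    for ident, xy in raw.positions.items():
        ok = ~np.isnan(xy).any(axis=1)
        missing = 1.0 - ok.mean()
        if missing > max_missing_fraction:
            logger.warning(
                "individual %r missing %.0f%% of samples (> %.0f%%); excluded",
                ident, 100 * missing, 100 * max_missing_fraction,
            )
            continue
        if ok.sum() < 4:
            logger.warning(
                "individual %r has %d valid samples (< 4 needed for a cubic spline); excluded",
                ident, int(ok.sum()),
            )
            continue
        spline = CubicSpline(raw.times[ok], xy[ok], bc_type=bc_type, axis=0)
        tracks.append(spline(grid))
        kept.append(ident)
    if not kept:
        raise ValueError("no individual has enough samples to resample")
    meta = raw.meta
    if meta.duration is None:
        meta = replace(meta, duration=float(grid[-1] - grid[0]), participant_count=len(kept))
    return TrajectorySet(
        frame_interval=frame_interval,
        individuals=kept,
        positions=np.stack(tracks),
        meta=meta,
    )


def compute_velocity(traj: TrajectorySet, scheme: str = VELOCITY_SCHEME) -> TrajectorySet:
    """Fill velocities by finite differences on the uniform grid.

    ``backward`` (default): v(t) = (c(t) - c(t-1)) / dt, first frame NaN.
    ``central``: v(t) = (c(t+1) - c(t-1)) / (2 dt), both end frames NaN.
    """
    pos = traj.positions
    vel = np.full_like(pos, np.nan)
    dt = traj.frame_interval
    if scheme == "backward":
        vel[:, 1:] = (pos[:, 1:] - pos[:, :-1]) / dt
    elif scheme == "central":
        vel[:, 1:-1] = (pos[:, 2:] - pos[:, :-2]) / (2 * dt)
    else:
        raise ValueError(f"unknown differencing scheme {scheme!r}")
    return TrajectorySet(
        frame_interval=traj.frame_interval,
        individuals=list(traj.individuals),
        positions=pos,
        velocities=vel,
        meta=traj.meta,
    )
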