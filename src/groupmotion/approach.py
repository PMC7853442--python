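"""Approach-event detection and the windowed approaching angle.

An approach event is the first frame at which a pair's inter-distance drops
below 50 cm — the personal-space threshold: a downward crossing, i.e.
d(t0) < 50 with d(t0-1) >= 50.  Each crossing yields two directed candidate
events (i -> j and j -> i); directionality emerges from each member's own
heading angles.

For each event, the heading angle theta_ij is sampled in a look-back window
before the onset (0-1 s, 1-2 s or 2-3 s), restricted to frames where the
inter-distance lies in the 100-200 cm band.  Those samples are the
approaching angles theta'_ij: mass near 0 degrees means the approacher was
running straight at its target in the seconds before contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import PairSeries

__all__ = [
    "ApproachEvent",
    "ApproachSamples",
    "ApproachMatrix",
    "detect_events",
    "approach_angles",
    "approach_matrix",
    "samples_by_child",
    "APPROACH_THRESHOLD",
    "DISTANCE_BAND",
    "WINDOWS",
]

logger = logging.getLogger(__name__)

#: inter-distance (cm) below which an approach has happened
APPROACH_THRESHOLD = 50.0
#: look-back distance band (cm): samples must satisfy lo <= d < hi
DISTANCE_BAND = (100.0, 200.0)
#: the three look-back windows, seconds before onset
WINDOWS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0))


@dataclass(frozen=True)
class ApproachEvent:
    """A directed candidate approach: ``approacher`` closed on ``target``."""

    approacher: str
    target: str
    onset_frame: int


@dataclass
class ApproachSamples:
    """theta' samples per directed pair for one look-back window.

    ``samples[(i, j)]`` is a list of ``(frame, theta_deg)`` tuples recording
    provenance: every sample's source frame lies inside the window before
    some i->j onset and inside the distance band.
    """

    window: tuple[float, float]
    band: tuple[float, float]
    frame_interval: float
    samples: dict[tuple[str, str], list[tuple[int, float]]] = field(default_factory=dict)

    def angles(self, i: str, j: str) -> np.ndarray:
        return np.array([a for _, a in self.samples.get((i, j), [])], dtype=float)

    def all_angles(self) -> np.ndarray:
        out = [a for vals in self.samples.values() for _, a in vals]
        return np.array(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, j, f"{self.window[0]:g}-{self.window[1]:g}", f, a)
            for (i, j), vals in sorted(self.samples.items())
            for f, a in vals
        ]
        return pd.DataFrame(
            rows, columns=["approacher", "target", "window", "frame", "theta_deg"]
        )


@dataclass
class ApproachMatrix:
    """Directed-pair normalized frequencies of one theta' bin.

    ``cells[r, c]`` is the share of approacher ``labels[r]``'s theta' samples
    that fall in the bin while approaching ``labels[c]`` (row-normalized by
    the approacher's total samples over all targets).  Diagonal is zero.
    """

    labels: list[str]
    cells: np.ndarray
    bin_edges: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.labels, columns=self.labels)


def detect_events(
    distances: PairSeries, threshold: float = APPROACH_THRESHOLD
) -> list[ApproachEvent]:
    """Find all downward threshold crossings; two directed events per crossing.

    A pair already below the threshold at frame 0 produces no onset — an
    event requires a crossing.
    """
    if distances.kind != "distance":
        raise ValueError("detect_events expects a distance PairSeries")
    events: list[ApproachEvent] = []
    for k, (i, j) in enumerate(distances.pairs):
        d = distances.values[k]
        below = d < threshold
        onsets = np.flatnonzero(below[1:] & ~below[:-1]) + 1
        for t0 in onsets:
            events.append(ApproachEvent(i, j, int(t0)))
            events.append(ApproachEvent(j, i, int(t0)))
    events.sort(key=lambda e: (e.onset_frame, e.approacher, e.target))
    return events


def approach_angles(
    events: list[ApproachEvent],
    angles: PairSeries,
    distances: PairSeries,
    window: tuple[float, float] = WINDOWS[0],
    band: tuple[float, float] = DISTANCE_BAND,
) -> ApproachSamples:
    """Collect theta' samples for each directed pair in one look-back window.

    For each event with onset t0, frames t in [t0 - w_hi, t0 - w_lo) (in
    seconds; half-open, onset excluded) contribute theta_ij(t) whenever
    band_lo <= d_ij(t) < band_hi and theta_ij(t) is valid.  Windows that
    precede the session start are truncated with a logged notice.
    """
    if angles.kind != "angle" or distances.kind != "distance":
        raise ValueError("approach_angles expects angle and distance PairSeries")
    dt = angles.frame_interval
    w_lo, w_hi = window
    lo_f = int(round(w_lo / dt))
    hi_f = int(round(w_hi / dt))
    out = ApproachSamples(window=window, band=band, frame_interval=dt)
    for ev in events:
        start = ev.onset_frame - hi_f
        stop = ev.onset_frame - lo_f
        if start < 0:
            logger.info(
                "event %s->%s at frame %d: look-back window truncated at session start",
                ev.approacher, ev.target, ev.onset_frame,
            )
            start = 0
        if stop <= start:
            continue
        d = distances.get(ev.approacher, ev.target)[start:stop]
        th = angles.get(ev.approacher, ev.target)[start:stop]
        ok = (
            distances.get_valid(ev.approacher, ev.target)[start:stop]
            & angles.get_valid(ev.approacher, ev.target)[start:stop]
            & (d >= band[0])
            & (d < band[1])
        )
        if ok.any():
            bucket = out.samples.setdefault((ev.approacher, ev.target), [])
            for off in np.flatnonzero(ok):
                bucket.append((start + int(off), float(th[off])))
    return out


def approach_matrix(
    samples: ApproachSamples,
    labels: list[str],
    bin_edges: tuple[float, float] = (10.0, 20.0),
) -> ApproachMatrix:
    """Row-normalized directed-pair frequencies of one theta' bin.

    cell(i, j) = (# i->j samples with bin_lo < theta <= bin_hi) divided by
    the total theta' samples of approacher i over all targets; the first bin
    of the family (lower edge 0) additionally includes theta == 0.  Rows with
    no samples are all-zero.
    """
    lo, hi = bin_edges
    n = len(labels)
    counts = np.zeros((n, n))
    totals = np.zeros(n)
    idx = {lab: k for k, lab in enumerate(labels)}
    for (i, j), vals in samples.samples.items():
        if i not in idx or j not in idx:
            continue
        th = np.array([a for _, a in vals], dtype=float)
        totals[idx[i]] += len(th)
        in_bin = (th > lo) & (th <= hi)
        if lo <= 0:
            in_bin |= th == lo
        counts[idx[i], idx[j]] += in_bin.sum()
    cells = np.zeros((n, n))
    np.divide(counts, totals[:, None], out=cells, where=totals[:, None] > 0)
    np.fill_diagonal(cells, 0.0)
    return ApproachMatrix(labels=list(labels), cells=cells, bin_edges=bin_edges)


def samples_by_child(samples: ApproachSamples) -> dict[str, np.ndarray]:
    """Pool each approacher's theta' samples over all targets."""
    pooled: dict[str, list[float]] = {}
    for (i, _j), vals in samples.samples.items():
        pooled.setdefault(i, []).extend(a for _, a in vals)
    return {i: np.array(v, dtype=float) for i, v in pooled.items()}
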