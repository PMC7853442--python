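"""Per-individual normalized histograms and per-bin group comparison.

Each individual contributes one probability vector per index (bin counts
divided by that individual's total samples), so children with different
amounts of activity weigh equally.  Classes are compared bin by bin with a
pooled-variance two-sample Student t-test at the 5% level, Bonferroni
corrected over the bin family, and the effect size is Hedges' g computed as
the pooled-SD standardized mean difference *without* the small-sample J
correction, so that |g| = |t| * sqrt(1/n_a + 1/n_b) holds exactly.

Sign convention: class A first (the younger class in the motivating study),
so a negative t means class B has the higher mean frequency in that bin.

Binning convention: bins are left-open/right-closed and labeled by their
upper edge ("50 cm" is (0, 50]); the first bin additionally includes its
lower edge so a 0-degree or 0-cm sample is counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import AngularMomentumSet, PairSeries

__all__ = [
    "BinSpec",
    "ChildHistogram",
    "GroupComparison",
    "per_child_histogram",
    "class_mean_histogram",
    "compare_bin",
    "compare_histograms",
    "comparisons_frame",
    "hedges_g_from_t",
    "distance_samples_by_child",
    "angle_samples_by_child",
    "momentum_samples_by_child",
]

#: default extent of the distance bin family (cm); covers the arena diagonal
DISTANCE_MAX_EDGE = 1350.0
DISTANCE_BIN_WIDTH = 50.0


@dataclass(frozen=True)
class BinSpec:
    """A fixed bin family for one index kind.

    ``edges`` are strictly increasing; bin k is (edges[k], edges[k+1]],
    except bin 0 which is [edges[0], edges[1]].  Samples above the last edge
    go to an overflow bin that is included in normalization but excluded
    from statistical testing.
    """

    index_kind: str
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        return [f"{e:g}" for e in self.edges[1:]]

    def assign(self, samples: np.ndarray) -> np.ndarray:
        """Bin index per sample; -1 below range, n_bins for overflow."""
        x = np.asarray(samples, dtype=float)
        edges = np.asarray(self.edges)
        idx = np.searchsorted(edges, x, side="left") - 1
        idx[x == edges[0]] = 0  # first bin includes its lower edge
        idx[x > edges[-1]] = self.n_bins
        return idx

    @classmethod
    def distance(
        cls, max_edge: float = DISTANCE_MAX_EDGE, width: float = DISTANCE_BIN_WIDTH
    ) -> "BinSpec":
        n = int(round(max_edge / width))
        return cls("distance", tuple(width * k for k in range(n + 1)))

    @classmethod
    def angle(cls) -> "BinSpec":
        return cls("angle", tuple(float(10 * k) for k in range(19)))

    @classmethod
    def approach_angle(cls) -> "BinSpec":
        return cls("approach_angle", tuple(float(10 * k) for k in range(19)))

    @classmethod
    def momentum(cls) -> "BinSpec":
        return cls("momentum", tuple(round(0.1 * k, 10) for k in range(11)))


@dataclass
class ChildHistogram:
    """One individual's normalized frequencies over a bin family.

    ``frequencies`` has one entry per regular bin; ``overflow`` holds the
    share of samples above the last edge.  Together they sum to 1 when
    ``n_samples > 0``.
    """

    individual: str
    bin_spec: BinSpec
    frequencies: np.ndarray
    overflow: float
    n_samples: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.n_samples > 0:
            total = self.frequencies.sum() + self.overflow
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")


@dataclass
class GroupComparison:
    """Per-bin between-class test result."""

    bin_label: str
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    t: float
    df: int
    p_raw: float
    p_corrected: float
    g: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


def per_child_histogram(
    samples: Iterable[float], spec: BinSpec, individual: str = ""
) -> ChildHistogram:
    """Normalized histogram of one individual's samples over ``spec``.

    Zero samples yield an all-zero histogram with ``n_samples == 0``; such
    histograms are excluded from group comparison downstream.
    """
    x = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples,
                   dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    counts = np.zeros(spec.n_bins)
    overflow = 0.0
    if n:
        idx = spec.assign(x)
        if np.any(idx < 0):
            raise ValueError("sample below the first bin edge")
        over = int((idx == spec.n_bins).sum())
        core = np.bincount(idx[idx < spec.n_bins], minlength=spec.n_bins)
        counts = core / n
        overflow = over / n
    return ChildHistogram(
        individual=individual,
        bin_spec=spec,
        frequencies=counts,
        overflow=overflow,
        n_samples=n,
    )


def class_mean_histogram(
    histograms: Sequence[ChildHistogram],
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-bin mean and standard error over individuals.

    SE is the sample standard deviation (ddof=1) divided by sqrt(n).
    """
    hists = [h for h in histograms if h.n_samples > 0]
    if len(hists) < 2:
        raise ValueError("need at least two non-empty histograms")
    mat = np.stack([h.frequencies for h in hists])
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / math.sqrt(len(hists))
    return mean, se


def hedges_g_from_t(t: float, n_a: int, n_b: int) -> float:
    """|g| from the t statistic: |t| * sqrt(1/n_a + 1/n_b).

    Algebraic identity of the pooled-SD standardized mean difference without
    small-sample correction.
    """
    return abs(t) * math.sqrt(1.0 / n_a + 1.0 / n_b)


def compare_bin(
    freqs_a: Sequence[float],
    freqs_b: Sequence[float],
    n_bins_family: int,
    bin_label: str = "",
) -> GroupComparison:
    """Pooled-variance two-sample Student t-test for one bin.

    ``freqs_a``/``freqs_b`` are the per-individual normalized frequencies of
    the bin in each class.  p is Bonferroni-multiplied by the family size and
    capped at 1.  Zero pooled variance yields t = 0 for equal means and
    signed infinity otherwise (flagged, p_raw = 0).
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each class needs at least two individuals")
    df = n_a + n_b - 2
    mean_a, mean_b = a.mean(), b.mean()
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    diff = mean_a - mean_b
    scale = math.sqrt(1.0 / n_a + 1.0 / n_b)
    if sp2 == 0:
        if diff == 0:
            t, g, p_raw = 0.0, 0.0, 1.0
        else:
            t = math.copysign(math.inf, diff)
            g = math.copysign(math.inf, diff)
            p_raw = 0.0
    else:
        sp = math.sqrt(sp2)
        t = diff / (sp * scale)
        g = diff / sp
        p_raw = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        bin_label=bin_label,
        mean_a=float(mean_a),
        se_a=float(np.std(a, ddof=1) / math.sqrt(n_a)),
        mean_b=float(mean_b),
        se_b=float(np.std(b, ddof=1) / math.sqrt(n_b)),
        t=float(t),
        df=df,
        p_raw=float(p_raw),
        p_corrected=float(min(1.0, p_raw * n_bins_family)),
        g=float(g),
        n_a=n_a,
        n_b=n_b,
    )


def compare_histograms(
    hists_a: Sequence[ChildHistogram],
    hists_b: Sequence[ChildHistogram],
) -> list[GroupComparison]:
    """Per-bin comparison of two classes of child histograms.

    Individuals with zero samples are excluded (they carry no frequency
    vector); the Bonferroni family is the number of regular bins in the
    shared bin spec.  The overflow bin is not tested.
    """
    hists_a = [h for h in hists_a if h.n_samples > 0]
    hists_b = [h for h in hists_b if h.n_samples > 0]
    if not hists_a or not hists_b:
        raise ValueError("both classes need non-empty histograms")
    spec = hists_a[0].bin_spec
    for h in hists_a + hists_b:
        if h.bin_spec != spec:
            raise ValueError("all histograms must share one bin spec")
    mat_a = np.stack([h.frequencies for h in hists_a])
    mat_b = np.stack([h.frequencies for h in hists_b])
    out = []
    for k, label in enumerate(spec.labels):
        out.append(compare_bin(mat_a[:, k], mat_b[:, k], spec.n_bins, bin_label=label))
    return out


_COMPARISON_COLUMNS = (
    "index", "bin", "mean_a", "se_a", "mean_b", "se_b",
    "t", "df", "p_raw", "p_bonferroni", "g",
)


def comparisons_frame(comparisons: Sequence[GroupComparison], index: str = "") -> pd.DataFrame:
    """Tabulate comparisons: ``index,bin,mean_a,se_a,mean_b,se_b,t,df,p_raw,p_bonferroni,g``."""
    if not comparisons:
        return pd.DataFrame(columns=list(_COMPARISON_COLUMNS))
    return pd.DataFrame(
        {
            "index": index,
            "bin": [c.bin_label for c in comparisons],
            "mean_a": [c.mean_a for c in comparisons],
            "se_a": [c.se_a for c in comparisons],
            "mean_b": [c.mean_b for c in comparisons],
            "se_b": [c.se_b for c in comparisons],
            "t": [c.t for c in comparisons],
            "df": [c.df for c in comparisons],
            "p_raw": [c.p_raw for c in comparisons],
            "p_bonferroni": [c.p_corrected for c in comparisons],
            "g": [c.g for c in comparisons],
        }
    )


# ---------------------------------------------------------------------------
# Per-child sample extraction from index series


def distance_samples_by_child(distances: PairSeries) -> dict[str, np.ndarray]:
    """Child i's distance samples: d(i, j, t) over all j != i and valid t.

    Each unordered sample appears in both members' sets.
    """
    out = {}
    for i in distances.individuals:
        chunks = [
            distances.get(i, j)[distances.get_valid(i, j)]
            for j in distances.individuals
            if j != i
        ]
        out[i] = np.concatenate(chunks) if chunks else np.array([])
    return out


def angle_samples_by_child(angles: PairSeries) -> dict[str, np.ndarray]:
    """Child i's heading-angle samples theta_ij over all targets and valid frames."""
    out = {}
    for i in angles.individuals:
        chunks = [
            angles.get(i, j)[angles.get_valid(i, j)]
            for j in angles.individuals
            if j != i
        ]
        out[i] = np.concatenate(chunks) if chunks else np.array([])
    return out


def momentum_samples_by_child(momentum: AngularMomentumSet) -> dict[str, np.ndarray]:
    """Child i's valid m_i samples."""
    return {
        ident: momentum.values[k][momentum.valid[k]]
        for k, ident in enumerate(momentum.individuals)
    }
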