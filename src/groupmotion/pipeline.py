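"""End-to-end orchestration: sessions in, comparison tables and figures out.

The pipeline loads (or accepts) analysis-ready trajectories for two classes,
computes the per-child histograms for all four indices (pair distance,
heading angle, approaching angle, angular momentum), runs the per-bin
between-class comparison, builds the directed-pair approach matrices, and
writes everything as CSV/JSON first with figures as derived artifacts — no
number exists only inside an image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import approach as ap
from . import indices as ix
from . import stats as st
from .trajectory import TrajectorySet, compute_velocity, read_trajectory

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_outputs", "load_config"]

logger = logging.getLogger(__name__)

INDEX_NAMES = ("distance", "angle", "approach_angle", "momentum")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and session."""


@dataclass
class PipelineConfig:
    """Inputs and knobs of one comparison run.

    ``class_a``/``class_b`` are lists of trajectory CSV paths (or in-memory
    :class:`TrajectorySet` objects); class A is conventionally the younger
    group.  ``window`` selects the approach look-back window in seconds.
    """

    class_a: list = field(default_factory=list)
    class_b: list = field(default_factory=list)
    label_a: str = "class_a"
    label_b: str = "class_b"
    window: tuple[float, float] = (0.0, 1.0)
    approach_bin: tuple[float, float] = (10.0, 20.0)
    distance_max_edge: float = st.DISTANCE_MAX_EDGE
    out_dir: str | Path | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "class_a": [str(s) for s in self.class_a],
            "class_b": [str(s) for s in self.class_b],
            "label_a": self.label_a,
            "label_b": self.label_b,
            "window": list(self.window),
            "approach_bin": list(self.approach_bin),
            "distance_max_edge": self.distance_max_edge,
            "out_dir": str(self.out_dir) if self.out_dir else None,
            "seed": self.seed,
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML; paths are checked at run start."""
    data = yaml.safe_load(Path(path).read_text())
    cfg = PipelineConfig(
        class_a=list(data["class_a"]),
        class_b=list(data["class_b"]),
        label_a=data.get("label_a", "class_a"),
        label_b=data.get("label_b", "class_b"),
        window=tuple(data.get("window", (0.0, 1.0))),
        approach_bin=tuple(data.get("approach_bin", (10.0, 20.0))),
        distance_max_edge=float(data.get("distance_max_edge", st.DISTANCE_MAX_EDGE)),
        out_dir=data.get("out_dir"),
        seed=int(data.get("seed", 0)),
    )
    for p in cfg.class_a + cfg.class_b:
        if not isinstance(p, TrajectorySet) and not Path(p).exists():
            raise FileNotFoundError(p)
    return cfg


@dataclass
class SessionResult:
    """Everything computed from one session."""

    name: str
    trajectories: TrajectorySet
    histograms: dict[str, list[st.ChildHistogram]]
    approach_samples: ap.ApproachSamples
    matrix: ap.ApproachMatrix


@dataclass
class ReportBundle:
    """Machine-readable results of one pipeline run."""

    config: PipelineConfig
    sessions_a: list[SessionResult]
    sessions_b: list[SessionResult]
    comparisons: dict[str, list[st.GroupComparison]]
    run_log: dict


def _load(entry, name: str) -> TrajectorySet:
    if isinstance(entry, TrajectorySet):
        traj = entry
    else:
        try:
            traj = read_trajectory(entry)
        except Exception as exc:  # noqa: BLE001 - stage failures must name the session
            raise PipelineError(f"stage=load session={name}: {exc}") from exc
    if traj.velocities is None:
        traj = compute_velocity(traj)
    return traj


def analyze_session(
    traj: TrajectorySet,
    name: str,
    window: tuple[float, float] = (0.0, 1.0),
    approach_bin: tuple[float, float] = (10.0, 20.0),
    distance_max_edge: float = st.DISTANCE_MAX_EDGE,
) -> SessionResult:
    """Compute all indices, per-child histograms and the approach matrix."""
    try:
        dist = ix.pair_distance(traj)
        ang = ix.pair_angle(traj)
        mom = ix.angular_momentum(traj)
        events = ap.detect_events(dist)
        samples = ap.approach_angles(events, ang, dist, window=window)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage=indices session={name}: {exc}") from exc

    specs = {
        "distance": st.BinSpec.distance(max_edge=distance_max_edge),
        "angle": st.BinSpec.angle(),
        "approach_angle": st.BinSpec.approach_angle(),
        "momentum": st.BinSpec.momentum(),
    }
    by_child = {
        "distance": st.distance_samples_by_child(dist),
        "angle": st.angle_samples_by_child(ang),
        "approach_angle": ap.samples_by_child(samples),
        "momentum": st.momentum_samples_by_child(mom),
    }
    histograms = {}
    for index in INDEX_NAMES:
        hists = []
        for ident in traj.individuals:
            vals = by_child[index].get(ident, np.array([]))
            hists.append(st.per_child_histogram(vals, specs[index], individual=ident))
        histograms[index] = hists
    matrix = ap.approach_matrix(samples, traj.individuals, bin_edges=approach_bin)
    return SessionResult(
        name=name,
        trajectories=traj,
        histograms=histograms,
        approach_samples=samples,
        matrix=matrix,
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full comparison; deterministic given inputs and config."""
    if not config.class_a or not config.class_b:
        raise PipelineError("stage=config: both classes need at least one session")

    def _analyze(entries, label):
        results = []
        for k, entry in enumerate(entries):
            name = f"{label}_s{k + 1}"
            traj = _load(entry, name)
            results.append(
                analyze_session(
                    traj,
                    name,
                    window=config.window,
                    approach_bin=config.approach_bin,
                    distance_max_edge=config.distance_max_edge,
                )
            )
        return results

    sessions_a = _analyze(config.class_a, config.label_a)
    sessions_b = _analyze(config.class_b, config.label_b)

    comparisons = {}
    for index in INDEX_NAMES:
        hists_a = [h for s in sessions_a for h in s.histograms[index] if h.n_samples > 0]
        hists_b = [h for s in sessions_b for h in s.histograms[index] if h.n_samples > 0]
        if len(hists_a) < 2 or len(hists_b) < 2:
            # a class where fewer than two children contribute samples (e.g.
            # no approach events at all) cannot be tested; emit an empty table
            logger.warning(
                "index %s: %d vs %d contributing children; comparison empty",
                index, len(hists_a), len(hists_b),
            )
            comparisons[index] = []
            continue
        try:
            comparisons[index] = st.compare_histograms(hists_a, hists_b)
        except ValueError as exc:
            raise PipelineError(f"stage=compare index={index}: {exc}") from exc

    run_log = {
        "config": config.to_dict(),
        "settings": {
            "velocity_scheme": "backward",
            "approach_threshold_cm": ap.APPROACH_THRESHOLD,
            "distance_band_cm": list(ap.DISTANCE_BAND),
            "window_s": list(config.window),
            "approach_matrix_bin_deg": list(config.approach_bin),
            "hedges_g_small_sample_correction": False,
            "t_test": "pooled-variance two-sample Student",
            "bonferroni_family": {index: len(comparisons[index]) for index in INDEX_NAMES},
            "histogram_first_bin_includes_lower_edge": True,
        },
        "sessions": {
            "class_a": [s.name for s in sessions_a],
            "class_b": [s.name for s in sessions_b],
        },
    }
    bundle = ReportBundle(
        config=config,
        sessions_a=sessions_a,
        sessions_b=sessions_b,
        comparisons=comparisons,
        run_log=run_log,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write comparison tables, per-child histograms, matrices and the run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for index, comps in bundle.comparisons.items():
        st.comparisons_frame(comps, index=index).to_csv(
            out / f"comparison_{index}.csv", index=False, float_format="%.9g"
        )
    for sessions, label in (
        (bundle.sessions_a, bundle.config.label_a),
        (bundle.sessions_b, bundle.config.label_b),
    ):
        for s in sessions:
            rows = []
            for index in INDEX_NAMES:
                for h in s.histograms[index]:
                    for lab, f in zip(h.bin_spec.labels, h.frequencies):
                        rows.append((index, h.individual, lab, f, h.n_samples))
            pd.DataFrame(
                rows, columns=["index", "individual", "bin", "frequency", "n_samples"]
            ).to_csv(out / f"histograms_{s.name}.csv", index=False, float_format="%.9g")
            s.matrix.to_frame().to_csv(
                out / f"approach_matrix_{s.name}.csv", float_format="%.9g"
            )
    (out / "run_log.json").write_text(json.dumps(bundle.run_log, indent=2, sort_keys=True))


def render_outputs(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Figures from the bundle: grouped-bar histograms with SE bars and heat maps.

    Every figure gets a CSV sidecar holding exactly the numbers plotted.
    Empty tables are skipped with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for index, comps in bundle.comparisons.items():
        if not comps:
            logger.warning("comparison table for %s is empty; figure skipped", index)
            continue
        df = st.comparisons_frame(comps, index=index)
        sidecar = out / f"fig_histogram_{index}.csv"
        df.to_csv(sidecar, index=False, float_format="%.9g")
        fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(comps)), 3.2))
        x = np.arange(len(comps))
        w = 0.4
        ax.bar(x - w / 2, df["mean_a"], w, yerr=df["se_a"], capsize=2,
               label=bundle.config.label_a)
        ax.bar(x + w / 2, df["mean_b"], w, yerr=df["se_b"], capsize=2,
               label=bundle.config.label_b)
        ax.set_xticks(x)
        ax.set_xticklabels(df["bin"], rotation=90, fontsize=7)
        ax.set_ylabel("normalized frequency")
        ax.set_title(index)
        ax.legend()
        fig.tight_layout()
        path = out / f"fig_histogram_{index}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    for sessions in (bundle.sessions_a, bundle.sessions_b):
        for s in sessions:
            sidecar = out / f"fig_heatmap_{s.name}.csv"
            s.matrix.to_frame().to_csv(sidecar, float_format="%.9g")
            fig, ax = plt.subplots(figsize=(4.2, 3.6))
            im = ax.imshow(s.matrix.cells, cmap="hot")
            ax.set_xticks(range(len(s.matrix.labels)))
            ax.set_yticks(range(len(s.matrix.labels)))
            ax.set_xticklabels(s.matrix.labels, rotation=90, fontsize=7)
            ax.set_yticklabels(s.matrix.labels, fontsize=7)
            ax.set_xlabel("target c2")
            ax.set_ylabel("approacher c1")
            fig.colorbar(im, ax=ax, label="normalized frequency")
            ax.set_title(f"approach bin {s.matrix.bin_edges[1]:g} deg: {s.name}")
            fig.tight_layout()
            path = out / f"fig_heatmap_{s.name}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
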