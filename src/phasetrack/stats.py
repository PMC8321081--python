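"""Directional migration statistics, accuracy scoring, and interval sweeps.

A trajectory is counted as south-moving when its final centroid lies
strictly below its starting centroid (row increases toward the south of
the view plane) and east-moving when strictly to the right; exact ties
count as neither. Accuracy against ground truth is strict: a track is
correct only if every one of its points lies within the match radius of
the SAME true cell — a single identity switch (or an unmatched point)
makes the whole track a failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bgsub, contour
from .io import ConfigurationError, ImageSequence, RunConfig
from .simulate import GroundTruth
from .tracking import (
    ThresholdRule,
    TrajectorySet,
    filter_trajectories,
    subsample_sequence,
    threshold_for_interval,
    track_masks,
)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with exact halves going up (table-style formatting)."""
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass
class MigrationStats:
    n_tracks: int
    n_south: int
    n_east: int
    interval: float  # s
    pct_south: Optional[float] = None  # 1-decimal %, None when n_tracks = 0
    pct_east: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_tracks > 0:
            self.pct_south = round_half_up(100.0 * self.n_south / self.n_tracks)
            self.pct_east = round_half_up(100.0 * self.n_east / self.n_tracks)


@dataclass
class TrackVerdict:
    track_id: int
    correct: bool
    first_error_frame: Optional[int] = None


@dataclass
class AccuracyReport:
    n_tracks: int
    n_correct: int
    verdicts: list[TrackVerdict] = field(default_factory=list)

    @property
    def accuracy(self) -> Optional[float]:
        if self.n_tracks == 0:
            return None
        return round_half_up(100.0 * self.n_correct / self.n_tracks)


def directional_stats(trajs: TrajectorySet, interval: Optional[float] = None) -> MigrationStats:
    """Count south- and east-moving trajectories (strict inequalities)."""
    interval = trajs.interval if interval is None else interval
    n_south = sum(1 for tr in trajs.tracks if tr.end[0] > tr.start[0])
    n_east = sum(1 for tr in trajs.tracks if tr.end[1] > tr.start[1])
    return MigrationStats(len(trajs.tracks), n_south, n_east, interval)


def star_plot_vectors(trajs: TrajectorySet) -> np.ndarray:
    """Net displacement (end - start) per track, origin-anchored, (n, 2) px."""
    if not trajs.tracks:
        return np.empty((0, 2))
    return np.array([tr.end - tr.start for tr in trajs.tracks])


def save_star_plot(
    trajs: TrajectorySet, csv_path=None, figure_path=None
) -> np.ndarray:
    vectors = star_plot_vectors(trajs)
    if csv_path is not None:
        pd.DataFrame(vectors, columns=["d_row_px", "d_col_px"]).to_csv(
            csv_path, index=False, float_format="%.3f"
        )
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        for d_row, d_col in vectors:
            ax.plot([0, d_col], [0, -d_row], lw=0.7, alpha=0.7)
        ax.set_xlabel("east displacement (px)")
        ax.set_ylabel("north displacement (px)")
        ax.set_aspect("equal")
        ax.axhline(0, color="0.8", lw=0.5)
        ax.axvline(0, color="0.8", lw=0.5)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return vectors


def compute_confluence(mask: np.ndarray) -> float:
    """Cell-covered fraction of the view plane, in percent."""
    mask = np.asarray(mask, dtype=bool)
    return 100.0 * np.count_nonzero(mask) / mask.size


def evaluate_accuracy(
    trajs: TrajectorySet, gt: GroundTruth, match_radius: float
) -> AccuracyReport:
    """Strict per-track accuracy against ground-truth paths.

    Track frame indices are interpreted as ground-truth frame indices;
    for tracks built from a subsampled sequence use
    :func:`evaluate_accuracy_subsampled`, which rescales them first.
    Each point is assigned to the nearest true cell within
    ``match_radius`` at its frame; a track is correct iff every point is
    assigned and all assignments name the same cell.
    """
    if match_radius <= 0:
        raise ConfigurationError("match_radius must be positive")
    by_frame = {
        int(f): (g["cell_id"].to_numpy(), g[["row_px", "col_px"]].to_numpy(float))
        for f, g in gt.table.groupby("frame")
    }
    verdicts = []
    n_correct = 0
    for tr in trajs.tracks:
        assigned = None
        verdict = TrackVerdict(tr.track_id, True)
        for f, pos in zip(tr.frames, tr.positions):
            entry = by_frame.get(int(f))
            cell = None
            if entry is not None and len(entry[0]):
                ids, positions = entry
                dist = np.hypot(*(positions - pos).T)
                k = int(np.argmin(dist))
                if dist[k] <= match_radius:
                    cell = int(ids[k])
            if cell is None or (assigned is not None and cell != assigned):
                verdict = TrackVerdict(tr.track_id, False, int(f))
                break
            assigned = cell
        if verdict.correct:
            n_correct += 1
        verdicts.append(verdict)
    return AccuracyReport(len(trajs.tracks), n_correct, verdicts)


@dataclass
class SweepRow:
    interval: float  # s
    stats: MigrationStats
    accuracy: Optional[AccuracyReport] = None
    confluence_range: Optional[tuple[float, float]] = None


@dataclass
class SweepReport:
    rows: list[SweepRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            records.append(
                {
                    "interval_s": row.interval,
                    "trajectories": row.stats.n_tracks,
                    "south_moving": row.stats.n_south,
                    "pct_south": row.stats.pct_south,
                    "east_moving": row.stats.n_east,
                    "pct_east": row.stats.pct_east,
                    "accuracy": (
                        row.accuracy.accuracy if row.accuracy else None
                    ),
                    "confluence_min": (
                        row.confluence_range[0] if row.confluence_range else None
                    ),
                    "confluence_max": (
                        row.confluence_range[1] if row.confluence_range else None
                    ),
                }
            )
        return pd.DataFrame.from_records(records)


def segment_sequence(seq: ImageSequence, config: RunConfig) -> np.ndarray:
    """Dispatch to the configured segmentation backend."""
    if config.segmentation_backend == "bgsub":
        return bgsub.segment_sequence(seq, tau=config.tau)
    return contour.segment_sequence(seq)


def run_pipeline(
    seq: ImageSequence,
    config: RunConfig,
    gt: Optional[GroundTruth] = None,
    experiment_duration_s: Optional[float] = None,
) -> SweepRow:
    """Segment → track → duration-filter → stats for one stored sequence."""
    rule = ThresholdRule(config.D_anchors)
    D = threshold_for_interval(rule, seq.interval)
    masks = segment_sequence(seq, config)
    trajs = track_masks(
        masks, D, seq.interval, area_bounds=config.area_bounds
    )
    if experiment_duration_s is None:
        experiment_duration_s = seq.duration
    kept = filter_trajectories(
        trajs, config.duration_fraction, experiment_duration_s
    )
    stats = directional_stats(kept)
    acc = None
    if gt is not None:
        radius = config.match_radius if config.match_radius is not None else D
        acc = evaluate_accuracy_subsampled(kept, gt, radius, seq)
    conf = [compute_confluence(m) for m in masks]
    return SweepRow(
        seq.interval, stats, acc, (min(conf), max(conf)) if conf else None
    )


def evaluate_accuracy_subsampled(
    trajs: TrajectorySet,
    gt: GroundTruth,
    match_radius: float,
    seq: ImageSequence,
) -> AccuracyReport:
    """Accuracy of tracks from a (possibly subsampled) sequence.

    Ground truth is stored per base-interval frame; track frame indices
    refer to the subsampled sequence, so they are rescaled by the
    subsampling factor before lookup.
    """
    factor = int(round(seq.interval / seq.origin_interval))
    if factor == 1:
        rescaled = trajs
    else:
        from .tracking import Track

        rescaled = TrajectorySet(
            [
                Track(tr.track_id, tr.frames * factor, tr.times, tr.positions)
                for tr in trajs.tracks
            ],
            trajs.interval,
        )
    return evaluate_accuracy(rescaled, gt, match_radius)


def interval_sweep(
    seq: ImageSequence,
    gt: Optional[GroundTruth],
    config: RunConfig,
) -> SweepReport:
    """Re-run the whole pipeline at each interval in the sweep list.

    Each interval must be an integer multiple of the stored base
    interval; the duration-filter threshold always refers to the
    original experiment duration.
    """
    experiment_duration = seq.duration
    rows = []
    for interval in config.intervals_to_sweep:
        ratio = interval / seq.interval
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigurationError(
                f"sweep interval {interval}s is not an integer multiple "
                f"of the base interval {seq.interval}s"
            )
        sub = subsample_sequence(seq, int(round(ratio)))
        rows.append(
            run_pipeline(
                sub, config, gt=gt, experiment_duration_s=experiment_duration
            )
        )
    rows.sort(key=lambda r: r.interval)
    return SweepReport(rows)
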