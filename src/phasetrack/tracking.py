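"""Centroid extraction, greedy global-minimum linking, trajectory assembly.

The linker follows the closest-target assumption: between two consecutive
frames it repeatedly picks the globally smallest entry of the pairwise
centroid distance array, creates that link if the distance is within the
threshold D, removes the corresponding row and column, and recurses.
This is deliberately NOT an optimal-assignment (Hungarian) solver; the
greedy procedure is the method under study. The threshold D scales with
the acquisition interval: 10 px at 30 s rising linearly to 50 px at
15 min, clamped outside that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .io import ConfigurationError, ImageSequence

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class ObjectSet:
    """Labelled foreground objects of one frame (areas px^2, centroids px)."""

    frame_index: int
    areas: np.ndarray  # (n,)
    centroids: np.ndarray  # (n, 2) row, col

    def __len__(self) -> int:
        return len(self.areas)


@dataclass
class LinkSet:
    """Links between consecutive ObjectSets: (i, j) index pairs + distances."""

    pairs: np.ndarray  # (m, 2) int
    distances: np.ndarray  # (m,)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Track:
    track_id: int
    frames: np.ndarray  # indices into the (possibly subsampled) sequence
    times: np.ndarray  # seconds
    positions: np.ndarray  # (n, 2) row, col px

    @property
    def duration(self) -> float:
        """Elapsed seconds between first and last sighting."""
        return float(self.times[-1] - self.times[0])

    @property
    def start(self) -> np.ndarray:
        return self.positions[0]

    @property
    def end(self) -> np.ndarray:
        return self.positions[-1]


@dataclass
class TrajectorySet:
    tracks: list[Track] = field(default_factory=list)
    interval: float = 0.0

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class ThresholdRule:
    """Interval-dependent linking threshold, linear between two anchors."""

    anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (30.0, 10.0),
        (900.0, 50.0),
    )

    def __post_init__(self) -> None:
        (i0, d0), (i1, d1) = self.anchors
        if not (i1 > i0 and d0 > 0 and d1 >= d0):
            raise ConfigurationError("anchors must be increasing in interval")


def threshold_for_interval(rule: ThresholdRule, interval_s: float) -> float:
    """Piecewise-linear D(interval), clamped to the anchor range."""
    (i0, d0), (i1, d1) = rule.anchors
    return float(np.interp(interval_s, [i0, i1], [d0, d1]))


def mask_to_objects(
    mask: np.ndarray,
    area_bounds: tuple[float, float] = (20.0, 5000.0),
    frame_index: int = 0,
) -> ObjectSet:
    """8-connected components, area-filtered, with unweighted centroids."""
    min_area, max_area = area_bounds
    if min_area > max_area:
        raise ConfigurationError("area_bounds must satisfy min <= max")
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        return ObjectSet(frame_index, np.empty(0), np.empty((0, 2)))
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n + 1)[1:].astype(float)
    rows, cols = np.indices(mask.shape).reshape(2, -1)
    sum_r = np.bincount(flat, weights=rows, minlength=n + 1)[1:]
    sum_c = np.bincount(flat, weights=cols, minlength=n + 1)[1:]
    keep = (areas >= min_area) & (areas <= max_area)
    if not keep.any():
        return ObjectSet(frame_index, np.empty(0), np.empty((0, 2)))
    centroids = np.stack(
        [sum_r[keep] / areas[keep], sum_c[keep] / areas[keep]], axis=1
    )
    return ObjectSet(frame_index, areas[keep], centroids)


def link_frames(A: ObjectSet, B: ObjectSet, D: float) -> LinkSet:
    """Greedy global-minimum linking under threshold D.

    Equivalent to repeatedly taking the smallest remaining entry of the
    full |A| x |B| distance array and deleting its row and column, with
    ties broken toward the lexicographically smallest (i, j); implemented
    as one stable sort over the admissible pairs.
    """
    if D <= 0:
        raise ConfigurationError("D must be positive")
    if len(A) == 0 or len(B) == 0:
        return LinkSet(np.empty((0, 2), dtype=int), np.empty(0))
    d = cdist(A.centroids, B.centroids)
    flat = d.ravel()
    admissible = np.flatnonzero(flat <= D)
    # stable sort of flat (row-major) indices = (d, i, j) lexicographic order
    order = admissible[np.argsort(flat[admissible], kind="stable")]
    used_i = np.zeros(len(A), dtype=bool)
    used_j = np.zeros(len(B), dtype=bool)
    pairs, dists = [], []
    ncol = len(B)
    for k in order:
        i, j = divmod(int(k), ncol)
        if used_i[i] or used_j[j]:
            continue
        used_i[i] = used_j[j] = True
        pairs.append((i, j))
        dists.append(flat[k])
    if not pairs:
        return LinkSet(np.empty((0, 2), dtype=int), np.empty(0))
    return LinkSet(np.array(pairs, dtype=int), np.array(dists))


def build_trajectories(
    link_sets: Sequence[LinkSet],
    object_sets: Sequence[ObjectSet],
    interval: float,
) -> TrajectorySet:
    """Chain links sharing object endpoints into tracks.

    Any unlinked object starts a new (possibly single-point) track; a
    track ends at the first frame where its object has no outgoing link.
    No gap closing. Single-point tracks are materialised and left to the
    duration filter, so every segmented object belongs to some track.
    """
    if len(link_sets) != len(object_sets) - 1:
        raise ConfigurationError(
            "need exactly one LinkSet per consecutive ObjectSet pair"
        )
    tracks: list[Track] = []
    # open chains: map from object index in current frame -> list of
    # (frame_index, position)
    open_chains: dict[int, list] = {}
    next_id = 0

    def flush(chain) -> None:
        nonlocal next_id
        frames = np.array([f for f, _ in chain], dtype=int)
        pos = np.array([p for _, p in chain], dtype=float)
        tracks.append(
            Track(next_id, frames, frames * float(interval), pos)
        )
        next_id += 1

    for t, objs in enumerate(object_sets):
        incoming = open_chains
        open_chains = {}
        linked_from: dict[int, list] = {}
        if t > 0:
            for (i, j) in link_sets[t - 1].pairs:
                if int(i) in incoming:
                    linked_from[int(j)] = incoming.pop(int(i))
        # chains whose object got no outgoing link terminate
        for chain in incoming.values():
            flush(chain)
        for obj_idx in range(len(objs)):
            chain = linked_from.get(obj_idx, [])
            chain.append((objs.frame_index, objs.centroids[obj_idx]))
            open_chains[obj_idx] = chain
    for chain in open_chains.values():
        flush(chain)
    tracks.sort(key=lambda tr: (tr.frames[0], tr.track_id))
    for new_id, tr in enumerate(tracks):
        tr.track_id = new_id
    return TrajectorySet(tracks, float(interval))


def filter_trajectories(
    trajs: TrajectorySet,
    duration_fraction: float,
    experiment_duration_s: float,
) -> TrajectorySet:
    """Keep tracks lasting at least duration_fraction of the experiment.

    The experiment duration is that of the ORIGINAL acquisition (e.g.
    15% of 24 h = 3.6 h), unchanged by temporal subsampling; the bound
    is inclusive and there is no upper bound.
    """
    if not 0 < duration_fraction < 1:
        raise ConfigurationError("duration_fraction must be in (0, 1)")
    threshold = duration_fraction * experiment_duration_s
    kept = [tr for tr in trajs.tracks if tr.duration >= threshold]
    return TrajectorySet(kept, trajs.interval)


def subsample_sequence(seq: ImageSequence, k: int) -> ImageSequence:
    """Keep frames 0, k, 2k, ...; the stored interval scales by k."""
    if not float(k).is_integer() or k < 1:
        raise ConfigurationError("subsampling factor must be a positive integer")
    k = int(k)
    return ImageSequence(
        seq.frames[::k],
        seq.pixel_size,
        seq.interval * k,
        origin_interval=seq.origin_interval,
    )


def track_masks(
    masks: np.ndarray,
    D: float,
    interval: float,
    area_bounds: tuple[float, float] = (20.0, 5000.0),
) -> TrajectorySet:
    """Full linking stage: mask stack -> objects -> links -> trajectories."""
    object_sets = [
        mask_to_objects(m, area_bounds=area_bounds, frame_index=t)
        for t, m in enumerate(masks)
    ]
    link_sets = [
        link_frames(object_sets[t], object_sets[t + 1], D)
        for t in range(len(object_sets) - 1)
    ]
    return build_trajectories(link_sets, object_sets, interval)
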