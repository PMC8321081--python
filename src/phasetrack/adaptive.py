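"""Adaptive acquisition-interval control driven by tracking quality.

The controller closes a feedback loop between cell tracking and data
acquisition: when frame-to-frame tracking quality drops below a lower
threshold the acquisition interval is divided by a factor (imaging more
often); when quality rises above an upper threshold the interval is
multiplied (imaging less often, sparing the cells light exposure). The
quality signal is the link ratio — the fraction of objects in the
earlier frame that receive a link to the later frame under the
interval's distance threshold D — which is computable online and
degrades exactly when linking does.

Hardware is emulated: the controller replays a stored sequence acquired
at the base interval and, at each virtual acquisition, reads the stored
frame nearest to the requested time, mirroring how coarser intervals
are derived by discarding intermediate frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import bgsub, contour
from .io import ConfigurationError, ImageSequence, RunConfig
from .tracking import (
    LinkSet,
    ObjectSet,
    ThresholdRule,
    build_trajectories,
    link_frames,
    mask_to_objects,
    threshold_for_interval,
)


@dataclass
class ControllerState:
    current_interval: float  # s
    interval_min: float = 30.0
    interval_max: float = 900.0
    q_low: float = 0.80
    q_high: float = 0.95
    factor: float = 2.0
    window: int = 5
    cooldown: int = 5
    quality_window: list[float] = field(default_factory=list)
    steps_since_change: Optional[int] = None  # None = never changed

    def __post_init__(self) -> None:
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ConfigurationError("need 0 <= q_low < q_high <= 1")
        if self.factor <= 1:
            raise ConfigurationError("factor must be > 1")
        if not self.interval_min <= self.current_interval <= self.interval_max:
            raise ConfigurationError("current_interval outside bounds")


def link_quality(A: ObjectSet, B: ObjectSet, D: float) -> float:
    """Fraction of frame-A objects linked to frame B (1.0 when A is empty)."""
    if len(A) == 0:
        return 1.0
    return len(link_frames(A, B, D)) / len(A)


def adapt_interval(state: ControllerState, q: float) -> ControllerState:
    """Feed one quality sample into the controller; returns the new state.

    Decisions use the windowed mean quality and are suppressed until the
    window is full and the cooldown since the last change has elapsed;
    the window is cleared whenever the interval changes (hysteresis plus
    cooldown prevent step-to-step oscillation).
    """
    qw = state.quality_window + [float(q)]
    steps = (
        None if state.steps_since_change is None
        else state.steps_since_change + 1
    )
    new = replace(state, quality_window=qw, steps_since_change=steps)
    if len(qw) < state.window:
        return new
    if steps is not None and steps < state.cooldown:
        return new
    mean_q = float(np.mean(qw[-state.window:]))
    interval = state.current_interval
    if mean_q < state.q_low:
        interval = max(interval / state.factor, state.interval_min)
    elif mean_q > state.q_high:
        interval = min(interval * state.factor, state.interval_max)
    if interval != state.current_interval:
        return replace(
            new,
            current_interval=interval,
            quality_window=[],
            steps_since_change=0,
        )
    return new


@dataclass
class AdaptiveRun:
    log: pd.DataFrame  # columns: step, time_s, interval_s, quality
    trajectories: "object"  # TrajectorySet over the acquired frames
    final_interval: float


def run_adaptive(
    seq: ImageSequence,
    state: Optional[ControllerState] = None,
    config: Optional[RunConfig] = None,
) -> AdaptiveRun:
    """Replay a stored base-interval sequence as a virtual microscope.

    Starting from ``state.current_interval`` (default: the base
    interval), frames are "acquired" at the controller's current
    interval; after each acquisition the link quality to the previous
    acquired frame is fed to the controller. Requested intervals below
    the stored base interval are clamped to it. Returns the adaptation
    log, the trajectories built over the acquired frames, and the final
    interval.
    """
    config = config or RunConfig()
    if state is None:
        state = ControllerState(current_interval=seq.interval)
    if state.current_interval < seq.interval:
        state = replace(state, current_interval=seq.interval)
    rule = ThresholdRule(config.D_anchors)

    # segment the full stored sequence once; the virtual microscope then
    # reads per-frame objects as needed
    masks = _segment(seq, config)
    object_cache: dict[int, ObjectSet] = {}

    def objects_at(idx: int) -> ObjectSet:
        if idx not in object_cache:
            object_cache[idx] = mask_to_objects(
                masks[idx], area_bounds=config.area_bounds, frame_index=idx
            )
        return object_cache[idx]

    base = seq.interval
    n = len(seq.frames)
    t = 0.0
    acquired = [0]  # stored frame indices, first frame at t = 0
    records = []
    step = 0
    acq_objects = [objects_at(0)]
    link_sets: list[LinkSet] = []
    while True:
        interval = max(state.current_interval, base)
        t_next = t + interval
        idx = int(round(t_next / base))
        if idx >= n:
            break
        D = threshold_for_interval(rule, interval)
        A = acq_objects[-1]
        B = objects_at(idx)
        links = link_frames(A, B, D)
        q = link_quality(A, B, D)
        link_sets.append(links)
        acq_objects.append(B)
        acquired.append(idx)
        t = idx * base
        state = adapt_interval(state, q)
        records.append(
            {
                "step": step,
                "time_s": t,
                "interval_s": interval,
                "quality": q,
            }
        )
        step += 1

    # trajectories over the acquired (variable-interval) frames; times are
    # true acquisition times, so durations remain physical
    renumbered = [
        ObjectSet(k, objs.areas, objs.centroids)
        for k, objs in enumerate(acq_objects)
    ]
    trajs = build_trajectories(link_sets, renumbered, base)
    times = np.array(acquired, dtype=float) * base
    for tr in trajs.tracks:
        tr.times = times[tr.frames]
    log = pd.DataFrame.from_records(
        records, columns=["step", "time_s", "interval_s", "quality"]
    )
    return AdaptiveRun(log, trajs, state.current_interval)


def _segment(seq: ImageSequence, config: RunConfig) -> np.ndarray:
    if config.segmentation_backend == "bgsub":
        return bgsub.segment_sequence(seq, tau=config.tau)
    return contour.segment_sequence(seq)
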