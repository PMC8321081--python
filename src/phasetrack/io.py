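"""Image-sequence, trajectory-table and run-configuration I/O.

Coordinate convention used throughout the package: 0-based ``(row, col)``
pixel coordinates. Row increases toward the image bottom, which is SOUTH;
col increases toward EAST. Frame ``k`` of a sequence acquired at interval
``dt`` seconds carries time stamp ``k * dt`` (first frame at t = 0).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml


class FormatError(ValueError):
    """Raised when an on-disk sequence violates the expected layout."""


class ConfigurationError(ValueError):
    """Raised for invalid parameter values or missing required metadata."""


# positions are stored to 3 decimal px in every CSV written by this module
_POS_FMT = "%.3f"


@dataclass
class ImageSequence:
    """An ordered grayscale time-lapse.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        8- or 16-bit grayscale frames in temporal order.
    pixel_size : float
        Physical pixel size in μm/px.
    interval : float
        Seconds between consecutive *stored* frames.
    origin_interval : float, optional
        Interval of the original acquisition before any temporal
        subsampling; defaults to ``interval``.
    """

    frames: np.ndarray
    pixel_size: float
    interval: float
    origin_interval: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise FormatError("frames must be a (T, H, W) stack with T >= 1")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.interval <= 0:
            raise ConfigurationError("interval must be positive")
        if self.origin_interval is None:
            self.origin_interval = self.interval
        ratio = self.interval / self.origin_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "interval must be an integer multiple of origin_interval"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Total experiment duration in seconds (frame count x interval)."""
        return len(self.frames) * self.interval

    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.interval


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``D_anchors`` are ``(interval_s, D_px)`` pairs between which the linking
    threshold D is interpolated linearly; the defaults pin D = 10 px at a
    30 s interval and D = 50 px at 15 min. ``match_radius`` of ``None``
    means "use the D of the current interval" when scoring accuracy.
    """

    segmentation_backend: str = "bgsub"
    area_bounds: tuple[float, float] = (20.0, 5000.0)
    duration_fraction: float = 0.15
    D_anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (30.0, 10.0),
        (900.0, 50.0),
    )
    intervals_to_sweep: tuple[float, ...] = (
        30.0, 60.0, 120.0, 180.0, 300.0, 450.0, 600.0, 900.0,
    )
    match_radius: Optional[float] = None
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.segmentation_backend not in ("contour", "bgsub"):
            raise ConfigurationError(
                f"unknown segmentation backend {self.segmentation_backend!r}"
            )
        if not 0 < self.duration_fraction < 1:
            raise ConfigurationError("duration_fraction must be in (0, 1)")
        (i0, d0), (i1, d1) = self.D_anchors
        if not (d0 > 0 and d1 > 0 and i1 > i0 and d1 >= d0):
            raise ConfigurationError(
                "D anchors must be positive and non-decreasing in interval"
            )
        if self.area_bounds[0] > self.area_bounds[1]:
            raise ConfigurationError("area_bounds must satisfy min <= max")


_IMAGE_EXTS = (".tif", ".tiff", ".png")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def read_sequence(
    path: str | os.PathLike,
    pixel_size: Optional[float] = None,
    interval: Optional[float] = None,
) -> ImageSequence:
    """Read a multi-page TIFF stack or a directory of single-frame images.

    Frames from a directory are ordered lexicographically by file name.
    ``pixel_size`` and ``interval`` override (or supply, when absent) the
    metadata from the sidecar file written by :func:`write_sequence`.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS
        )
        if not files:
            raise FormatError(f"no image files found in {path}")
        frames = []
        for p in files:
            if p.suffix.lower() in (".tif", ".tiff"):
                frames.append(tifffile.imread(p))
            else:
                import imageio.v3 as iio

                frames.append(iio.imread(p))
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"mixed frame shapes in {path}: {shapes}")
        stack = np.stack(frames)
        meta_path = _sidecar_path(path)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        meta_path = _sidecar_path(path)
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    interval = interval if interval is not None else meta.get("interval")
    if pixel_size is None or interval is None:
        raise ConfigurationError(
            "pixel_size and interval must come from metadata or arguments"
        )
    return ImageSequence(
        stack,
        float(pixel_size),
        float(interval),
        origin_interval=meta.get("origin_interval"),
    )


def write_sequence(seq: ImageSequence, path: str | os.PathLike) -> None:
    """Write a multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
    meta = {
        "pixel_size": float(seq.pixel_size),
        "interval": float(seq.interval),
        "origin_interval": float(seq.origin_interval),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def write_trajectories(trajs, path: str | os.PathLike) -> None:
    """Write a TrajectorySet as CSV (track_id, frame, time_s, row_px, col_px)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("track_id,frame,time_s,row_px,col_px\n")
        for tr in trajs.tracks:
            for f, t, (r, c) in zip(tr.frames, tr.times, tr.positions):
                fh.write(
                    f"{tr.track_id},{f},{_POS_FMT % t},"
                    f"{_POS_FMT % r},{_POS_FMT % c}\n"
                )


def read_trajectories(path: str | os.PathLike):
    """Inverse of :func:`write_trajectories` (positions at 3-decimal px)."""
    import pandas as pd

    from .tracking import Track, TrajectorySet

    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(int),
                times=grp["time_s"].to_numpy(float),
                positions=grp[["row_px", "col_px"]].to_numpy(float),
            )
        )
    if tracks:
        intervals = [
            tr.times[1] - tr.times[0] for tr in tracks if len(tr.frames) > 1
        ]
        interval = float(min(intervals)) if intervals else 0.0
    else:
        interval = 0.0
    return TrajectorySet(tracks=tracks, interval=interval)


def read_config(path: str | os.PathLike) -> RunConfig:
    """Read a flat YAML run configuration mirroring RunConfig field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, value in raw.items():
        if key == "area_bounds":
            value = tuple(float(v) for v in value)
        elif key == "D_anchors":
            value = tuple((float(a), float(b)) for a, b in value)
        elif key == "intervals_to_sweep":
            value = tuple(float(v) for v in value)
        kwargs[key] = value
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path: str | os.PathLike) -> None:
    raw = asdict(config)
    raw["area_bounds"] = list(raw["area_bounds"])
    raw["D_anchors"] = [list(a) for a in raw["D_anchors"]]
    raw["intervals_to_sweep"] = list(raw["intervals_to_sweep"])
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
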