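"""Shared fixtures: small rendered scenes with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from phasetrack import (
    GroundTruth,
    MotionConfig,
    RenderConfig,
    render_sequence,
)


def straight_path_gt(specs, n_frames):
    """Ground truth from (cell_id, row0, col0, d_row, d_col) per-frame steps."""
    rows = []
    for cid, r0, c0, dr, dc in specs:
        for f in range(n_frames):
            rows.append((cid, f, r0 + dr * f, c0 + dc * f))
    return GroundTruth(
        pd.DataFrame(rows, columns=["cell_id", "frame", "row_px", "col_px"])
    )


@pytest.fixture(scope="session")
def touching_pair():
    """Two east-drifting cells whose halos touch throughout.

    The pair stays 19 px apart (outer halo radii 8 + 2 sum to 20, so the
    halos overlap) while sweeping east fast enough that every pixel is
    cell-free in well over half of the frames. Rendered with a wide
    blur and scored with an explicit subtraction threshold, this is the
    canonical over/under-detection contrast scene: edge+contour merges
    the pair into one object, background subtraction splits each cell
    into interior and halo fragments.
    """
    n_frames = 60
    gt = straight_path_gt(
        [(0, 90.0, 40.0, 0.0, 1.5), (1, 109.0, 40.0, 0.0, 1.5)], n_frames
    )
    mcfg = MotionConfig(
        n_cells=2, frame_count=n_frames, image_shape=(200, 200), seed=5
    )
    rcfg = RenderConfig(
        cell_radius_mean=8.0,
        cell_radius_sd=0.0,
        interior_intensity_range=(30.0, 60.0),
        noise_sd=2.0,
        psf_sigma=2.0,
    )
    return render_sequence(gt, rcfg, mcfg), gt


@pytest.fixture(scope="session")
def single_cell_scene():
    """One static cell, dark interior, noise-free, unblurred."""
    n_frames = 2
    gt = straight_path_gt([(0, 32.0, 32.0, 0.0, 0.0)], n_frames)
    mcfg = MotionConfig(
        n_cells=1, frame_count=n_frames, image_shape=(64, 64), seed=3
    )
    rcfg = RenderConfig(
        cell_radius_mean=8.0,
        cell_radius_sd=0.0,
        interior_intensity_range=(40.0, 40.0),
        noise_sd=0.0,
        psf_sigma=0.0,
    )
    return render_sequence(gt, rcfg, mcfg), gt, rcfg


@pytest.fixture(scope="session")
def sweeping_cell_noise_free():
    """A single cell crossing the field, noise-free: every pixel is
    cell-free in > 50% of frames, so the temporal mode recovers the
    true background exactly."""
    n_frames = 80
    gt = straight_path_gt([(0, 32.0, 5.0, 0.0, 1.5)], n_frames)
    mcfg = MotionConfig(
        n_cells=1, frame_count=n_frames, image_shape=(64, 140), seed=9
    )
    rcfg = RenderConfig(
        cell_radius_mean=7.0,
        cell_radius_sd=0.0,
        interior_intensity_range=(30.0, 220.0),
        noise_sd=0.0,
        psf_sigma=1.0,
    )
    return render_sequence(gt, rcfg, mcfg), gt, rcfg
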