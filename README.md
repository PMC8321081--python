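# phasetrack

Fully-automated cell tracking for phase-contrast time-lapse microscopy,
built to study how the acquisition **time step interval** — the time
between consecutive microscope frames — trades off against tracking
quality, and to select that interval adaptively.

The package is aimed at people who analyse migration of slow-moving
adherent cells (speeds below 1 μm/min, e.g. fibrosarcoma lines or
primary keratinocytes) in chemotaxis chambers: frequent imaging tracks
cells almost perfectly but costs light exposure, heat and storage;
sparse imaging spares the cells but lets nearest-neighbour tracking
lose or confuse them. `phasetrack` provides the whole measurement
chain plus a ground-truthed synthetic data generator, so every stage
can be validated end to end without microscope data.

## What is inside

- **Synthetic time-lapse generator** (`phasetrack.simulate`) —
  Gaussian-step random-walk motion with optional constant drift
  (chemotaxis emulated as a southward drift), rendered with the
  characteristic phase-contrast appearance: bright halo ring, interior
  flickering from dark to bright, Gaussian noise. Per-cell ground-truth
  trajectories come with every dataset.
- **Two segmentation backends** — edge detection + region-based active
  contour (`phasetrack.contour`; under-segments touching cells) and
  temporal-mode background reconstruction + subtraction
  (`phasetrack.bgsub`; over-segments cells into interior/halo
  fragments). The temporal mode takes, per pixel, the most frequent
  intensity across all frames.
- **Greedy global-minimum linker** (`phasetrack.tracking`) — between
  consecutive frames the globally smallest centroid distance d_ij =
  |C_A,i − C_B,j| is linked first, its row and column removed, and the
  procedure recursed until the smallest remaining distance exceeds a
  threshold D. D scales with the interval: 10 px (16.1 μm) at 30 s
  rising linearly to 50 px at 15 min. Tracks shorter than 15% of the
  experiment duration are discarded.
- **Migration statistics** (`phasetrack.stats`) — south-/east-moving
  trajectory counts and percentages (strict end-versus-start
  comparison), star-plot displacement vectors, per-frame confluence,
  strict accuracy against ground truth (a single identity switch fails
  the whole track), and an interval sweep that re-runs the pipeline at
  30 s, 1, 2, 3, 5, 7.5, 10 and 15 min by subsampling the stored 30 s
  sequence.
- **Adaptive interval controller** (`phasetrack.adaptive`) — a feedback
  loop that halves the interval when the frame-to-frame link ratio
  falls below 0.80 and doubles it when the ratio exceeds 0.95, with a
  sliding window and cooldown to prevent oscillation.

## Worked example

```python
from phasetrack import RunConfig, interval_sweep, make_dataset

# 4 h of directed (southward-drifting) cells at a 30 s base interval
seq, gt = make_dataset("directed_HT1080", seed=1, frame_count=480)
report = interval_sweep(seq, gt, RunConfig())
print(report.to_frame()[["interval_s", "trajectories",
                         "pct_south", "accuracy"]].to_string(index=False))
```

prints

```
 interval_s  trajectories  pct_south  accuracy
       30.0            49      100.0      81.6
       60.0            45      100.0      80.0
      120.0            52       98.1      78.8
      180.0            55       98.2      80.0
      300.0            51       98.0      78.4
      450.0            51       96.1      76.5
      600.0            53       90.6      75.5
      900.0            48       97.9      77.1
```

Each row is one choice of time step interval: the number of accepted
trajectories (those lasting at least 15% of the 4 h experiment), the
percentage whose end point lies south of their start — far above 50%,
recovering the imposed chemotactic drift at every interval — and the
strict tracking accuracy against the simulator's ground truth, which
erodes as frames are sampled more sparsely.

The same pipeline is available from the shell:

```sh
phasetrack simulate --scenario directed_HT1080 --frames 480 --seed 1 --out data/
phasetrack sweep --in data/sequence.tif --gt data/ground_truth.csv --out report.csv
phasetrack adapt --in data/sequence.tif --out adapt_log.csv
```

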