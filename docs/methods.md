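# Methods

## Problem setting

Phase-contrast time-lapse microscopy of slow-moving adherent cells
(mesenchymal migration, mean speeds under 1 μm/min) is the standard way
to quantify chemotaxis: a chemoattractant reservoir on one side of the
chamber — by convention the *south* (bottom) of the view plane here —
induces directed migration, while matched media on both sides give an
unbiased random walk. Automated tracking of such recordings has two
stages, segmentation and frame-to-frame particle linking, and both are
sensitive to the acquisition time step interval: short intervals keep
cells close to their previous positions but cost light exposure;
longer intervals let cells move, deform, or pass each other between
frames. `phasetrack` implements the full measurement chain, an
interval sweep that re-runs it at coarser sampling, and a feedback
controller that picks the interval online.

Conventions: 0-based (row, col) pixel coordinates; row grows southward,
col eastward; frame k at interval Δt carries time k·Δt; pixel size
defaults to 1.61 μm/px (4× objective) and the base interval to 30 s.

## Synthetic data generator

Real recordings of this kind are rarely redistributable, so the package
ships a simulator whose defaults mirror the study conditions, and every
quantitative claim in the test suite is made against its ground truth.

**Motion.** Each cell takes per-frame steps `drift·Δt + ε`,
`ε ~ N(0, σ²I₂)`. A per-cell target speed is drawn from
N(speed_mean, speed_sd) (clipped at 0) and σ solves
E|drift·Δt + ε| = target·Δt — a Rice-distribution mean, evaluated with
exponentially scaled Bessel functions and inverted by bracketed
root-finding. When the drift alone meets the target the noise is zero
and motion is ballistic. This single calibration makes the empirical
mean path speed match `speed_mean` to well within 5% and reduces to
exact straight-line drift in the noise-free case. Scenario presets:
HT1080-like cells at 0.8 μm/min (directed variant: 0.4 μm/min
southward drift), nHEK-like cells at 0.5 μm/min; these means are
calibration choices within the "below 1 μm/min" slow-moving regime,
not measured values. With `boundary_mode="open"` a cell is dropped at
the first frame it leaves the view plane (cells move freely in and
out); `"reflect"` folds paths back for closed-world tests.

**Rendering.** Each present cell is an interior disk (radius per cell
from N(8, 1) px, intensity re-drawn per frame uniformly from
(30, 220) to emulate the dark-to-bright interior flicker of phase
contrast) surrounded by a halo annulus (width 2 px, intensity 200) on
a uniform background (level 100), followed by a Gaussian blur
(psf_sigma, default 1 px) standing in for the optical transfer, then
additive Gaussian noise (sd 3) and quantisation to 8 or 16 bits. The
blur matters: it creates the smooth interior-to-halo intensity
transition through the background level that makes background
subtraction split a cell into interior and halo fragments — the
over-detection failure mode this class of methods is known for. A blur
of a constant is that constant, so cell-free pixels still render
exactly at the background level and temporal-mode reconstruction can
be checked for pixel-exact recovery. Motion and rendering consume
separate random sub-streams, so re-rendering with different appearance
settings never changes the trajectories.

The generator does **not** model cell division, collision dynamics,
explicit filopodia or photorealistic optics; per-frame radius jitter is
the only stand-in for area change. Consequently, passing tests
demonstrate correctness of the algorithmic chain under the stated
motion/appearance model, not performance on real morphologically
active cells.

**Stress scenarios.** Two additional generators create regimes the
plain scenarios cannot reach. `make_crossing_dataset` composes
sub-populations drifting north/south/east/west, three cells per
direction at each drift speed of a ladder (0.6, 1.2, 2.0, 3.0 μm/min;
48 cells in 360² px): purely diffusive cells displace only ∝ √Δt
between samples and never challenge the linker, whereas
counter-drifting cells separate ∝ Δt, so sparsely sampled sequences
contain passing events in which the nearest next-frame centroid
belongs to the *other* cell. The speed ladder staggers the interval at
which each sub-population enters that regime, producing graded rather
than cliff-edge degradation of count and accuracy. Cell radius
(4.5 px) and density were chosen by pilot simulation so that outright
halo contact — which penalises every sampling rate equally under
strict scoring — stays rare. `make_speed_mix_dataset`
renders straight movers with a 70/20/10% mix of speeds (0.04, 0.10,
0.15 px/s) bouncing off the walls; from the link-failure condition
v·I > D(I) this places the frame-to-frame link ratio above 0.95 at
60 s, near 0.90 at 120 s and below 0.80 from 240 s up, so exactly one
rung of a factor-2 interval ladder lies inside the adaptive
controller's quality band.

## Segmentation

**Edge + active contour** (`contour`). Gradient magnitude from
Gaussian-derivative filters (sigma 2 px); hysteresis thresholds taken
at the 0.85/0.95 quantiles of the magnitude image, each floored at
3×/6× the median magnitude so that sparse scenes (where those
quantiles fall inside the noise) yield no spurious edges. The edge
mask, dilated by 2 px, seeds a two-phase piecewise-constant
(Chan–Vese-style, morphological) contour evolution (100 iterations,
smoothing 1). The minority-area phase is taken as foreground — valid
because confluence stays below 50% in this domain — and holes are
filled, so interior intensity flips are absorbed into one solid
component per object. Documented failure mode: cells whose halos touch
merge into a single component (under-detection).

**Temporal-mode background subtraction** (`bgsub`). The background is
the per-pixel mode of the intensity histogram over all frames — valid
whenever each pixel is cell-free in most frames — with ties broken
toward the smaller intensity for reproducibility. For 16-bit data with
more than 4096 distinct levels the histogram switches to 256
equal-width bins and reports bin centres (exact where cheap, bounded
memory otherwise). Foreground is |frame − background| > τ, absolute
difference because interiors may be darker or brighter than
background; τ defaults to 3× a robust noise sd (1.4826 × median
absolute frame-minus-background difference, estimated on a spread
subsample of frames). No morphological post-processing: fragment and
noise removal is delegated to the downstream area filter. Documented
failure modes: one cell → interior + halo fragments (over-detection),
and cells that do not vacate their own footprint within the recording
are partially absorbed into the background and can be missed — at the
4 h desk scale used in the tests this affects near-stationary
random-walk cells, which is direction-neutral for the migration
statistics.

## Linking and trajectories

Objects are 8-connected components with areas inside (20, 5000) px²
(size filtering removes noise and fragments; diagonal-touching halo
pixels belong to one object); positions are unweighted pixel-coordinate
centroids. Between consecutive frames the linker repeatedly selects the
globally smallest entry of the pairwise distance array, links it if
≤ D, deletes its row and column, and recurses — the closest-target
assumption with a global-minimum ordering, deliberately *not* an
optimal-assignment solver (a brute-force re-sort-every-step oracle in
the tests pins down these exact semantics, including the case where
greedy total distance exceeds the Hungarian optimum). Ties break to
the lexicographically smallest (i, j); the implementation is a single
stable sort over admissible pairs, which is provably equivalent and
O(E log E).

Chains of links become tracks; every unlinked object starts a new
(possibly single-point) track, a track ends at its first frame without
an outgoing link, and there is no gap closing or motion prediction.
Track duration is (points − 1) × interval; tracks shorter than 15% of
the *original* experiment duration (3.6 h for a 24 h recording) are
rejected, with no upper bound. Interval sweeps subsample the stored
base-interval sequence (frames 0, k, 2k, …) and re-run everything,
keeping the duration threshold tied to the original acquisition.

The linking threshold D interpolates linearly between the anchors
(30 s, 10 px) and (15 min, 50 px), clamped outside; only the two
endpoints of this rule are established, and the gap between them is
resolved by the simplest monotone choice.

## Statistics and evaluation

South-moving = end row strictly greater than start row (ties count as
neither side; the conservative, testable reading). Percentages are
formatted half-up to one decimal. Star-plot vectors are end − start
per track. Confluence is the foreground fraction of the view plane per
frame, reported as a min–max range over the recording. Strict
accuracy: each track point is assigned to the nearest ground-truth
cell within a match radius (default: the D of the current interval);
a track is correct only if every point is assigned and all assignments
name one cell. This is invariant to track ids and order.

## Adaptive interval control

Quality signal: the link ratio — the fraction of previous-frame
objects that receive a link — computable online and degrading exactly
when tracking does (the quality metric is a design choice; the
feedback idea itself prescribes none). The controller keeps a sliding
window (5 samples) of quality values; when the windowed mean falls
below q_low = 0.80 the interval is divided by the factor 2, above
q_high = 0.95 it is multiplied by 2, always clamped to [30 s, 15 min].
The window is cleared on every change and changes are suppressed for a
cooldown (5 samples), so with hysteresis (q_low < q_high) the
controller cannot flip direction within one cooldown. Acquisition
hardware is emulated by replaying a stored 30 s sequence and reading,
at each virtual acquisition, the stored frame nearest the requested
time — the same discard-the-intermediates construction used for the
interval sweeps.

## Problem sizes and numerical choices

The shipped study conditions are desk-scale: 480 frames (4 h at 30 s)
instead of a full 24 h recording, 400² px view planes (360² for the
crossing fixture, 512² for the speed-mix fixture), 50–60 cells, and
5–10 seeds per pooled statistic; full-length generation remains one
config field away. Determinism: every stochastic component draws from
`numpy` SeedSequence streams keyed by (purpose, seed); mode ties break
low; linker ties break lexicographically; percentages round half-up.
Degenerate inputs are defined rather than accidental: empty object
sets link to nothing, an empty reference frame has link quality 1.0,
zero-track statistics report percentages as unavailable, and
single-frame sequences are rejected for background reconstruction
(a one-frame mode is not a background estimate).

## Known limitations

Strict accuracy charges every ambiguity to the track, so values at
dense confluence are pessimistic relative to human judgement. The
background model is global and static (no illumination drift or
rolling updates). The contour backend runs a global two-phase
evolution per frame rather than per object. Trajectory-based
re-segmentation feedback is out of scope. Simulated appearance omits
elongation and protrusions, so absolute accuracy figures should not be
read as predictions for real recordings — the qualitative contrasts
(directed vs random, backend over/under-detection, degradation with
coarser sampling) are the validated content.
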