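# Methods

This note documents the quantification model implemented by `capnet`, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the procedure was genuinely open.

## Event calling

Per-cell traces are the arithmetic means of the movie over each labeled
nuclear ROI (the nuclear mask itself, with no dilation into the cytoplasm:
the nuclear label is the cell proxy, and dilated ROIs would mix neighboring
cells on densely packed capillaries). The trace is normalized against a
windowed minimum: frames are partitioned into consecutive non-overlapping
100-frame windows and each frame's reference is the minimum of its window.
This absorbs slow baseline drift and photobleaching without modeling
either. A Ca²⁺ event is a maximal run of frames with

```
MFI[t] > (1 + r) · windowed_min[t],    r = 0.5
```

Both this threshold and the persistence threshold below are strict
inequalities; the boundary cases (exactly 1.5× the minimum, exactly 170)
are not events, and are tested explicitly.

Runs crossing a window seam merge into one event: events are counted per
cell over the whole recording, and splitting at an arbitrary normalization
seam would inflate counts. Events touching the first or last frame are kept
with a censored flag — their observed duration is a lower bound, and no
censoring correction is applied. Supra-threshold runs separated by one or
more sub-threshold frames are distinct events by default; a `gap_tolerance`
parameter (default 0 frames) can merge across brief dips.

Summary statistics per cell, with a recording of `n` frames at interval
`dt` seconds (`minutes = n·dt/60`):

- status: active iff ≥ 1 event;
- frequency = n_events / minutes (events/minute). At the default timebase
  (300 frames × 3.44 s = 17.2 min) a single event gives the frequency
  floor 1/17.2 ≈ 0.0581 events/min ≈ 0.001 Hz;
- avg_duration = total signaling seconds / n_events; undefined (NaN) for
  inactive cells.

**Dynamics classes.** High-frequency and high-average-duration cells are
those strictly above mean + 1 SD of the respective distribution over the
*active* cells of a reference population — by default the analyzed
population itself; for revisits the Day-0 population; for knockout
comparisons the control population. The SD is the sample SD (ddof = 1):
cell populations are samples. The two flags are independent and both are
retained. On unimodal, Gaussian-like frequency distributions the 1-SD rule
tags roughly the upper ~16% tail.

**Persistent activity.** A cell in a persistent signaling state keeps its
minimum fluorescence high, so the windowed-minimum rule is blind to it by
construction. Persistence is therefore detected on the absolute scale: time
spent with MFI strictly above 170 (out of 255). A cell is flagged
persistent when that time reaches `min_persistent_duration_s` (default
120 s, configurable): persistent events run from about two minutes up to
the entire recording, and without a duration floor a single bright
transient would be misclassified. Intensities must be on (or rescaled to)
the 0–255 scale; 16-bit input is divided by the recorded acquisition scale
factor, and out-of-scale values are a hard error rather than being silently
rescaled.

## Cluster analysis

The vessel surface (a binary mask; segmentation is an input) is tiled into
0.0076 × 0.0076 mm² grids anchored at the image origin, pixel (y, x)
belonging to grid (⌊y·ps/g⌋, ⌊x·ps/g⌋) — exact for non-integer grid widths,
with partial edge grids. A grid is retained iff it overlaps ≥ 1 vessel
pixel, and its trace averages over its vessel pixels only (averaging the
full square would dilute signal with background; this is an
interpretation, flagged as such). Grid traces are thresholded with exactly
the per-cell detector semantics.

Clusters are connected components over active (grid, frame) entries: two
entries link iff their grids are identical or spatially adjacent and their
frames differ by at most 1. Spatial adjacency defaults to 8-connectivity
(capillaries run diagonally across the tiling); a 4-connectivity toggle
exists because "adjacent" is not otherwise pinned down. Linking uses active
entries (co-activity within the 1-frame tolerance), the more inclusive
reading, rather than event onsets. ECs per cluster are nuclei whose
centroid falls in a member grid under half-open bounds, so a centroid on a
shared edge is counted exactly once. Cluster size distributions are
reported as proportions of clusters in size bins {1}, {2–4}, {≥5} plus the
raw histogram. A cluster is "persistently active" when at least one member
grid is active in ≥ `full_span_fraction` of frames (default 1.0: every
frame).

## Longitudinal conservation

Cell correspondence across revisit days is an input (landmark-based
revisiting with positionally stable cells); no image registration is
attempted. Maintained status = same active/inactive status on both days.

The conservation test is a two-category χ² goodness of fit with df = 1:
observed (maintained, not-maintained) counts against expected proportions
(p₀, 1 − p₀), where p₀ is the Day-0 active proportion (0.58 for 24-hour
revisits, 0.54 for 14-day revisits, 0.74 for the knockout 14-day
revisits). Note this null — "the maintained proportion equals the Day-0
active proportion" — is not the independence null; under independent
re-draws the expected maintained proportion would be p₀² + (1 − p₀)².
Both are computed and labeled; the p₀ form is the default for fidelity,
the independence form for statistical correctness. Expected counts below 1
trigger a validity warning.

Dynamics-class retention is |class_day0 ∩ class_dayN| / |class_day0|, with
classes assigned on both days using Day-0 (or control) thresholds, plus
the Venn counts (day-0 only, day-N only, both). Treatment effects are
summarized as 100·(post − pre)/pre of per-mouse mean metrics, compared
between conditions with an unpaired two-tailed t test (equal variances
assumed by default to mirror the study's test; Welch available). Normality
is assumed, not tested.

## Line-scan flow

A line across a vessel scanned at 300 lines/s yields a 1-D intensity
profile in which unlabeled cells transiting the fluorescent plasma appear
as valleys. The profile is partitioned into 600-sample (2 s) blocks;
flux = valleys per block / 2 s, in cells/s.

Valley detection first smooths the profile with a short moving average
(default 5 samples, about a quarter of a typical transit width; 1 disables
it): raw samples are far noisier than transit valleys are wide, and
counting raw minima mistakes single-sample noise excursions for cells. On
the smoothed profile, valleys are local minima satisfying per-block rules:
prominence ≥ 0.3 × (block median − block minimum), pairwise separation ≥
`min_distance` (default the expected valley width), width within [2, 50]
samples, and minimum value ≤ 0.6 × block median — the intensity
qualification that rejects shallow fluctuations riding on the bright
dextran baseline. These defaults stand in for the per-vessel parameters a
user would tune interactively; all are logged and overridable. Vessels
whose per-block red median ranges over more than 30% of the global median
are flagged by QC as baseline shifts (field drifted off the vessel) and
should be discarded.

Blocks are labeled from the green (Ca²⁺) channel: a block is `during` iff
its green mean strictly exceeds 1.5 × the minimum block mean. Gap blocks
between two during-runs are split by proximity (nearer the preceding run →
`after`, nearer the following → `before`, ties → `before`); leading and
trailing gaps are `before`/`after`; with no during-run every block is
`no_event`. The smoothed flux trend is a centered 5-point moving average
(2 prior, 2 after; the window shrinks at the series edges). Per period
(maximal run of during or non-during blocks): change = flux at last block −
flux at first block (0 for single-block periods), average flux = period
mean, and period durations are split at mean + 1 SD within each kind.
Signaling vs non-signaling changes are compared by unpaired two-tailed
t test.

## Morphometry and permeability

**Loops.** Fully enclosed vascular loops are connected components
(8-connectivity) of the vessel-mask complement that do not touch the image
border, with area ≥ `min_area_px` (default 4). Measurements: pixel area,
centroid, equivalent diameter √(4A/π), and perimeter by an 8-connected
Moore boundary trace summing unit steps and √2 diagonal steps. The
perimeter estimator is fixed and documented because perimeter comparisons
are only meaningful within one estimator; single-pixel regions have
perimeter 0 under it.

**Linear EC density.** Nuclear centroids snap to the nearest skeleton
pixel by Euclidean distance (ties resolve to the lexicographically
smallest (row, col) pixel) and are retained iff the distance is strictly
under 10 µm. Skeleton node pixels are those with ≠ 2 eight-connected
skeleton neighbors; adjacent node pixels collapse into single junction
nodes (a connected-neighborhood grouping, since 8-connected junctions are
several pixels wide), and segments are maximal paths between nodes through
degree-2 pixels. Geodesic length sums the step lengths (1 or √2 × pixel
size) along the path; isolated cycles are traced as single closed
segments. A nucleus snapped to a junction pixel counts toward the first
incident segment in the deterministic (lexicographic) walk order — an
arbitrary but fixed tie rule. Density = 100 × n_nuclei / length (cells per
100 µm); cells/µm is also emitted.

**Permeability.** The extravascular region is the complement of the vessel
mask dilated by 2 px by default (guarding against partial-volume bleed at
vessel edges; 0 disables the margin). Each post-injection frame's
extravascular mean is divided by the pre-injection recording's average
extravascular mean; the series is scale-invariant under common intensity
rescaling and is also sampled at requested minutes post-injection (nearest
frame).

## Synthetic data

The generators produce every input the pipeline consumes, with planted
ground truth. Defaults are the homeostatic study conditions: 300 frames at
3.44 s/frame (a 0.62 s dialect is a parameter change), ~50% active cells,
0.45 events/min per active cell, mean event duration 8.4 s, baseline MFI
100 on the 0–255 scale, event amplitude 1.6× baseline, persistent cells
(default fraction 0; ~0.19 emulates the knockout condition) held at MFI
200 for the whole recording. Line scans default to 150 two-second blocks
of 600 samples, baseline 200, valley depth 120, width 20 samples.

Choices worth knowing:

- Nuclear ROIs are ellipses with ≥ 2 px margins, so label masks are
  disjoint by construction and trace extraction is unambiguous. Placement
  beyond the retry budget raises a placement error.
- Event placement is a censored Poisson process (count ~ Poisson(rate ×
  minutes), uniform starts, exponential durations of ≥ 1 frame); events
  truncated at the recording boundary are kept and flagged censored, since
  detector boundary behavior is itself under test. Planted events keep
  ≥ 1 quiet frame between them (maximal-run detection cannot distinguish
  abutting events) and ≥ 1 baseline frame per 100-frame window (the
  windowed minimum must see baseline to be well defined).
- Noise is Gaussian, clipped to [0, 255] — the simplest model that
  exercises threshold robustness. Poisson shot noise, optics (PSF,
  scattering), motion artifacts and spectral bleed-through are explicitly
  not modeled, so passing tests demonstrate correctness of the
  quantification rules, not robustness to those real-data effects.
- Event durations and inter-event intervals use exponential draws because
  the in-vivo distributions are not established; both are parameters, not
  claims.
- Transit counts per line-scan block are round(flux × block duration);
  valleys are smooth cosine dips of exact support `valley_width`, with
  centers separated by ≥ 2 × width by default (`min_separation` lowers
  this to allow colliding transits).
- Vessel geometry plants rectangular annuli (one enclosed hole each) for
  loop detection, and disjoint 1-px straight/diagonal polylines in
  separate bands for segment analysis, with nuclei exactly on segment
  pixels (distance 0) plus optional off-skeleton nuclei at stated
  distances for the retention rule.
- Revisit pairs draw Day-0 status Bernoulli(p_active); the revisit keeps
  status with probability p_maintain, or redraws independently under the
  null mode.

Identical seeds reproduce identical outputs bit for bit in every
generator.

## Numerical and testing notes

- The detector is validated against an independent brute-force oracle
  (frame-by-frame windowed-minimum thresholding + run merge) on random
  traces, and cluster linking against an exhaustive spatiotemporal flood
  fill on small rasters.
- The χ² statistic matches the closed form to 10⁻⁹ and its type-I error is
  calibrated at 5% (within [0.03, 0.07]) under the p₀ null with n = 200
  matched cells per replicate — a realistic per-region revisit count given
  100–150 cells per region.
- Planted-event recovery runs on 200 seeds noise-free (exact start/end
  frames) and on 40 seeds at noise SD = 5% of baseline (event-level recall
  and precision ≥ 0.95, events pooled across seeds); recordings use 100
  cells in a 200 × 200 px field, sizes chosen to keep the default suite
  fast while preserving the stated cell count.
- Flux recovery runs 200 seeds at SNR 5 (valley depth / noise SD) with
  non-overlapping valleys (exact per-block counts) and one 150-block run
  with overlapping valleys (mean flux within 5%).

## Known limitations

- No motion correction, segmentation of real imagery, or registration
  across sessions: masks, labels and cell correspondences are inputs.
- The censored-event convention (observed duration, no correction) biases
  average durations downward slightly for events clipped by the recording.
- The p₀ conservation null is reported verbatim alongside the independence
  null rather than resolved; they answer different questions.
- Grid tiling anchored at the image origin is a convention; an anchor at
  the mask bounding box would shift partial edge grids.
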