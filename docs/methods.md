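# Methods

This note documents the models behind each pipeline stage, the tunable
parameters with their defaults and units, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Synthetic cells

**Geometry.** A migrating cell is two half-ellipses joined at their common
widest point: a blunt front half (semi-axis `a_f`) and a longer tapered rear
half (`a_r`), sharing the semi-width `b`. Area `πb(a_f+a_r)/2` and perimeter
are analytic, so the ground truth for the shape metrics needs no
rasterization. Per cell, area is uniform on `cell_area_um2_range`
(default 38–60 µm², the particle gate of the tracking assay), the
length/width aspect is ~N(2.1, 0.2) clipped to [1.6, 2.8], and the front
fraction is 0.42. Dead cells are circles.

**Channels.** `(membrane, actin, reporter, viability)`, in that order.
The membrane is a Gaussian ridge on the cell outline. The actin channel is a
cortical Gaussian band displaced *inward* from the membrane by a spacing that
depends on the outward normal's angle to the migration direction: the
leading-edge value (default 174 nm) on the front arc (within 60°, with a
smooth roll-off to 80°), the side value (default 43 nm) elsewhere, plus a
diffuse cytoplasmic floor and a leading-edge amplitude enrichment. The
reporter is membrane-tethered (both MPAct and CaaX are) and modulated along
the normalized axial coordinate `u` (0 = rear, 1 = front) by
`m(u) = (1 + (E−1)u)(1 − (1−D)u)` with `E = reporter_front_enrichment` and
`D = mpact_front_depletion`. Dead cells fill the viability channel
(propidium-iodide-like) and are stationary and round.

**Rendering.** Signed distances to the boundary polyline are computed per
pixel (KD-tree nearest boundary point, inside test from the implicit shape
equation). The point-spread function is folded analytically into the
normal-direction profile widths (`σ_eff = √(σ_intrinsic² + σ_PSF²)`) rather
than applied as an image-space blur: the membrane line (σ 30 nm) is far
below one pixel at widefield sampling (0.325 µm/px) and image-space blurring
of a point-sampled sub-pixel line aliases into a broken ring. The analytic
fold is exact for a straight edge and accurate when the curvature radius is
much larger than σ, which holds for these cells. The trade-off: tangential
blur of the speckle texture is not modelled.

**Speckle flow.** A frozen 1-D random pattern on a 0.05 µm arc grid,
advected along the cortex at `flow_um_min` and sampled with linear
interpolation, modulates the cortical band amplitude (contrast 0.45). A
separate TIRF-like generator (`generate_speckle_movie`) advects a frozen 2-D
speckle field across a stationary field of view — the retrograde-flow assay
images non-translocating cells on PEG-coated glass, so the moving texture on
a fixed cell is the physically faithful picture.

**Noise and determinism.** Poisson shot noise (optional) is applied to the
rendered counts, then additive Gaussian read noise. All randomness derives
from one root seed through counter-based substreams
(`SeedSequence(seed, spawn_key=(kind, index))`), so increasing `n_cells`
appends cells without reshuffling existing ones and identical configurations
are bit-identical.

**Ground truth.** Each cell records its realized speed, direction, area,
circularity, spacings, polarity ratio, perimeter polarization, flow and
viability. The polarity ground truth applies the pipeline's own 12-bin
front-3/back-3 definition to the analytic boundary modulation `m(u)`
(arc-length weighted), not to rendered pixels — so recovery tests compare an
image-derived estimate against an image-free reference.

**What is not emulated.** No photorealism, no 3-D PSF, no deconvolution
artefacts, no nucleus beyond reporter exclusion, no shape dynamics
(protrusion/retraction), no collisions (cells are placed so trajectories
stay separated in every frame), and no chromatic offsets. Passing recovery
tests therefore demonstrates estimator correctness on data matching the
stated geometric and noise model, not robustness to every property of real
microscopy.

## Tracking and shape

The detection channel is thresholded with the triangle construction on a
256-bin histogram (maximum perpendicular distance from the peak-to-far-tail
line, in normalized coordinates), holes are filled *before* the radius-1
binary opening (a thin membrane ring would not survive opening first), and
8-connected components are gated to [38, 60] µm² inclusive.

A membrane stain thresholds to the faint outer tail of the ring, so the
filled outline overshoots the cell. Ring-stain masks (auto-detected: interior
much dimmer than the mask maximum) are eroded until the boundary band sits on
the intensity ridge (deepest erosion within 1% of the best boundary-mean
score), and the metrics are corrected for the half of the boundary band that
straddles the ridge. Cytoplasmic-dye masks are used as-is. On noise-free
synthetic frames the corrected areas sit within ~3% of ground truth.

Perimeters come from the marching-squares contour simplified by
Douglas–Peucker at 0.7 px tolerance — the raw contour staircases on smooth
outlines and would overestimate a disc's perimeter by ~5%, while the
simplification keeps true corners, so discs score circularity ≈ 1 and squares
≈ π/4.

Linking is greedy mutual nearest neighbour per consecutive frame pair
(globally smallest distance first), gated at `max_disp_um` (default 3× the
median per-frame displacement from an ungated first pass), with no gap
closing. Track exclusion: viability-positive tracks (majority of detections
above the viability channel's triangle threshold) and tracks strictly shorter
than `min_fraction · n_frames` (½ under agarose, ⅓ in collagen; a track of
exactly the boundary length is kept). Speed is path length over elapsed
time.

## Polarity profiles

The axial coordinate of a pixel is its projection on the migration-direction
unit vector through the mask centroid; the cell length is split into 12
equal-length bins spanning the full width, ordered leading-edge first. Bins
are equal in length, not in pixel count (the protocol draws equal-length
bins along a line). 0–1 normalization is per protein per cell; a constant
profile normalizes to zeros with a degenerate flag. LE/TE anchoring flips
all profiles when the CDC42 peak bin comes after the CD44 peak bin and flags
a conflict when the two peaks are within 2 bins.

Perimeter polarization uses the marching-squares contour resampled to ~1 px
arc spacing (single-pixel bilinear samples, not band averages); the window
is ⌈0.25 N⌉ samples centred on the argmax with wrap-around, ties to the
lowest index.

The MPAct/CaaX ratio divides the *max-normalized* (highest value per
fluorophore per cell set to 1) MPAct profile by the max-normalized CaaX
profile; the polarity scalar is the mean of the front 3 ratio bins over the
back 3. Max normalization rather than min-max is deliberate: a uniform CaaX
profile min-max-normalizes to all zeros and the ratio would be undefined,
whereas divide-by-max leaves it at 1 — and it is what the assay description
prescribes. Bins with normalized CaaX below 0.05 are excluded from the ratio
(guard against near-zero denominators). 95% CI bands on mean profiles are
per-bin `mean ± 1.96·SEM` across cells.

## Membrane-to-F-actin spacing

The leading edge is the longest contour arc whose outward normal lies within
60° of the migration direction. Each arc point is re-centred on the membrane
ridge (parabolic peak along the normal, then a 5-point moving average along
the arc), and a 30-px band is resampled along the inward normals (bilinear),
row 0 outermost. Perpendicular lines average 20 adjacent columns with a
10-px step (50% overlap — the protocol says "overlapping" without a step),
are 0–1 normalized per channel, and aligned so the parabola-refined membrane
peak sits at position 0 with the interior positive.

Per line, the F-actin peak is the highest actin sample at positions in
(0, 400 nm] — interior side only, since cortical actin is intracellular —
refined by a 3-point parabola and clamped non-negative; the per-cell value
is the mean over lines. Two numerical guards matter at realistic noise:

- each line is Gaussian-smoothed (σ = 1 sample) before peak finding. The
  smoothing is shift-free for a symmetric peak; without it, noise on the
  flat peak top scatters the argmax and the one-sided window turns that
  scatter into a systematic overestimate (about +11 nm at SNR 10 for a
  43 nm truth);
- an argmax on the outer window edge with the profile still rising is the
  truncated tail of an exterior peak, not a peak within the window; the
  estimator falls back to the best interior local maximum, or skips the
  line (flagged) if none exists. A window smaller than the true spacing
  therefore refuses to answer rather than returning the window edge.

Frame choice for movie-level analysis is a seeded uniform draw (the manual
protocol picks a random frame while viewing only the membrane stain), and
the chosen frame is recorded in the output. Spacing–speed correlation is
Pearson r with a two-sided t-test (n−2 df) and an ordinary least-squares
line; the per-cell spacing entering the correlation is the mean of per-line
distances.

## Retrograde flow

Kymographs sample a polyline (resampled to 1 px arc spacing, width-averaged
across 5 px by default) in every frame, giving an (arc, time) array. The
stripe slope is found by an orientation scan — rotate, project, maximize
projection variance, equivalent to a Radon-transform variance criterion —
at 1° coarse and 0.1° fine steps with parabolic refinement, then sharpened
by a long-lag column correlation: columns half the kymograph apart are
cross-correlated within ±3 px of the displacement the coarse slope predicts,
measuring the accumulated shift over many frames directly. The restriction
to the predicted neighbourhood keeps a static background from dragging the
estimate to zero; the automated readout replaces manual kymograph reading
for reproducibility. Flow = |tan θ| · pixel / Δt, reported as a magnitude
(retrograde by construction of the assay). A kymograph whose peak
orientation response is below 2.5× the median response is flagged
indeterminate. For kymographs along the cell cortex, where moving speckles
ride on static structure (leading-edge enrichment), `detrend="row"`
subtracts each position's temporal mean first; it is off by default because
it would erase genuinely stationary stripes.

Parameter recovery: relative error ≤ ~3% for flows of 1–20 µm/min at SNR 5
on synthetic speckle movies (documented tolerance 10%).

## Volumes, media, ICP-MS, NMR

Stack volume is Σ(slice area)·Δz. Modal volume is the centre of the tallest
1-fL histogram bin on the instrument granularity grid, ties to the lower bin,
requiring ≥ 100 cells (the mode of a smaller sample is unstable); the median
aggregator is also provided, the modal readout is the default. Osmolarity
arithmetic is linear in concentration (ideal solutions): replacing a
fraction `f` of the isotonic medium (292 mOsm/l) with NaCl-free solution
gives `292(1−f)`, reproducing 277.4 / 262.8 / 248.2 / 233.6 mOsm/l exactly;
non-ionic osmolytes (d-sorbitol, L-glucose) contribute 1 mOsm/l per mM. The
ICP-MS chain divides analyte counts by internal-standard counts (removing
instrument drift), subtracts the mean of IS-normalized repeat blanks, and
converts through an ordinary-least-squares six-point calibration with free
intercept; negative blank-corrected signals clamp to zero concentration with
a flag rather than propagating. The noiseless chain inverts the synthetic
plate generator exactly.

## Statistics

Mann–Whitney U is exact (full enumeration) when the smaller group has ≤ 8
observations and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections; p-values are two-sided
throughout. Kruskal–Wallis uses the tie-corrected H with a chi-square
reference (k−1 df); all-identical data return H = 0, p = 1 rather than an
error.

The two-stage step-up FDR is defined here as: stage 1, a Benjamini–Hochberg
step-up at the deflated level α/(1+α), whose rejection count r₁ estimates
the number of true nulls m₀ = m − r₁; stage 2, a BH step-up at the inflated
level α·m/m₀. q-values are the adaptive BH quantities with m₀
(`q_i = min_{j≥i} m₀ p_(j)/j`, capped at 1), so the stage-2 discoveries are
exactly q ≤ α, the procedure never rejects fewer hypotheses than plain BH at
α, and it reduces to plain BH when stage 1 rejects nothing. (The published
two-stage procedure runs its second stage at the deflated level α′·m/m₀;
the α-level variant used here is the one consistent with reporting
adaptive-BH q-values against the nominal α and is marginally more liberal —
the two differ by a factor 1+α on the stage-2 threshold.) Monte-Carlo checks
under the global null (m = 100, 1000 replicates) confirm the false-discovery
proportion stays within 2 standard errors of α. One-/two-way ANOVA,
mixed-effects and Friedman analyses are routine fits that belong to a
general statistics backend and are intentionally not re-implemented.

## Problem sizes used in the test suite

Recovery tests run at the smallest scales that exercise the estimators: the
tracking movie is widefield-like (0.325 µm/px, 640–768 px fields, 16–20
frames, 7–10 cells), polarity/spacing movies are iSIM-like (0.1083 µm/px,
512 px, 6 frames, 3 cells), spacing stacks use 100 lines at SNR 10, flow
movies 60 frames, and the FDR oracle comparison 1000 random vectors of up to
20 p-values. Documented recovery tolerances: speed 5% (median), MPAct
polarity 15%, leading-edge spacing ± half a sampling step, flow 10%.

## Known limitations

- The generator's speed distribution is a free choice (log-normal spread
  around the configured mean); published speed figures are box plots without
  numeric parameters, so no calibration to them is claimed.
- Segmentation-mask areas from membrane stains carry a residual ±3% bias
  from integer-pixel erosion; cytoplasmic-dye segmentation does not.
- The straightening step assumes a locally smooth leading edge; strongly
  ruffled edges would need a finer contour model.
- Kymograph placement on real data requires the analyst to choose the
  sampling line; only the synthetic pipelines place it automatically.
- No claim of numerical equivalence with the original interactive toolchain
  (TrackMate, FIJI kymograph reading) is made — the automated readouts are
  validated against generator ground truth instead.
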