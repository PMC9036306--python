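# Methods

This note documents the models, conventions and numerical choices behind
`skinquant`, what the synthetic data generator does and does not emulate,
and the known limitations.

## Coordinate and unit conventions

All geometry lives in pixel units, row-major `(row, col)`, 0-based, pixel
centers at integer coordinates, and is converted to micrometres only at
reporting time through a single `ScaleCalibration` (px/µm). Calibration is
mandatory caller-supplied metadata — typically from a measured scale bar
(`calibrate_from_scale_bar`) — and is never guessed from image headers,
because exported TIFF/PNG rasters lose physical resolution unreliably.
GeoJSON annotations use `(x, y) = (col, row)`.

`split_dilation_steps` exists to document and verify the manual workaround
for raster editors that cap a single selection expansion (at 500 px): it
returns the minimal number of near-equal integer steps. The pipeline itself
never iterates dilations — the dermal band uses an exact Euclidean distance
transform.

## Rasterization

A pixel belongs to a polygon if its center lies inside, with a half-open
tie-break (centers on left/top edges are inside, right/bottom outside) so
adjacent polygons partition the grid exactly. Implementation: the center is
nudged by +1e-7 in both axes before a prepared-geometry containment test.
Tests verify this against an independent ray-casting oracle and against the
shoelace area (agreement within one perimeter's worth of pixels for convex
polygons).

## Compartment geometry

The dermal compartment is `{pixels with Euclidean distance ≤ depth_px from
the epidermis mask}` minus the epidermis, then clipped: pixels strictly
left/right of the boundary polylines (linearly interpolated by row, extended
with end values) and pixels above the apical polyline are removed. "Apical =
vertically above" assumes the slide was aligned horizontally before export,
which the workflow requires. Depth defaults to 400 µm, the band that
captures the vast majority of dermally infiltrating T cells near the
epidermis.

Epidermal length is measured on the apical surface polyline (the default
denominator); the dermo-epidermal interphase can be measured with the same
operation if supplied. `estimate_length_by_chords` reproduces the
ruler-tool approximation — resampling at n+1 equally spaced arc-length
points and summing chords — and is always ≤ the polyline length,
converging from below as n grows.

## Stain classification

*Threshold route.* A pixel is positive when its RGB Euclidean distance to
the nearest reference color is within a tolerance (default 60; the maximum
possible distance is √3·255 ≈ 441.7). Plain RGB distance is used because it
is exactly reproducible, unlike the undocumented "fuzziness" of interactive
color-range tools. The optional coherence dilation (discrete disk, default
radius 2 px) merges fragmented selections. **On synthetic sections the
threshold captures painted cells wholly, so recovery runs disable the
dilation (radius 0): with nothing fragmented to repair, a dilation would
simply add one margin of ring area to every cell.** On real stains, where
the operator's color picks cover only part of each cell, the 2–3 px radius
is the appropriate default and remains the config default.

*Classifier route.* A small MLP (one hidden layer of 16 units, scaled
inputs, fixed random state) over a declared 12-feature recipe at a working
resolution of 0.91 µm/px: per-channel intensity, per-channel Gaussian blur
at σ = 1 and 2 px, per-channel Sobel gradient magnitude. Training data come
from square annotated tiles (default 100×100 µm) resampled to working
resolution and composed into a grid montage; labels are carried through the
resampling by one-hot interpolation and argmax (majority). Training pixels
are deterministically subsampled to at most 20 000; accuracy is reported on
all labeled pixels; single-class training data is an error. At apply time
the image is downsampled (Gaussian-prefiltered linear resampling as the
area-weighted approximation), classified per pixel, and the binary mask is
upsampled with nearest-neighbor so it stays binary. Manual corrections are
supported as an XOR polygon layer, not interactively.

## Cell quantification

A "cell" is a connected component (default 8-connectivity) of the positive
mask passing the size filter. The default minimum area is a 2 µm-diameter
disk at the image calibration — a sub-lymphocyte debris filter declared by
this package, not inherited from any protocol. Touching cells are counted
as one component (no watershed); this is the operational definition of a
count here. Circularity is `4π·area/perimeter²` with the standard weighted
perimeter estimator, reported but not used for filtering; a degenerate
component with zero estimated perimeter reports circularity 1. A component
straddling the compartment border is counted where its centroid lies, while
stained area always splits by exact pixel membership, so areas are conserved
and counts stay integers.

Random-grid subsampling tiles the ROI with squares of a given physical side,
indexes squares by grid position (so every point belongs to exactly one
square), and selects a seeded uniform subset; scaling the subsample count by
M/selected is an unbiased estimator of the ROI total, verified by Monte
Carlo over 500 seeds.

## Density metrics

Per compartment (epidermis, dermis, total = their sum):
`area_per_length` (µm²/µm), `area_per_area` (dimensionless), and counts per
mm / mm². The two normalizations satisfy the exact identity
`area_per_area = area_per_length · L / A[c]`, asserted on every report the
test suite builds. For NL/LS pairs the area-dilution factor
`(L_LS/A_LS)/(L_NL/A_NL)` uses the *epidermal* compartment area; 100·(1 −
factor) is the percentage by which per-area normalization shrinks the
apparent increase. This percentage is data-dependent (it reflects the
realized thickness change of the samples at hand), so the package reports
per-pair factors and their mean ± SD rather than a single constant. The
cohort-level contrast between per-length and per-area relative increases is
tested with a paired Student t-test on the epidermal stained-area metric.

## Agreement statistics

Bland–Altman differences are (classifier − threshold) in the metric's
native units; bias is the mean difference, SD uses n−1, limits of agreement
are bias ± 1.96·SD (multiplier configurable). The agreement report covers
six strata: stained cell area for epidermis/dermis/total under each
normalization. `run_cohort` emits two regression families: *density
regressions* (stained-area density vs count density, per compartment and
normalization — the question of whether areas and counts measure the same
infiltrate) and *method regressions* (classifier vs threshold per stratum).
Degenerate regressions in a cohort (constant regressor, e.g. identical
samples) are skipped with a logged warning rather than aborting the run. No
multiple-testing correction is applied.

## Synthetic sections

The generator draws a horizontally aligned section: slide background above,
an epidermal band whose apical/basal edges follow a sinusoid (amplitude
10 µm, wavelength 300 µm by default), dermis below; stained cells are
non-overlapping ellipses (axis ratio ≤ 1.5, radius 3.5 ± 0.7 µm truncated
at 2 µm) of DAB-brown color with per-pixel Gaussian color jitter (SD 4).
Default conditions: 2.2 px/µm (the scale-bar example), 600 µm of section
width, 100 µm epidermal thickness, a 400 µm dermal band, 80 epidermal and
120 dermal cells. Exact-bookkeeping constructions:

* the epidermis occupies, per column, the integer rows in `[f(c), f(c)+t_px)`
  with integer `t_px`, hence exactly `t_px·width` pixels at any phase;
* integer cell centers make ellipse footprints translation-invariant, so the
  NL/LS generator realizes a stain factor ρ *exactly* by replicating the NL
  shape list ρ times (when ρ·count is integral);
* a minimum 3 px gap between cells makes component counting exact.

Because thickness is rasterized to integer pixels, the realized NL/LS
thickness ratio equals the requested k only when k·t_px is integral (true
for the default k = 3); ground-truth identities are therefore stated
against the realized ratio carried in `GroundTruth`.

NL/LS pairs share the undulation phase, so both members have identical
epidermal length; the pair baseline used in tests is a sparse non-lesional
infiltrate (8 epidermal / 24 dermal cells) scaled ×10 in the lesional
member with ×3 thickness.

What the generator does **not** emulate: staining-intensity variation,
out-of-focus blur, tissue folds, touching/overlapping cells (a deliberate
violation of the count-recovery contract if enabled), dendritic
morphologies, or photorealistic histology. Passing the recovery suite
therefore demonstrates the pipeline's arithmetic and geometry are right on
idealized sections — not that classification is robust to real-world stain
variability, which no desk-scale fixture can show. An optional melanin
speckle layer (same brown hue family at reduced chroma, off by default)
exercises the pigment confounder.

## Problem sizes and tolerances in the test suite

The recovery and agreement suites run on ten default sections (seeds 1–10,
about 1260×1320 px each) and three to ten NL/LS pairs — sizes chosen so the
whole suite completes in about a minute while still exercising full-scale
geometry. Tolerances: cell counts exact; stained area within 5 % (threshold
route is pixel-exact; the classifier route carries the boundary-discretization
bias below); epidermal length and compartment areas within 2 %; ground-truth
bookkeeping identities at 1e-12; OLS r² vs the squared Pearson correlation at
1e-12; Bland–Altman coverage within 94–96 % on 10⁴ Normal differences.

## Known limitations

* The MLP classifier systematically over-covers cell boundaries by roughly
  half a working pixel after nearest-neighbor upsampling, inflating stained
  area by ~3 % on default sections. This is a discretization effect of
  classifying at 0.91 µm/px, not a color confusion; it stays well inside the
  5 % method-agreement band but is visible as a positive Bland–Altman bias.
* The feature recipe and network size are a declared minimal stand-in for
  the much richer default feature sets of interactive trainable-segmentation
  tools; no claim of equivalence is made.
* Counts treat touching stained cells as one object; dense infiltrates are
  better quantified by stained area (which is why both are reported).
* Proprietary whole-slide formats, pyramidal reading, and automatic
  epidermis segmentation are out of scope; the epidermis outline is an
  operator input by design.
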