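# Methods

`ccpipe` estimates canopy cover (CC) — the fraction of ground covered by
plant material — from nadir RGB images of field plots, and quality-controls
the resulting per-plot time series. This note documents the models and
procedures, their assumptions, the tunable parameters, and the design
choices made where the design was genuinely open.

## Image model and vegetation indices

Input rasters are 3-channel images rescaled to [0, 1]. The pipeline treats
the first channel symbolically as "R"; on cameras whose red channel has
been converted to near-infrared, that channel carries NIR signal, where
vegetation reflects strongly. All index formulas are channel-symbolic, so
no code path depends on which physical band the channel holds.

Plain indices (on [0, 1] channels): ExR = 1.4R − G, ExB = 1.4B − G,
ExR − ExB, NDI2 = (R − B)/(R + B) and NDI3 = (R + G − 2B)/(R + G + 2B).
Pixels with a zero NDI denominator (pure black) map to 0, the
background-neutral value.

Product indices multiply an NDI plane with a color-space plane to sharpen
the plant/soil contrast where the raw index is flat: NDI3·V (HSV value, in
[0, 1] already) and NDI2·a, NDI3·a (CIE Lab a-plane). The a-axis is signed
with no canonical multiplicative scale, so it is min-max rescaled per
image to [0, 1] before the product; this preserves the sign structure of
the NDI factor and keeps thresholds comparable across images. A constant
a-plane (degenerate rescale) maps to 0.5 with a warning. Lab conversion
uses the sRGB/D65 convention throughout.

Because NDIs are ratios, they are invariant to multiplicative illumination
changes; the V factor deliberately re-introduces brightness so that
thresholding can exploit it. NDI3·V is the default segmentation plane.

## Automated thresholding

**μRow.** Drilled crops show periodic rows. Averaging a VI image across
all image rows yields a column profile whose peaks sit on the plant rows.
A penalized natural cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`) suppresses pixel noise; the
penalty is `(smooth_strength × profile_length)⁴` so the effective
bandwidth scales with image width (default `smooth_strength = 0.018`,
which resolves 6–12 rows per frame without merging neighbours — the
default is set so that a 10-row synthetic stripe image yields exactly 10
peaks). Peaks are detected on the spline subject to a minimum spacing
(`min_row_spacing_px`, default 12) and a minimum prominence of 10 % of the
smoothed profile's value range — a relative floor, which makes the whole
procedure equivariant under affine rescaling of the VI
(threshold(αv + β) = α·threshold(v) + β for α > 0). The threshold is the
arithmetic mean of the *smoothed* profile at the detected peaks (peak
values are read off the spline, where they are defined); troughs are
detected and reported for diagnostics but play no role in the threshold.
With `row_axis="auto"` both orientations are profiled and the one with
the more regular inter-peak spacing (lower coefficient of variation) wins.
A profile with no qualifying peak — bare soil, pre-emergence imagery, or a
constant plane — raises `NoRowsDetectedError`; the pipeline then falls
back to Otsu when configured to.

Near-flat handling: a constant profile smooths to numerical ripple of
order 1e-16; any profile whose smoothed range is below 1e-8 of its
magnitude is treated as flat rather than letting the relative prominence
floor resurrect noise peaks.

**Otsu.** VI values are histogrammed into 256 bins over [min, max]; every
interior bin edge is a candidate and the between-class-variance maximizer
is returned, ties resolving to the lowest candidate. The argmax is
invariant to affine transforms of the bin centers, so the criterion is
evaluated in exact integer arithmetic on bin indices (criterion
∝ (S₀w₁ − S₁w₀)²/(w₀w₁) with integer class weights w and index-weighted
sums S, compared by cross-multiplication). Floating-point round-off can
therefore never flip the selected bin — the test suite checks exact
agreement with an independent rational-arithmetic exhaustive search.

Masks use the strict convention plant = (vi > t); the boundary convention
is not observable on continuous data but is frozen for reproducibility.

## Illumination-scenario classification

Field illumination is grouped into two scenarios: **LLC** (low
light-contrast, class 1) — all scene detail captured, histogram mass in
the low-to-mid intensities — and **HLC** (high light-contrast, class 2) —
extremely bright (often saturated) and deep-shadow regions present. The
feature is the concatenation of the three per-channel 256-bin histograms
of the 8-bit-quantized image (768 values), each block normalized to
frequencies so images of different sizes are comparable. The classifier
is an RBF-kernel SVM (C = 1, variance-scaled gamma — the standard
configuration; the hyperparameters are exposed). The label convention is
1 = LLC, 2 = HLC; because the opposite mapping also circulates in the
field-phenotyping literature, the convention is stated here explicitly
and fixed throughout the package.

## Pixel segmentation

Supervised models classify each pixel from a fixed-order 10-column
feature vector: R, G, B, H, S, V, L, a, b, NDI3·V. The column order is
recorded in the trained model and checked at prediction time, making
models portable across runs. Two algorithms are provided:

* **DT** — a decision tree, depth-limited to 10 to avoid pure
  memorization of training pixel values;
* **SVM** — a linear SVM (`LinearSVC`), chosen for tractable per-pixel
  prediction on full frames; an RBF pixel-SVM is prohibitively slow at
  frame scale and linear separation suffices in this feature space.

Training tables larger than the pixel budget (default 500,000) are
stratified-subsampled with the caller's seed. Models are trained per
illumination scenario — M_LLC, M_HLC and the pooled general model M_ALC —
and collected in a `ModelBank`. At run time the illumination label routes
each image to its scenario model (1 → M_LLC, 2 → M_HLC), falling back to
M_ALC with a logged warning.

The unsupervised alternative clusters the per-pixel Lab (a, b) values
with K-means (k = 3, 10 restarts, seeded) and takes the cluster with the
highest mean NDI3 as plant — the same construction by which vegetation is
picked out of NDVI imagery. A tie on mean NDI3 breaks toward the larger
cluster. Fewer than 3 distinct (a, b) values is a degenerate-clustering
error.

## Post-processing and canopy cover

Raw masks carry salt-and-pepper noise. Clean-up applies a 5×5 median
filter first (a local majority vote on binary data; reflect padding),
then removes 8-connected components strictly smaller than
`min_object_px`. The strictly-smaller convention (399 px removed, 400 px
kept) and the order (median before removal) are frozen by regression
tests. 8-connectivity keeps diagonal leaf segments joined.

The 400-px default matches ~21-megapixel plot frames. Object area scales
with the square of image resolution, so desk-scale synthetic frames
(160×220 ≈ 0.17 % of that area) use a proportionally smaller floor; the
tests and worked examples use 25 px. Canopy cover is the plant-pixel
fraction over the full frame or a configured rectangular ROI.

## Segmentation-accuracy factors

Against a reference mask R, a segmentation S is scored over plant pixels
by Qseg = |S∩R|/|S∪R| (Jaccard; 1.0 = perfect), Sr = |S∩R|/|R| (recall)
and Es = |S∩¬R|/|R| (false plant pixels relative to true plant count; may
exceed 1). Counts are exact integers, division last; Qseg ≤ Sr holds for
every pair since |S∪R| ≥ |R|. Degenerate cases: two empty masks agree
vacuously (Qseg = 1); an empty reference leaves Sr and Es undefined —
they are returned as NaN with a warning rather than raising, so batch
evaluation over early-season (bare) plots does not abort.

## Time-series quality control

The plot-wise CC vector of each date is Pearson-correlated (Spearman
optional) with that of every other date, over pairwise-complete plots
with at least 3 pairs. Within a season the plot ranking changes slowly,
so adjacent dates correlate strongly; a date whose correlation with
*both* chronological neighbours falls below `r_min` (default 0.5) is
flagged as a likely segmentation failure. Requiring both neighbours low
distinguishes one bad imaging day from a genuine biological shift (snow
cover or melt depresses a whole period, not a single date); end dates are
judged by their single neighbour. The 0.5 default sits between the
neighbour correlations observed on known-bad imaging days (≈ 0.1–0.4) and
the near-unity values of normal adjacent days, and is configurable.

## Synthetic field scenes

The generator renders drilled-crop plots: leaf blobs (disks of radius
2–5 px) accumulate with jitter along evenly spaced vertical rows until
the plant fraction is within ±0.02 of the requested cover. Plants are
bright in the first channel (mean 0.75, emulating an NIR-substituted red
channel) and dark in blue (0.15); soil is desaturated brown
(0.45, 0.40, 0.35); Gaussian pixel noise has sd 0.03. LLC scenes have
uniform illumination. HLC scenes are multiplied by a smooth field with
bright Gaussian patches — amplified deterministically until at least 5 %
of pixels saturate at the 8-bit ceiling — and shadow patches dimming to
≤ 0.25× in their cores. The truth mask is frozen *before* illumination,
so saturation and shadow create genuine segmentation difficulty without
corrupting the ground truth. All randomness flows from one seeded
generator per call; identical calls are bit-identical.

Campaigns follow per-plot logistic growth
cc(t) = cc_max/(1 + e^(−rate·(t − midpoint))) with defaults drawn once
from realistic early-season wheat ranges: cc_max ~ U(0.55, 0.85),
midpoint at 35–65 % of the campaign span, rate ~ U(0.10, 0.18) day⁻¹.

What the generator does *not* emulate: leaf-level texture and specular
detail, mixed plant/soil pixels at low resolution, dirt on leaves, snow,
weeds, and plot-boundary effects. Passing tests therefore demonstrate the
pipeline's mechanics and its relative behaviour across illumination
scenarios — not absolute accuracy on real field imagery.

## Problem sizes in the test suite

Benchmarks run at desk scale, chosen to exercise every code path with
stable statistics: scenes of 120×176 to 160×220 px, 8 rows; the
illumination benchmark uses 100 + 100 scenes; scenario-model comparisons
train on 6 scenes per scenario (≈ 127k labelled pixels each, subsampled
to 60k) and test on 20 scenes per scenario; the series benchmark is 8
plots × 6 weekly dates. At these sizes the full suite runs in well under
a minute.

## Known limitations

* μRow presumes visible row structure; closed canopies (rows merged) and
  pre-emergence imagery defeat it — by design it fails loudly and the
  pipeline falls back to Otsu.
* The illumination classifier is a two-scenario model; overcast-bright,
  flooded or wet-leaf conditions would need additional scenarios and
  training data.
* Supervised models inherit the synthetic color model when trained on
  generated scenes; for real imagery, import labelled pixel tables
  (CSV with the 10 canonical feature columns plus `label`) instead.
* CC is computed over the full frame or a fixed ROI; plot-boundary
  detection from imagery is out of scope.
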