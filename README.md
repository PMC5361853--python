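# ccpipe

Canopy-cover phenotyping from nadir field imagery.

High-throughput field phenotyping platforms photograph hundreds of plots
daily through a growing season. Turning those images into reliable canopy
cover (CC) — the plant-pixel fraction of a plot frame — is hard because
field illumination is uncontrolled: bright days produce saturated leaves
and deep shadows that defeat any single segmentation rule. `ccpipe`
implements a three-stage pipeline for this problem, aimed at crop
scientists and breeders processing row-crop (e.g. wheat) plot imagery:

1. **Image conversion** — color-space planes (HSV, CIE L\*a\*b\*) and
   vegetation indices: ExR = 1.4R − G, ExB = 1.4B − G,
   NDI2 = (R − B)/(R + B), NDI3 = (R + G − 2B)/(R + G + 2B), and the
   contrast-enhanced product indices NDI3·V and NDI3·a. On cameras with an
   NIR-converted red channel, "R" carries near-infrared signal; the
   formulas are channel-symbolic.
2. **Segmentation** — automated thresholding (Otsu, and the row-profile
   **μRow** method: the threshold is the mean of the smoothed column-mean
   VI profile at its crop-row peaks), K-means clustering on Lab (a, b)
   with the highest-NDI3 cluster taken as plant, or supervised per-pixel
   models (decision tree / linear SVM over 10 features:
   R, G, B, H, S, V, L, a, b, NDI3·V). An SVM on whole-image RGB
   histograms (256 bins × 3 channels) classifies each frame as low or
   high light-contrast (LLC = class 1 / HLC = class 2) and routes it to
   the scenario-specific model M_LLC or M_HLC, with a pooled M_ALC
   fallback.
3. **Post-processing & QC** — 5×5 median filtering and small-object
   removal, CC computation, segmentation scoring against reference masks
   (Qseg = |S∩R|/|S∪R|, Sr = |S∩R|/|R|, Es = |S∩¬R|/|R|), and time-series
   quality control: plot-wise CC vectors are correlated between dates and
   a date whose correlation with both chronological neighbours collapses
   is flagged as a likely segmentation failure.

A seeded synthetic-field generator renders row-crop scenes with exact
ground-truth masks under both illumination scenarios, so every stage is
testable without field data. See `docs/methods.md` for the full model
description, parameter defaults and limitations.

## Worked example

```python
from ccpipe import (generate_field_image, compute_product_vi, otsu_threshold,
                    apply_threshold, denoise_mask, canopy_cover,
                    evaluate_segmentation)

scene = generate_field_image("LLC", row_count=8, cc_target=0.35, seed=7)
vi = compute_product_vi(scene.image, "NDI3V")
t = otsu_threshold(vi)
mask = denoise_mask(apply_threshold(vi, t.threshold), min_object_px=25)
rec = canopy_cover(mask, plot_id="demo", date="2014-11-07")
q = evaluate_segmentation(mask, scene.truth)
print(f"otsu threshold on NDI3V : {t.threshold:.4f}")
print(f"true canopy cover       : {scene.cc_true:.4f}")
print(f"estimated canopy cover  : {rec.cc:.4f}")
print(f"Qseg / Sr / Es          : {q.qseg:.3f} / {q.sr:.3f} / {q.es:.3f}")
```

prints

```
otsu threshold on NDI3V : 0.1659
true canopy cover       : 0.3500
estimated canopy cover  : 0.3228
Qseg / Sr / Es          : 0.835 / 0.875 / 0.047
```

The Otsu threshold on the NDI3·V plane sits between the soil (≈ 0.04) and
plant (≈ 0.46) index levels; the estimated cover is within 0.03 of the
ground truth, and the mask recovers 87.5 % of true plant pixels (Sr) with
4.7 % false plant area relative to the true plant count (Es). The
`min_object_px=25` floor is the 400-px full-resolution default scaled to
this 160×220 synthetic frame (object area scales with resolution squared).

The same flow runs from the shell over an image manifest
(`path, plot_id, date` CSV):

```sh
ccpipe synth scene --scenario HLC --cc 0.3 --seed 1 --out scenes/
ccpipe run --config config.yaml --manifest images.csv --out results/
ccpipe eda --cc results/cc.csv --out corr.csv --flags flags.csv
```

`ccpipe run` writes one mask PNG per image plus `cc.csv`, the
between-date correlation matrix `corr.csv`, flagged dates in `flags.csv`
and a plain-text QC report.

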