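# wmseg — two-step brain-tumor segmentation on 2D MR slices

`wmseg` is a tested re-implementation of a "watershed-matching" pipeline for
delineating hyperintense brain lesions (e.g. gliomas on FLAIR/T1c slices)
and staging them by area, aimed at researchers who want an inspectable,
fully scriptable baseline rather than a black box.  The pipeline has two
verification levels: the lesion is first segmented by an immersion
watershed transform, then the segmentation is *matched* against the expert
ground truth with SIFT keypoints before the clinical report is issued.

The stages are:

1. **De-noising** — trilateral (gradient-detilted bilateral) smoothing,
   then bilateral smoothing, then a 3×3 zero-padded median filter for
   impulse (salt-and-pepper) noise.  The improvement of a statistic *S* is
   reported as (*S*₀ − *S*₁)/*S*₀.
2. **Watershed segmentation** — intensity exclusion at *T*ᵢ (default 10),
   grayscale opening/closing with a flat 3×3 square, 3×3 Gaussian blur
   (σ = 1), Sobel gradient magnitude |∇I| = √(gₓ² + g_y²), binarization at
   *T*_g (default 0.5) times a histogram-derived gradient reference, and
   immersion flooding: a hole is punched at each regional minimum, water
   rises uniformly, and one-pixel-thick dams are built where basins meet.
   The brightest basin(s) above a hyperintensity floor form the tumor mask.
3. **SIFT verification** — from-scratch difference-of-Gaussians scale
   space, 26-neighbor extremum detection, Taylor sub-pixel localization
   with low-contrast/edge rejection, 36-bin orientation assignment, 128-d
   descriptors (4×4 cells × 8 bins from a 16×16 sample array), and
   ratio-test matching of the segmented lesion against the ground truth.
4. **Status report** — white-pixel count *W*, tumor size *W* × 0.264
   (1 pixel = 0.264 mm), and the staging rule: *W* ≥ 500 → *critical*,
   0 < *W* < 500 → *initial*, *W* = 0 → *no tumor*.

A seeded synthetic phantom generator (bright ellipse on dark parenchyma,
Gaussian + impulse noise, crisp analytic ground truth) makes every stage
testable without downloading a dataset.

## Worked example

`examples/` contains one narrative script per capability.  The end-to-end
run (`python examples/05_full_pipeline.py`) generates a ~650-pixel lesion
phantom, de-noises it, segments it and verifies the mask:

```
white pixels (W):  659
tumor size:        173.976 mm^2
status:            critical
SIFT matches:      8
pixel accuracy:    1.0000
Dice coefficient:  0.9985
verification:      PASS
```

The detected area (659 white pixels) crosses the 500-pixel boundary, so
the lesion is staged *critical*; Dice 0.9985 means the watershed mask and
the analytic ground-truth ellipse overlap almost perfectly, and the SIFT
matches confirm the segmented structure is the annotated one.

The same pipeline is scriptable from a shell:

```sh
wmseg generate --out-image img.png --out-mask truth.png --tumor-pixels 650 --seed 9
wmseg run img.png --truth-image img.png --truth-mask truth.png --outdir out/
```

which writes every intermediate artifact (filtered image, gradient image,
label map, mask, contour overlay, keypoint plot, CSV reports) under
`out/`.

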