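# Methods

This note documents the models and numerical choices behind `wmseg`, what
its synthetic phantoms do and do not emulate, and the design decisions
taken where the underlying procedure left details open.

## Conventions

Grids are indexed `(row, col)`, 0-based, row 0 at the top.  Intensities are
float64 internally on a nominal [0, 255] scale and clamped to that range
only when written to disk; colour inputs collapse to luminance with ITU-R
BT.601 weights (0.299, 0.587, 0.114).  Angles are degrees in [0, 360),
measured from the +col axis toward the +row axis.  The physical pixel scale
defaults to 0.264 mm/pixel.

## De-noising stack

The default stack is trilateral → bilateral → median: edge-aware smoothing
first, impulse rejection last.

* **Median (3×3, zero padding).**  Zero padding is deliberate — edge
  pixels are filtered against an explicit zero frame, so output size equals
  input size; a consequence is that corner pixels of a constant image
  darken (median of five zeros and four values).  The filter never invents
  intensities: every output value is a member of the padded input set.
* **Gaussian (3×3).**  Discrete kernel `exp(-(i²+j²)/2σ²)` normalized to
  sum 1, σ = 1 by default, reflective borders.
* **Bilateral.**  Normalized product of a spatial Gaussian (σ_s, window
  truncated at radius `round(3σ_s)`) and an intensity-difference Gaussian
  (σ_r).  Constant regions are fixed points; as σ_r → ∞ the filter
  converges to plain Gaussian blur over the same truncated window, which
  the tests exploit as an oracle.
* **Trilateral.**  The bilateral range weight penalizes any intensity
  difference, so it under-smooths sloped regions.  Here a bilaterally
  smoothed gradient plane (from central differences) is fitted at each
  pixel; neighbor differences are measured against that tilted plane, and
  the weighted residual is added back.  A clean linear ramp passes through
  exactly on the interior (the plane absorbs it); border pixels deviate by
  a few percent of the range because reflective padding folds the ramp.
  σ_r defaults to half the robust intensity range (1st–99th percentile).
  The detilt residual is not a convex average, so the output is clamped at
  0 to keep intensities physical.  One iteration by default.

Filter improvement factors are `(original − filtered) / original` for both
variance and standard deviation; the two reference statistic pairs the
package reproduces are consistent with this definition independently (the
printed variance and std pairs are *not* mutually consistent — the std
values are not the square roots of the variances — so each pair is treated
as its own statistic).

## Watershed segmentation

Pipeline: exclude pixels below *T*ᵢ (default 10) → grayscale opening then
closing (flat 3×3 square) → 3×3 Gaussian (σ = 1) → Sobel gradients (3×3;
central differences available behind config) → gradient reference *R* →
binarize at *T*_g·*R* (default *T*_g = 0.5) → flood.

*R* is the maximum gradient magnitude attained by pixels in the top bin of
a 256-bin intensity histogram of the smoothed image.  This makes the cut
scale linearly with intensity (Sobel is linear and bin membership is
preserved under scaling), so *T*_g is a dimensionless fraction rather than
an absolute gradient.  The flooded surface is the gradient magnitude with
sub-cut values flattened to zero: homogeneous tissue collapses into large
flat minima, which is what keeps over-segmentation manageable.

**Flooding.**  Immersion simulation with explicit tie-breaks (stated in
the module docstring and mirrored verbatim by the brute-force oracle in
the test suite): levels ascend; within a level, pixels adjacent to
labelled territory are seeded FIFO in raster order and grown breadth-first
with a fixed neighbor order; one distinct neighboring basin → join it, two
or more → dam (label 0), reachable only through dams → dam; leftover flat
zones become new basins, one per connected plateau.  Connectivity defaults
to 8.  Because only the intensity order matters, the labelling is
invariant under strictly increasing transforms of the surface.

**Tumor-basin selection.**  The procedure being reproduced never states
how the tumor is picked from the over-segmented map; since the lesions of
interest are hyperintense, the brightest basin rule is used.  A bare
*T*ᵢ = 10 criterion cannot reject a featureless slice (parenchyma sits
near 30), so candidates must exceed a hyperintensity floor — slice median
plus the larger of 2.5 robust sigmas (1.4826·MAD) and an absolute 25
intensity units — and contain at least 16 pixels.  The absolute term
matters because after de-noising the residual sigma is tiny and a purely
relative floor would promote shallow fluctuations to lesions; 25 units is
well below any plausible lesion contrast on an 8-bit scale and well above
filtered noise.  All candidates within 90% of the brightest candidate's
mean are kept, so a lesion split by dams (or two separate lesions of
similar brightness) stays whole.  Dam pixels adjacent to a selected basin
are reclaimed when brighter than the midpoint between tumor and background
means, and a 3×3 binary closing seals one-pixel cracks.  When no basin
qualifies the result is an explicit "no tumor found", not an exception.
Whether *T*ᵢ applies before or after smoothing was unstated; it is applied
first, as the initialization step.

## SIFT

Per octave, s+3 Gaussian planes at σ₀·k^i (σ₀ = 1.6, k = 2^(1/s), s = 3)
are computed by **direct convolution of the octave base** — not Lowe's
incremental blurring — so each DoG plane is exactly the difference of two
discrete Gaussian responses; the next octave subsamples plane s by 2.  No
initial 2× upsampling.  Octaves shrink automatically (with a warning
record) when the coarsest plane would fall under 16×16.

Detection takes strict 26-neighbor extrema on interior voxels.
Localization solves x̂ = −H⁻¹∇D with central finite differences on the
3×3×3 neighborhood, re-centering up to 5 times when |x̂| components exceed
0.5; rejects: singular Hessian, out-of-bounds drift, non-convergence,
|D(x̂)| < 0.03 (intensities pre-scaled to [0, 1] by /255), and the edge
test tr²/det ≥ (r+1)²/r with r = 10 on the 2×2 spatial Hessian.

Orientation: 36-bin histogram of gradient directions, magnitude-weighted
with a Gaussian of σ_w = 1.5·(keypoint scale) over a radius-3σ_w window;
each circular-local-max bin within 80% of the peak spawns a keypoint, with
parabolic sub-bin interpolation.  Of the structurally fixed constants only
the 16×16 array, the 8-bin cells and the 36 orientation bins were
prescribed; the rest are the community-standard completions, all exposed
in `ScaleSpaceConfig`.  (The prescription's "8-bin histogram ... for the
keypoints orientation" is read as 8 bins per descriptor cell and 36 bins
for orientation assignment — the only internally consistent reading.)

Descriptor: a fixed 16×16 sample array (1-pixel spacing at octave
resolution) rotated to the keypoint orientation; gradients sampled
bilinearly, pooled into 4×4 cells × 8 orientation bins with trilinear
interpolation and Gaussian weighting (σ = 8 samples); normalized, clamped
at 0.2, renormalized.  Descriptors are exactly invariant to intensity
offsets and agree to ~1e-6 under 90° rotations.

Matching: per query, nearest and second-nearest database descriptors by
Euclidean distance; accept iff d₁ < ratio·d₂ (ratio 0.8).  ratio = 1
disables the test; a single database descriptor degenerates it and the
nearest neighbor is accepted.  Match counts on real data are
image-dependent and are reported, never asserted.

## Verification and staging

Pixel accuracy is the fraction of agreeing pixels; Dice is 2|P∩T|/(|P|+|T|)
(defined as 1 when both masks are empty).  Verification passes when the
SIFT match count between the mask-highlighted slice and the
truth-highlighted slice reaches `min_matches` (default 10) *and* Dice
reaches `dice_floor` (default 0.5); the thresholds are configurable because
matching is a qualitative confirmation — a smooth synthetic ellipse
legitimately carries fewer keypoints than a textured clinical lesion.

Tumor size defaults to *W* × 0.264 labelled mm² (`size_mode="linear"`),
the reporting convention this tool standardizes on even though a length
scale times a count is not dimensionally an area; `size_mode="physical"`
gives *W* × 0.264².  Staging: *W* ≥ 500 →
critical (boundary inclusive), else initial when *W* > 0, else no tumor.

## Synthetic phantoms

The generator emulates what the pipeline actually consumes: a bright,
roughly elliptical lesion (default level 200) on darker parenchyma
(default 30), the lesion's *image* edge softened by a σ = 1 Gaussian
(partial-volume effect) while the ground-truth mask stays the crisp
analytic ellipse, then additive Gaussian noise (σ = 8) and 2% impulse
pixels, all from a single seed.  It does **not** emulate anatomy (gyri,
ventricles, skull), bias fields, multi-modal contrast, heterogeneous or
irregular lesions, or partial annotations — so passing phantom tests shows
the numerics and the staging logic are correct under the stated intensity
model, not that the pipeline matches expert performance on clinical data.
Default problem sizes (256×256 slices, a few dozen flood levels, tens of
keypoints) keep a full end-to-end run around a second.

## Known limitations

* Single 2D grayscale slices only: no volumetric segmentation, no
  multi-modal fusion, no DICOM.
* The flooding is pure Python over precomputed neighbor lists — fine at
  256×256 (~0.5 s), not tuned for megapixel images.
* The brightest-basin rule assumes a hyperintense lesion; hypointense
  targets would need the selection rule swapped in config.
* The gradient-reference derivation is one defensible reading of an
  ambiguous prescription and is isolated in a single function
  (`derive_gradient_reference`) so it can be replaced.
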