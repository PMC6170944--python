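"""Immersion watershed segmentation of hyperintense lesions.

The intensity surface is read as terrain: a hole is punched at every
regional minimum and water rises through all holes at a uniform rate.
Where floods from two basins would merge, a one-pixel-thick dam (label 0)
is built; flooding ends with the image partitioned into catchment basins
separated by ridge lines.

The full segmentation stage mirrors the classic pipeline: exclude
sub-threshold intensities (T_i), morphologically smooth (grayscale opening
then closing with a flat 3x3 square), blur with a normalized 3x3 Gaussian,
take the Sobel gradient magnitude, derive a gradient reference level from
the intensity histogram's top bin, binarize the gradient at T_g times that
reference, flood the resulting surface, and finally pick the brightest
basin(s) as tumor.

Tie-breaking rules of the flood (these define the exact output and are
matched verbatim by the brute-force oracle used in the test suite):

* intensity levels are processed in ascending order;
* within a level, pixels adjacent to already-labelled territory are seeded
  into a FIFO queue in raster (row-major) order and grown breadth-first,
  neighbors enumerated in fixed raster order of offsets;
* a popped pixel joins the single distinct basin among its labelled
  neighbors, becomes a dam if there are two or more distinct basins, and
  also becomes a dam if it is reachable only through dam pixels;
* pixels of the level still unlabelled after the queue drains form new
  regional minima: one new basin per connected flat zone, numbered in
  raster order of each zone's first pixel.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .filtering import gaussian_filter_3x3
from .image import Image2D, BinaryMask

__all__ = [
    "WatershedConfig",
    "GradientImage",
    "LabelMap",
    "SegmentationResult",
    "morphological_smooth",
    "gradient_magnitude",
    "derive_gradient_reference",
    "threshold_gradient",
    "watershed_flood",
    "segment_tumor",
]

_OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_OFFSETS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


@dataclass
class WatershedConfig:
    """Tunable parameters of the segmentation stage.

    intensity_threshold (T_i, default 10): pixels below it are excluded as
    background before smoothing.  gradient_threshold (T_g, default 0.5) is a
    fraction of the histogram-derived gradient reference, not an absolute
    gradient.  The structuring element is always the flat 3x3 square.
    """

    intensity_threshold: float = 10.0
    gradient_threshold: float = 0.5
    connectivity: int = 8
    gaussian_sigma: float = 1.0
    gradient_operator: str = "sobel"  # or "central"
    histogram_bins: int = 256
    # tumor-basin selection (see segment_tumor)
    contrast_sigmas: float = 2.5
    min_contrast: float = 25.0
    selection_fraction: float = 0.9
    min_basin_size: int = 16
    include_boundary: bool = True
    close_mask: bool = True

    def validate(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("T_i must be non-negative")
        if not self.gradient_threshold > 0:
            raise ValueError("T_g must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.gradient_operator not in ("sobel", "central"):
            raise ValueError("gradient_operator must be 'sobel' or 'central'")


@dataclass
class GradientImage:
    """Signed gradient components and their magnitude sqrt(gx^2 + gy^2).

    gx differentiates along columns (x), gy along rows (y).
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray


@dataclass
class LabelMap:
    """Integer basin labels: 0 marks dam/ridge pixels, 1..K catchment basins."""

    labels: np.ndarray
    n_basins: int

    @property
    def dam_mask(self) -> np.ndarray:
        return self.labels == 0

    def basin_sizes(self) -> np.ndarray:
        """Pixel count of each basin, index k-1 for basin k."""
        return np.bincount(self.labels.ravel(), minlength=self.n_basins + 1)[1:]


@dataclass
class SegmentationResult:
    """Outcome of segment_tumor: never an exception for 'nothing found'."""

    found: bool
    tumor_mask: BinaryMask
    label_map: LabelMap
    tumor_basins: tuple[int, ...] = ()
    surface: np.ndarray | None = None
    gradient: GradientImage | None = None
    gradient_cut: float = 0.0


def morphological_smooth(image: Image2D, se: np.ndarray | None = None) -> Image2D:
    """Grayscale opening then closing with a flat 3x3 square.

    Opening (erode, then dilate) removes bright specks smaller than the
    structuring element; the subsequent closing (dilate, then erode) removes
    dark pits of the same size.
    """
    footprint = np.ones((3, 3), bool) if se is None else np.asarray(se, bool)
    opened = ndimage.grey_opening(image.pixels, footprint=footprint, mode="reflect")
    closed = ndimage.grey_closing(opened, footprint=footprint, mode="reflect")
    return image.with_pixels(closed)


def gradient_magnitude(image: Image2D, operator: str = "sobel") -> GradientImage:
    """Directional gradients and magnitude, reflective borders."""
    x = image.pixels
    if operator == "sobel":
        gx = ndimage.sobel(x, axis=1, mode="reflect")
        gy = ndimage.sobel(x, axis=0, mode="reflect")
    elif operator == "central":
        gy, gx = np.gradient(x)
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    return GradientImage(gx=gx, gy=gy, magnitude=np.hypot(gx, gy))


def derive_gradient_reference(
    smoothed: Image2D, bins: int = 256, operator: str = "sobel"
) -> float:
    """Gradient reference R from the intensity histogram's top bin.

    R is the maximum gradient magnitude attained by the pixels whose
    intensity falls in the highest-intensity histogram bin of ``smoothed``
    (the bin containing the global maximum, which is never empty).  The
    effective binarization cut is T_g * R.  A constant image gives R = 0,
    and scaling intensities by c scales R by c.
    """
    x = smoothed.pixels
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    members = x >= edges[-2]
    mag = gradient_magnitude(smoothed, operator).magnitude
    return float(mag[members].max())


def threshold_gradient(grad: GradientImage, cut: float) -> BinaryMask:
    """Binary gradient image G_dt: 1 where magnitude >= cut."""
    if cut < 0:
        raise ValueError("cut must be non-negative")
    return BinaryMask.from_bool(grad.magnitude >= cut)


def watershed_flood(surface: Image2D | np.ndarray, connectivity: int = 8) -> LabelMap:
    """Simulated immersion of the surface; see the module docstring for the
    exact flooding and tie-breaking rules.

    Returns basin labels 1..K (one basin per regional minimum, flat zones
    counted once) with dam pixels labelled 0.  Because only the ordering of
    intensities matters, the result is invariant under any strictly
    increasing transform of the surface.
    """
    x = surface.pixels if isinstance(surface, Image2D) else np.asarray(surface, np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("surface must be finite")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    offsets = _OFFSETS_8 if connectivity == 8 else _OFFSETS_4
    h, w = x.shape
    n = h * w
    flat = x.ravel()

    # neighbor index lists in fixed raster-offset order
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for p in range(n):
        r, c = divmod(p, w)
        lst = nbrs[p]
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                lst.append(rr * w + cc)

    UNVISITED, MASK = -2, -1
    label = np.full(n, UNVISITED, dtype=np.int64)
    order = np.argsort(flat, kind="stable")  # raster order within equal levels
    level_starts = np.flatnonzero(np.r_[True, np.diff(flat[order]) > 0])
    level_bounds = np.r_[level_starts, n]

    k = 0
    for li in range(len(level_starts)):
        pix = order[level_bounds[li] : level_bounds[li + 1]]
        pix = np.sort(pix)  # raster order
        label[pix] = MASK

        queued = np.zeros(n, dtype=bool)
        fifo: deque[int] = deque()
        for p in pix:
            for q in nbrs[p]:
                if label[q] >= 0:
                    fifo.append(p)
                    queued[p] = True
                    break

        while fifo:
            p = fifo.popleft()
            basins = set()
            for q in nbrs[p]:
                lq = label[q]
                if lq > 0:
                    basins.add(lq)
            if len(basins) == 1:
                label[p] = basins.pop()
            else:
                # >= 2 basins meet here, or only dams are reachable
                label[p] = 0
            for q in nbrs[p]:
                if label[q] == MASK and not queued[q]:
                    queued[q] = True
                    fifo.append(q)

        # untouched plateau pixels: new regional minima, one basin per flat zone
        for p in pix:
            if label[p] != MASK:
                continue
            k += 1
            label[p] = k
            grow = deque([p])
            while grow:
                u = grow.popleft()
                for q in nbrs[u]:
                    if label[q] == MASK:
                        label[q] = k
                        grow.append(q)

    return LabelMap(labels=label.reshape(h, w), n_basins=k)


def _basin_means(labels: np.ndarray, k: int, intensities: np.ndarray) -> np.ndarray:
    """Mean intensity of each basin (index k-1 for basin k)."""
    sums = np.bincount(labels.ravel(), weights=intensities.ravel(), minlength=k + 1)
    counts = np.bincount(labels.ravel(), minlength=k + 1)
    with np.errstate(invalid="ignore"):
        means = sums / np.maximum(counts, 1)
    return means[1:]


def segment_tumor(image: Image2D, cfg: WatershedConfig | None = None) -> SegmentationResult:
    """Full watershed segmentation of a (pre-filtered) slice.

    The flooded surface is the Sobel gradient magnitude of the smoothed
    image with sub-threshold gradients flattened to zero, so homogeneous
    tissue collapses into large flat minima and over-segmentation is kept
    in check.  Tumor basins are then selected by brightness: candidates must
    have mean intensity above both T_i and a hyperintensity floor (slice
    median plus the larger of contrast_sigmas robust-sigma and min_contrast
    intensity units) and at least min_basin_size pixels; every candidate within selection_fraction of the
    brightest candidate's mean is kept (a lesion split by dams stays whole).
    Dam pixels adjacent to a selected basin are reclaimed when brighter than
    the midpoint between tumor and background means, and the mask is sealed
    with a 3x3 binary closing.  If no basin qualifies the result reports
    "no tumor found" rather than raising.
    """
    cfg = cfg or WatershedConfig()
    cfg.validate()
    x = image.pixels

    work = np.where(x >= cfg.intensity_threshold, x, 0.0)  # T_i exclusion
    sm = morphological_smooth(image.with_pixels(work))
    sm = gaussian_filter_3x3(sm, cfg.gaussian_sigma)
    grad = gradient_magnitude(sm, cfg.gradient_operator)
    ref = derive_gradient_reference(sm, cfg.histogram_bins, cfg.gradient_operator)
    cut = cfg.gradient_threshold * ref
    gdt = threshold_gradient(grad, cut)
    surface = np.where(gdt.as_bool(), grad.magnitude, 0.0)
    label_map = watershed_flood(surface, cfg.connectivity)

    labels = label_map.labels
    k = label_map.n_basins
    means = _basin_means(labels, k, x)
    sizes = label_map.basin_sizes()
    # Hyperintensity floor: a tumor basin must stand clear of the bulk
    # tissue level.  Robust location/scale (median, 1.4826*MAD) so the
    # lesion itself does not drag the floor up, with an absolute minimum
    # contrast so that a de-noised but featureless slice (tiny residual
    # sigma) cannot promote shallow fluctuations to lesions.
    med = float(np.median(x))
    sigma_rob = 1.4826 * float(np.median(np.abs(x - med)))
    floor = max(
        cfg.intensity_threshold,
        med + max(cfg.contrast_sigmas * sigma_rob, cfg.min_contrast),
    )
    candidate = (means >= floor) & (sizes >= cfg.min_basin_size)
    empty_mask = BinaryMask.from_bool(np.zeros_like(x, dtype=bool))
    if not candidate.any():
        return SegmentationResult(
            found=False, tumor_mask=empty_mask, label_map=label_map,
            surface=surface, gradient=grad, gradient_cut=cut,
        )

    best = float(means[candidate].max())
    selected = np.flatnonzero(candidate & (means >= cfg.selection_fraction * best)) + 1
    sel_set = np.isin(labels, selected)
    mask = sel_set & (x >= cfg.intensity_threshold)

    if cfg.include_boundary:
        bg = ~sel_set
        bg_mean = float(x[bg].mean()) if bg.any() else 0.0
        midpoint = 0.5 * (best + bg_mean)
        near_sel = ndimage.binary_dilation(sel_set, structure=np.ones((3, 3), bool))
        mask |= (labels == 0) & near_sel & (x >= midpoint)
    if cfg.close_mask:
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), bool))

    return SegmentationResult(
        found=True,
        tumor_mask=BinaryMask.from_bool(mask),
        label_map=label_map,
        tumor_basins=tuple(int(s) for s in selected),
        surface=surface,
        gradient=grad,
        gradient_cut=cut,
    )
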