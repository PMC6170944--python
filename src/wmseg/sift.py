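"""Scale-invariant feature transform (SIFT), implemented from scratch.

The pipeline's second verification step matches keypoints between the
segmented slice and the ground-truth slice.  Stages:

1. scale space: per octave, Gaussian planes L(x, y, sigma) at geometrically
   spaced sigmas and their adjacent differences D = L(kq) - L(q) (DoG);
2. detection: 26-neighbor extrema of D across space and scale;
3. localization: quadratic (Taylor) refinement of each extremum with
   low-contrast and edge-response rejection;
4. orientation: 36-bin gradient-orientation histogram around the keypoint,
   one keypoint emitted per dominant peak;
5. descriptor: 16x16 gradient samples rotated into the keypoint frame,
   pooled into 4x4 cells of 8-bin orientation histograms -> 128-vector,
   normalized, clamped at 0.2 and renormalized;
6. matching: nearest-neighbor in descriptor space with Lowe's ratio test.

Conventions: angles are degrees in [0, 360), measured from the +col axis
toward the +row axis; subpixel offsets are (row, col, scale) with each
component in (-1, 1) after convergence.  Gaussian planes are computed by
direct convolution of the octave base with G(sigma0 * k^i), so each DoG
plane is exactly the difference of two discrete Gaussian responses.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .image import Image2D

__all__ = [
    "ScaleSpaceConfig",
    "Octave",
    "DoGPyramid",
    "Keypoint",
    "MatchSet",
    "build_scale_space",
    "detect_extrema",
    "localize_keypoint",
    "assign_orientation",
    "compute_descriptor",
    "match_keypoints",
    "detect_and_describe",
    "keypoints_to_csv",
    "matches_to_csv",
]


@dataclass
class ScaleSpaceConfig:
    """Pyramid and rejection-threshold constants.

    Only the 16x16 descriptor array, its 8-bin cell histograms and the
    36-bin orientation histogram are structurally fixed; the remaining
    constants are the community-standard completions and sit here so they
    can be tuned.  ``contrast_threshold`` assumes intensities on [0, 1].
    """

    n_octaves: int = 4
    scales_per_octave: int = 3
    base_sigma: float = 1.6
    contrast_threshold: float = 0.03
    edge_ratio: float = 10.0
    ratio: float = 0.8  # Lowe match ratio
    orientation_peak_fraction: float = 0.8
    descriptor_clamp: float = 0.2

    @property
    def k(self) -> float:
        return 2.0 ** (1.0 / self.scales_per_octave)

    def validate(self) -> None:
        if self.n_octaves < 1 or self.scales_per_octave < 1:
            raise ValueError("octave and scale counts must be positive")
        if self.base_sigma <= 0 or self.contrast_threshold <= 0 or self.edge_ratio <= 0:
            raise ValueError("sigma and thresholds must be positive")


@dataclass
class Octave:
    gauss: np.ndarray   # (s+3, H, W)
    dog: np.ndarray     # (s+2, H, W), dog[i] = gauss[i+1] - gauss[i]
    sigmas: np.ndarray  # per-gauss-plane sigma, octave pixel units


@dataclass
class DoGPyramid:
    octaves: list[Octave]
    cfg: ScaleSpaceConfig
    warnings: list[str] = field(default_factory=list)


@dataclass
class Keypoint:
    octave: int
    scale: int          # DoG plane index within the octave
    row: int
    col: int
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (drow, dcol, dscale)
    value: float = 0.0  # refined |DoG| response D(x-hat)
    sigma: float = 0.0  # scale in octave pixel units
    orientation: float = 0.0  # degrees in [0, 360)

    @property
    def row_img(self) -> float:
        """Row at input-image resolution."""
        return (self.row + self.offset[0]) * (2 ** self.octave)

    @property
    def col_img(self) -> float:
        return (self.col + self.offset[1]) * (2 ** self.octave)


@dataclass
class MatchSet:
    pairs: list[tuple[int, int, float]]

    @property
    def count(self) -> int:
        return len(self.pairs)


# ----------------------------------------------------------------- pyramid


def build_scale_space(image: Image2D | np.ndarray, cfg: ScaleSpaceConfig | None = None) -> DoGPyramid:
    """Gaussian + DoG pyramid; octave count shrinks (with a warning record)
    when the image cannot support 16x16 planes at the coarsest octave."""
    cfg = cfg or ScaleSpaceConfig()
    cfg.validate()
    base = image.pixels if isinstance(image, Image2D) else np.asarray(image, np.float64)
    base = base.astype(np.float64)

    warnings: list[str] = []
    n_oct = cfg.n_octaves
    while n_oct > 1 and min(base.shape) // (2 ** (n_oct - 1)) < 16:
        n_oct -= 1
    if n_oct < cfg.n_octaves:
        warnings.append(
            f"octave count reduced from {cfg.n_octaves} to {n_oct} "
            f"for image of shape {base.shape}"
        )

    s = cfg.scales_per_octave
    sigmas = cfg.base_sigma * cfg.k ** np.arange(s + 3)
    octaves: list[Octave] = []
    for _ in range(n_oct):
        gauss = np.stack(
            [ndimage.gaussian_filter(base, sig, mode="reflect") for sig in sigmas]
        )
        dog = gauss[1:] - gauss[:-1]
        octaves.append(Octave(gauss=gauss, dog=dog, sigmas=sigmas.copy()))
        base = gauss[s][::2, ::2]
    return DoGPyramid(octaves=octaves, cfg=cfg, warnings=warnings)


# ------------------------------------------------------------- detection


def detect_extrema(pyr: DoGPyramid) -> list[Keypoint]:
    """Candidates strictly greater or strictly smaller than all 26
    space-scale neighbors; borders and the first/last DoG planes excluded."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    out: list[Keypoint] = []
    for oi, octv in enumerate(pyr.octaves):
        d = octv.dog
        if d.shape[0] < 3:
            continue
        mx = ndimage.maximum_filter(d, footprint=footprint, mode="nearest")
        mn = ndimage.minimum_filter(d, footprint=footprint, mode="nearest")
        cand = (d > mx) | (d < mn)
        cand[0] = cand[-1] = False
        cand[:, 0, :] = cand[:, -1, :] = False
        cand[:, :, 0] = cand[:, :, -1] = False
        for si, r, c in np.argwhere(cand):
            out.append(Keypoint(octave=oi, scale=int(si), row=int(r), col=int(c)))
    return out


# ---------------------------------------------------------- localization


def _grad_hess(d: np.ndarray, s: int, r: int, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient and Hessian of D in (row, col, scale) order."""
    g = np.array([
        0.5 * (d[s, r + 1, c] - d[s, r - 1, c]),
        0.5 * (d[s, r, c + 1] - d[s, r, c - 1]),
        0.5 * (d[s + 1, r, c] - d[s - 1, r, c]),
    ])
    hrr = d[s, r + 1, c] - 2 * d[s, r, c] + d[s, r - 1, c]
    hcc = d[s, r, c + 1] - 2 * d[s, r, c] + d[s, r, c - 1]
    hss = d[s + 1, r, c] - 2 * d[s, r, c] + d[s - 1, r, c]
    hrc = 0.25 * (d[s, r + 1, c + 1] - d[s, r + 1, c - 1] - d[s, r - 1, c + 1] + d[s, r - 1, c - 1])
    hrs = 0.25 * (d[s + 1, r + 1, c] - d[s + 1, r - 1, c] - d[s - 1, r + 1, c] + d[s - 1, r - 1, c])
    hcs = 0.25 * (d[s + 1, r, c + 1] - d[s + 1, r, c - 1] - d[s - 1, r, c + 1] + d[s - 1, r, c - 1])
    h = np.array([[hrr, hrc, hrs], [hrc, hcc, hcs], [hrs, hcs, hss]])
    return g, h


def localize_keypoint(
    pyr: DoGPyramid, candidate: Keypoint, cfg: ScaleSpaceConfig | None = None,
    max_iter: int = 5,
) -> tuple[Keypoint | None, str | None]:
    """Taylor refinement x-hat = -(d2D/dx2)^-1 (dD/dx) with up to ``max_iter``
    re-centerings when an offset component exceeds 0.5.

    Returns ``(keypoint, None)`` on success or ``(None, reason)`` with reason
    in {"singular", "out_of_bounds", "unstable", "low_contrast", "edge"}.
    """
    cfg = cfg or pyr.cfg
    d = pyr.octaves[candidate.octave].dog
    ns, h, w = d.shape
    s, r, c = candidate.scale, candidate.row, candidate.col

    for _ in range(max_iter):
        g, hess = _grad_hess(d, s, r, c)
        try:
            xhat = np.linalg.solve(hess, -g)
        except np.linalg.LinAlgError:
            return None, "singular"
        if np.all(np.abs(xhat) <= 0.5):
            break
        r += int(round(np.clip(xhat[0], -1, 1)))
        c += int(round(np.clip(xhat[1], -1, 1)))
        s += int(round(np.clip(xhat[2], -1, 1)))
        if not (1 <= s <= ns - 2 and 1 <= r <= h - 2 and 1 <= c <= w - 2):
            return None, "out_of_bounds"
    else:
        return None, "unstable"

    value = d[s, r, c] + 0.5 * float(g @ xhat)
    if abs(value) < cfg.contrast_threshold:
        return None, "low_contrast"

    # edge rejection on the 2x2 spatial Hessian: principal-curvature ratio
    tr = hess[0, 0] + hess[1, 1]
    det = hess[0, 0] * hess[1, 1] - hess[0, 1] ** 2
    rr = cfg.edge_ratio
    if det <= 0 or tr * tr * rr >= det * (rr + 1) ** 2:
        return None, "edge"

    sigma = cfg.base_sigma * cfg.k ** (s + float(xhat[2]))
    kp = Keypoint(
        octave=candidate.octave, scale=s, row=r, col=c,
        offset=(float(xhat[0]), float(xhat[1]), float(xhat[2])),
        value=float(value), sigma=float(sigma),
    )
    return kp, None


# ----------------------------------------------------------- orientation


def _plane_gradients(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g_r, g_c = np.gradient(L)
    return g_r, g_c


def assign_orientation(L: np.ndarray, kp: Keypoint) -> list[Keypoint]:
    """One keypoint per dominant orientation of the local gradient field.

    36-bin histogram of gradient directions in a Gaussian-weighted window
    (sigma_w = 1.5 x keypoint scale, radius 3 sigma_w, clipped at borders);
    every circular-local-max bin within 80% of the peak spawns a keypoint,
    with parabolic interpolation for sub-bin angles.  An all-zero gradient
    window drops the keypoint (empty list).
    """
    sigma_w = 1.5 * max(kp.sigma, 0.5)
    radius = max(1, int(round(3.0 * sigma_w)))
    h, w = L.shape
    r0 = int(round(kp.row + kp.offset[0]))
    c0 = int(round(kp.col + kp.offset[1]))
    r0 = min(max(r0, 0), h - 1)
    c0 = min(max(c0, 0), w - 1)
    rlo, rhi = max(0, r0 - radius), min(h, r0 + radius + 1)
    clo, chi = max(0, c0 - radius), min(w, c0 + radius + 1)

    g_r, g_c = _plane_gradients(L)
    gr = g_r[rlo:rhi, clo:chi]
    gc = g_c[rlo:rhi, clo:chi]
    mag = np.hypot(gr, gc)
    if not np.any(mag > 0):
        return []
    ang = np.degrees(np.arctan2(gr, gc)) % 360.0

    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    wgt = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_w**2))
    bins = (ang / 10.0).astype(int) % 36
    hist = np.bincount(bins.ravel(), weights=(mag * wgt).ravel(), minlength=36)

    peak = hist.max()
    if peak <= 0:
        return []
    out: list[Keypoint] = []
    for b in range(36):
        left, right = hist[(b - 1) % 36], hist[(b + 1) % 36]
        if hist[b] < 0.8 * peak or hist[b] < left or hist[b] < right:
            continue
        denom = left - 2.0 * hist[b] + right
        shift = 0.0 if denom == 0 else 0.5 * (left - right) / denom
        theta = ((b + 0.5 + shift) * 10.0) % 360.0
        out.append(Keypoint(
            octave=kp.octave, scale=kp.scale, row=kp.row, col=kp.col,
            offset=kp.offset, value=kp.value, sigma=kp.sigma,
            orientation=float(theta),
        ))
    return out


# ------------------------------------------------------------ descriptor


def _bilinear(plane: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    h, w = plane.shape
    r = np.clip(r, 0.0, h - 1.0)
    c = np.clip(c, 0.0, w - 1.0)
    r0 = np.clip(np.floor(r).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(c).astype(int), 0, w - 2)
    fr = r - r0
    fc = c - c0
    return (
        plane[r0, c0] * (1 - fr) * (1 - fc)
        + plane[r0 + 1, c0] * fr * (1 - fc)
        + plane[r0, c0 + 1] * (1 - fr) * fc
        + plane[r0 + 1, c0 + 1] * fr * fc
    )


def compute_descriptor(L: np.ndarray, kp: Keypoint, clamp: float = 0.2) -> np.ndarray:
    """128-vector from a 16x16 gradient sample array rotated to the keypoint
    orientation: 4x4 spatial cells x 8 orientation bins with trilinear
    interpolation and Gaussian weighting (sigma = 8 samples), normalized to
    unit length with a clamp-and-renormalize pass.  Samples falling outside
    the plane are clipped to border values."""
    theta = math.radians(kp.orientation)
    ct, st = math.cos(theta), math.sin(theta)
    r0 = kp.row + kp.offset[0]
    c0 = kp.col + kp.offset[1]

    offs = np.arange(16) - 7.5
    p, q = np.meshgrid(offs, offs, indexing="ij")  # p: cross-axis, q: along orientation
    dr = q * st + p * ct
    dc = q * ct - p * st

    g_r, g_c = _plane_gradients(L)
    sr = _bilinear(g_r, r0 + dr, c0 + dc)
    sc = _bilinear(g_c, r0 + dr, c0 + dc)
    mag = np.hypot(sr, sc)
    ang = (np.degrees(np.arctan2(sr, sc)) - kp.orientation) % 360.0

    wgt = np.exp(-(p**2 + q**2) / (2.0 * 8.0**2))
    contrib = mag * wgt
    cp = p / 4.0 + 1.5
    cq = q / 4.0 + 1.5
    ob = ang / 45.0

    hist = np.zeros((4, 4, 8))
    i0 = np.floor(cp).astype(int)
    j0 = np.floor(cq).astype(int)
    o0 = np.floor(ob).astype(int)
    fi, fj, fo = cp - i0, cq - j0, ob - o0
    for di in (0, 1):
        wi = np.where(di == 0, 1 - fi, fi)
        ii = i0 + di
        for dj in (0, 1):
            wj = np.where(dj == 0, 1 - fj, fj)
            jj = j0 + dj
            for do in (0, 1):
                wo = np.where(do == 0, 1 - fo, fo)
                oo = (o0 + do) % 8
                valid = (ii >= 0) & (ii < 4) & (jj >= 0) & (jj < 4)
                np.add.at(
                    hist,
                    (ii[valid], jj[valid], oo[valid]),
                    (contrib * wi * wj * wo)[valid],
                )

    vec = hist.ravel()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
        vec = np.minimum(vec, clamp)
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = vec / norm
    return vec


# -------------------------------------------------------------- matching


def match_keypoints(
    a: np.ndarray, b: np.ndarray, ratio: float = 0.8
) -> MatchSet:
    """Lowe ratio-test matching: each A-descriptor is paired with its nearest
    B-descriptor iff nearest / second-nearest distance < ratio.  With a
    single B-descriptor the ratio test degenerates and the nearest neighbor
    is accepted."""
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    a = np.atleast_2d(np.asarray(a, np.float64))
    b = np.atleast_2d(np.asarray(b, np.float64))
    if a.size == 0 or b.size == 0:
        return MatchSet(pairs=[])
    dist = cdist(a, b)
    pairs: list[tuple[int, int, float]] = []
    for i in range(dist.shape[0]):
        order = np.argsort(dist[i], kind="stable")
        j = int(order[0])
        d1 = float(dist[i, j])
        # ratio == 1 disables the test entirely; a single B-descriptor
        # degenerates it, so the nearest neighbor is accepted
        if b.shape[0] == 1 or ratio >= 1.0:
            pairs.append((i, j, d1))
            continue
        d2 = float(dist[i, order[1]])
        if d1 < ratio * d2:
            pairs.append((i, j, d1))
    return MatchSet(pairs=pairs)


# ------------------------------------------------------------ high level


def detect_and_describe(
    image: Image2D, cfg: ScaleSpaceConfig | None = None, *, normalize: bool = True
) -> tuple[list[Keypoint], np.ndarray]:
    """Full SIFT front end: pyramid -> extrema -> localization -> orientation
    -> descriptors.  ``normalize`` divides intensities by 255 so the default
    contrast threshold (0.03 on [0, 1]) applies to 8-bit-scaled slices."""
    cfg = cfg or ScaleSpaceConfig()
    arr = image.pixels / 255.0 if normalize else image.pixels
    pyr = build_scale_space(arr, cfg)
    keypoints: list[Keypoint] = []
    descriptors: list[np.ndarray] = []
    for cand in detect_extrema(pyr):
        kp, _reason = localize_keypoint(pyr, cand, cfg)
        if kp is None:
            continue
        plane_idx = int(np.clip(round(kp.scale + kp.offset[2]), 0, len(pyr.octaves[kp.octave].gauss) - 1))
        L = pyr.octaves[kp.octave].gauss[plane_idx]
        for oriented in assign_orientation(L, kp):
            vec = compute_descriptor(L, oriented, cfg.descriptor_clamp)
            if np.any(vec):
                keypoints.append(oriented)
                descriptors.append(vec)
    desc = np.array(descriptors) if descriptors else np.empty((0, 128))
    return keypoints, desc


def keypoints_to_csv(keypoints: list[Keypoint], descriptors: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["octave", "scale", "row", "col", "theta_deg"] + [f"d{i}" for i in range(128)])
        for kp, vec in zip(keypoints, descriptors):
            w.writerow(
                [kp.octave, kp.scale, f"{kp.row_img:.3f}", f"{kp.col_img:.3f}",
                 f"{kp.orientation:.3f}"] + [f"{v:.6f}" for v in vec]
            )


def matches_to_csv(matches: MatchSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index_a", "index_b", "distance"])
        for i, j, d in matches.pairs:
            w.writerow([i, j, f"{d:.6f}"])
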