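"""Synthetic brain-phantom generator.

Real glioma slices (e.g. BRATS FLAIR/T1c) show a hyperintense, roughly
elliptical lesion on darker parenchyma, degraded by thermal (Gaussian) noise
and occasional impulse (salt-and-pepper) pixels.  The phantom emulates
exactly those features so every pipeline stage is testable without a dataset
download: a flat background, a brighter ellipse whose *image* edge is
softened by a small Gaussian blur (tissue partial-volume effect) while the
*ground-truth mask* stays the crisp analytic ellipse, then seeded noise.

What the phantom does not emulate: anatomy (gyri, ventricles, skull), bias
fields, multi-modal contrast, and irregular or heterogeneous tumors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Image2D, BinaryMask, DEFAULT_PIXEL_SIZE_MM

__all__ = ["PhantomSpec", "generate_phantom", "axes_for_pixel_count", "ellipse_mask"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic slice.

    Intensity levels are on the 8-bit [0, 255] scale.  Defaults approximate a
    256x256 FLAIR-like slice: parenchyma near 30, lesion near 200 (strongly
    hyperintense), Gaussian noise sigma 8 and 2% impulse pixels.
    """

    shape: tuple[int, int] = (256, 256)
    background_level: float = 30.0
    tumor_center: tuple[float, float] = (128.0, 128.0)
    tumor_axes: tuple[float, float] = (11.0, 9.0)  # semi-axes (rows, cols), px
    tumor_level: float = 200.0
    gaussian_sigma: float = 8.0
    impulse_fraction: float = 0.02
    boundary_sigma: float = 1.0  # blur of the image edge only, never the mask
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        r0, c0 = self.tumor_center
        a, b = self.tumor_axes
        if a <= 0 or b <= 0:
            raise ValueError("tumor semi-axes must be positive")
        if not (r0 - a >= 0 and r0 + a <= h - 1 and c0 - b >= 0 and c0 + b <= w - 1):
            raise ValueError("tumor ellipse must lie fully inside the image")
        if not self.tumor_level > self.background_level:
            raise ValueError("tumor_level must exceed background_level (lesions are hyperintense)")
        if not 0 <= self.impulse_fraction <= 0.5:
            raise ValueError("impulse_fraction must be in [0, 0.5]")
        if self.gaussian_sigma < 0 or self.boundary_sigma < 0:
            raise ValueError("noise/blur sigmas must be non-negative")


def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 axes: tuple[float, float]) -> np.ndarray:
    """Boolean lattice membership ((r-r0)/a)^2 + ((c-c0)/b)^2 <= 1."""
    h, w = shape
    rr, cc = np.ogrid[0:h, 0:w]
    r0, c0 = center
    a, b = axes
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def axes_for_pixel_count(n_pixels: float, aspect: float = 1.2) -> tuple[float, float]:
    """Semi-axes (a, b) with a/b = aspect whose continuous area pi*a*b = n_pixels.

    The lattice pixel count of the resulting ellipse tracks the continuous
    area to within a few pixels at the sizes used here.
    """
    if n_pixels <= 0 or aspect <= 0:
        raise ValueError("n_pixels and aspect must be positive")
    b = math.sqrt(n_pixels / (math.pi * aspect))
    return aspect * b, b


def generate_phantom(spec: PhantomSpec) -> tuple[Image2D, BinaryMask]:
    """Generate one seeded phantom slice and its crisp ground-truth mask.

    The same spec (including seed) always yields bit-identical output, and
    the mask never depends on the noise parameters.
    """
    spec.validate()
    member = ellipse_mask(spec.shape, spec.tumor_center, spec.tumor_axes)

    clean = np.full(spec.shape, spec.background_level, dtype=np.float64)
    clean[member] = spec.tumor_level
    if spec.boundary_sigma > 0:
        clean = ndimage.gaussian_filter(clean, spec.boundary_sigma, mode="nearest")

    rng = np.random.default_rng(spec.seed)
    noisy = clean
    if spec.gaussian_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sigma, spec.shape)
    if spec.impulse_fraction > 0:
        n = int(round(spec.impulse_fraction * noisy.size))
        if n > 0:
            flat = rng.choice(noisy.size, size=n, replace=False)
            salt = rng.random(n) < 0.5
            noisy = noisy.copy().ravel()
            noisy[flat] = np.where(salt, 255.0, 0.0)
            noisy = noisy.reshape(spec.shape)
    noisy = np.clip(noisy, 0.0, 255.0)

    return (
        Image2D(noisy, spec.pixel_size_mm),
        BinaryMask.from_bool(member),
    )
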