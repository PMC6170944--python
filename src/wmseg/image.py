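"""Image containers and file I/O for 2D grayscale MR slices and binary masks.

Conventions used throughout the package:

* pixel grids are indexed ``(row, col)``, 0-based, row 0 at the top;
* intensities are stored as float64 internally (filters and gradients need
  sub-integer precision) and clamped to [0, 255] only when written to disk;
* colour inputs are collapsed to luminance with fixed ITU-R BT.601 weights
  (0.299 R + 0.587 G + 0.114 B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "Image2D",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

#: default physical edge length of one pixel, in mm
DEFAULT_PIXEL_SIZE_MM = 0.264

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class Image2D:
    """A 2D grayscale raster with a physical pixel scale.

    The intensity surface I(row, col) is what the watershed stage treats as
    terrain height.  Grids must be at least 3x3 so every 3x3 kernel in the
    pipeline fits after padding.
    """

    pixels: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image2D requires a 2D grid, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise ValueError(f"Image2D must be at least 3x3, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("Image2D intensities must be non-negative")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """A new image with the same pixel scale but different intensities."""
        return Image2D(np.asarray(pixels, dtype=np.float64), self.pixel_size_mm)


@dataclass
class BinaryMask:
    """Per-pixel tumor (1, white) / background (0, black) labelling."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"BinaryMask requires a 2D grid, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"BinaryMask values must be in {{0, 1}}, got {uniq}")
        self.pixels = arr.astype(np.uint8)

    @classmethod
    def from_bool(cls, arr: np.ndarray) -> "BinaryMask":
        return cls(np.asarray(arr, dtype=bool).astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def white_count(self) -> int:
        return int(self.pixels.sum())

    def as_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    arr = np.squeeze(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].astype(np.float64) @ _LUMA_WEIGHTS
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as a 2D grayscale image")
    return arr.astype(np.float64)


def read_image(
    path: str | Path,
    *,
    nifti_axis: int | None = None,
    nifti_index: int | None = None,
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM,
) -> Image2D:
    """Read a PNG/TIFF image, or one slice of a NIfTI volume, as an :class:`Image2D`.

    Intensities are returned exactly as stored (no rescaling).  NIfTI input
    requires ``nifti_axis`` and ``nifti_index`` selecting the slab to extract.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        vol = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        if vol.ndim == 2:
            arr = vol
        else:
            if nifti_axis is None or nifti_index is None:
                raise ValueError("NIfTI volumes need nifti_axis and nifti_index")
            if not (0 <= nifti_index < vol.shape[nifti_axis]):
                raise IndexError(
                    f"slice {nifti_index} out of range for axis {nifti_axis} "
                    f"with size {vol.shape[nifti_axis]}"
                )
            arr = np.take(vol, nifti_index, axis=nifti_axis)
            if arr.ndim != 2:
                raise ValueError("NIfTI slice extraction did not yield a 2D slab")
    else:
        arr = _to_gray(iio.imread(path))
    return Image2D(np.asarray(arr, dtype=np.float64), pixel_size_mm)


def write_image(image: Image2D, path: str | Path) -> None:
    """Write an image as 8-bit PNG/TIFF, clamping intensities to [0, 255]."""
    out = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit PNG with {0, 1} mapped to {0, 255}."""
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask written by :func:`write_mask` back to a {0, 1} grid."""
    arr = _to_gray(iio.imread(Path(path)))
    return BinaryMask.from_bool(arr > 127)
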