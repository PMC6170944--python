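"""Second verification step and clinical status report.

The watershed mask is checked against the ground truth two ways: pixel
overlap (accuracy and Dice) and SIFT keypoint matching between the
mask-highlighted slice and the ground-truth slice.  The white-pixel count W
is converted to a tumor size with the fixed pixel scale, and the staging
rule is applied: W >= 500 white pixels is "critical", any smaller positive
count "initial", zero "no tumor".

The default size formula W x 0.264 (labelled mm^2) is the reporting
convention this tool standardizes on even though a length scale times a
count is not dimensionally an area; the physically consistent
W x 0.264^2 is available as size_mode="physical".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .image import Image2D, BinaryMask, DEFAULT_PIXEL_SIZE_MM
from .sift import ScaleSpaceConfig, detect_and_describe, match_keypoints

__all__ = [
    "TumorReport",
    "count_white_pixels",
    "tumor_size",
    "classify_status",
    "pixel_metrics",
    "verify",
]

CRITICAL_THRESHOLD_DEFAULT = 500


@dataclass
class TumorReport:
    white_pixels: int
    tumor_size: float
    size_unit: str
    status: str  # "initial" | "critical" | "no tumor"
    match_count: int
    pixel_accuracy: float
    dice: float
    passed: bool

    def to_text(self) -> str:
        return (
            f"white pixels (W):  {self.white_pixels}\n"
            f"tumor size:        {self.tumor_size:.3f} {self.size_unit}\n"
            f"status:            {self.status}\n"
            f"SIFT matches:      {self.match_count}\n"
            f"pixel accuracy:    {self.pixel_accuracy:.4f}\n"
            f"Dice coefficient:  {self.dice:.4f}\n"
            f"verification:      {'PASS' if self.passed else 'FAIL'}\n"
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["white_pixels", "tumor_size", "size_unit", "status",
                        "match_count", "pixel_accuracy", "dice", "passed"])
            w.writerow([self.white_pixels, f"{self.tumor_size:.6f}", self.size_unit,
                        self.status, self.match_count, f"{self.pixel_accuracy:.6f}",
                        f"{self.dice:.6f}", int(self.passed)])


def count_white_pixels(mask: BinaryMask) -> int:
    """Exact count of 1-valued (white) pixels over the whole grid."""
    return mask.white_count


def tumor_size(
    w: int, pixel_scale: float = DEFAULT_PIXEL_SIZE_MM, mode: str = "linear"
) -> float:
    """Tumor size from the white-pixel count.

    mode="linear": W x pixel_scale (default reporting convention, mm^2 label);
    mode="physical": W x pixel_scale^2 (dimensionally consistent area).
    """
    if w < 0:
        raise ValueError("white-pixel count must be non-negative")
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    if mode == "linear":
        return w * pixel_scale
    if mode == "physical":
        return w * pixel_scale * pixel_scale
    raise ValueError(f"unknown size mode {mode!r}")


def classify_status(w: int, critical_threshold: int = CRITICAL_THRESHOLD_DEFAULT) -> str:
    """Staging rule: >= critical_threshold white pixels -> "critical";
    any positive count below it -> "initial"; zero -> "no tumor"."""
    if w < 0:
        raise ValueError("white-pixel count must be non-negative")
    if w >= critical_threshold:
        return "critical"
    if w > 0:
        return "initial"
    return "no tumor"


def pixel_metrics(predicted: BinaryMask, truth: BinaryMask) -> tuple[float, float]:
    """(pixel accuracy, Dice).  Dice of two empty masks is defined as 1."""
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth masks must share a shape")
    p = predicted.as_bool()
    t = truth.as_bool()
    accuracy = float((p == t).mean())
    denom = int(p.sum()) + int(t.sum())
    dice = 1.0 if denom == 0 else 2.0 * int((p & t).sum()) / denom
    return accuracy, dice


def verify(
    image: Image2D,
    predicted: BinaryMask,
    truth_image: Image2D,
    truth_mask: BinaryMask,
    sift_cfg: ScaleSpaceConfig | None = None,
    ratio: float = 0.8,
    *,
    min_matches: int = 10,
    dice_floor: float = 0.5,
    pixel_scale: float = DEFAULT_PIXEL_SIZE_MM,
    size_mode: str = "linear",
    critical_threshold: int = CRITICAL_THRESHOLD_DEFAULT,
    run_sift: bool = True,
) -> TumorReport:
    """Full verification: SIFT matching of the mask-highlighted slice against
    the ground-truth-highlighted slice, pixel metrics, white-pixel count,
    size and staging.  Verification passes when match_count >= min_matches
    AND dice >= dice_floor.  ``run_sift=False`` skips matching (match_count
    -1, matching criterion waived) for pixel-metrics-only use.
    """
    if predicted.shape != image.shape or truth_mask.shape != truth_image.shape:
        raise ValueError("masks must match their images in shape")
    if predicted.shape != truth_mask.shape:
        raise ValueError("predicted and truth masks must share a shape")

    accuracy, dice = pixel_metrics(predicted, truth_mask)
    w = count_white_pixels(predicted)
    size = tumor_size(w, pixel_scale, size_mode)
    status = classify_status(w, critical_threshold)

    if run_sift:
        cfg = sift_cfg or ScaleSpaceConfig()
        highlighted = image.with_pixels(image.pixels * predicted.pixels)
        truth_hl = truth_image.with_pixels(truth_image.pixels * truth_mask.pixels)
        _kp_a, desc_a = detect_and_describe(highlighted, cfg)
        _kp_b, desc_b = detect_and_describe(truth_hl, cfg)
        match_count = match_keypoints(desc_a, desc_b, ratio).count
        passed = match_count >= min_matches and dice >= dice_floor
    else:
        match_count = -1
        passed = dice >= dice_floor

    unit = "mm^2" if size_mode in ("linear", "physical") else ""
    return TumorReport(
        white_pixels=w, tumor_size=size, size_unit=unit, status=status,
        match_count=match_count, pixel_accuracy=accuracy, dice=dice,
        passed=passed,
    )
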