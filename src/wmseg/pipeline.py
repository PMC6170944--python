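"""End-to-end orchestration: filter stack -> watershed -> verification.

The default filter order is trilateral -> bilateral -> median (edge-aware
smoothing first, impulse rejection last); each stage and its parameters are
configurable.  ``run_pipeline`` is pure (arrays in, report out);
``run_pipeline_files`` adds the file I/O and intermediate artifacts the CLI
exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .filtering import (
    TrilateralParams,
    bilateral_filter,
    median_filter_3x3,
    trilateral_filter,
    filter_report,
    FilterReport,
)
from .image import Image2D, BinaryMask, read_image, read_mask, write_image, write_mask
from .sift import ScaleSpaceConfig, detect_and_describe, match_keypoints
from .verify import TumorReport, verify
from .watershed import SegmentationResult, WatershedConfig, segment_tumor

__all__ = ["PipelineConfig", "PipelineResult", "apply_filter_stack", "run_pipeline",
           "run_pipeline_files", "StageError"]


class StageError(RuntimeError):
    """Raised when a named pipeline stage fails."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    filter_order: tuple[str, ...] = ("trilateral", "bilateral", "median")
    trilateral: TrilateralParams = field(default_factory=TrilateralParams)
    bilateral_sigma_spatial: float = 2.0
    bilateral_sigma_range: float = 25.0
    watershed: WatershedConfig = field(default_factory=WatershedConfig)
    sift: ScaleSpaceConfig = field(default_factory=ScaleSpaceConfig)
    ratio: float = 0.8
    min_matches: int = 10
    dice_floor: float = 0.5
    pixel_scale: float = 0.264
    size_mode: str = "linear"
    critical_threshold: int = 500
    run_sift: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    filtered: Image2D
    filter_report: FilterReport
    segmentation: SegmentationResult
    report: TumorReport


def apply_filter_stack(image: Image2D, cfg: PipelineConfig) -> tuple[Image2D, FilterReport]:
    out = image
    for name in cfg.filter_order:
        if name == "trilateral":
            out = trilateral_filter(out, cfg.trilateral)
        elif name == "bilateral":
            out = bilateral_filter(out, cfg.bilateral_sigma_spatial, cfg.bilateral_sigma_range)
        elif name == "median":
            out = median_filter_3x3(out)
        else:
            raise ValueError(f"unknown filter {name!r}")
    return out, filter_report(image, out)


def run_pipeline(
    image: Image2D,
    truth_image: Image2D,
    truth_mask: BinaryMask,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """filter -> segment -> verify -> report, with stage-named failures."""
    cfg = cfg or PipelineConfig()
    try:
        filtered, freport = apply_filter_stack(image, cfg)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage name
        raise StageError("filter", str(exc)) from exc
    try:
        seg = segment_tumor(filtered, cfg.watershed)
    except Exception as exc:  # noqa: BLE001
        raise StageError("segment", str(exc)) from exc
    try:
        report = verify(
            filtered, seg.tumor_mask, truth_image, truth_mask,
            cfg.sift, cfg.ratio,
            min_matches=cfg.min_matches, dice_floor=cfg.dice_floor,
            pixel_scale=cfg.pixel_scale, size_mode=cfg.size_mode,
            critical_threshold=cfg.critical_threshold, run_sift=cfg.run_sift,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("verify", str(exc)) from exc
    return PipelineResult(filtered=filtered, filter_report=freport,
                          segmentation=seg, report=report)


def _overlay_contour(image: Image2D, mask: BinaryMask) -> np.ndarray:
    """RGB uint8 with the mask contour drawn in blue."""
    from scipy import ndimage

    gray = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    m = mask.as_bool()
    contour = m & ~ndimage.binary_erosion(m)
    rgb[contour] = (0, 0, 255)
    return rgb


def _keypoint_plot(image: Image2D, keypoints, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image.pixels, cmap="gray", vmin=0, vmax=255)
    if keypoints:
        ax.plot([kp.col_img for kp in keypoints], [kp.row_img for kp in keypoints],
                "+", color="lime", markersize=6)
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def run_pipeline_files(
    input_path: str | Path,
    truth_image_path: str | Path,
    truth_mask_path: str | Path,
    cfg: PipelineConfig,
    outdir: str | Path,
) -> PipelineResult:
    """File-based run writing every intermediate artifact under ``outdir``:
    filtered.png, gradient.png, labels.png, mask.png, overlay.png,
    keypoints.png, filter_report.csv, tumor_report.csv, tumor_report.txt."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        image = read_image(input_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", str(exc)) from exc
    try:
        truth_image = read_image(truth_image_path)
        truth_mask = read_mask(truth_mask_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("verify", f"cannot load ground truth: {exc}") from exc

    result = run_pipeline(image, truth_image, truth_mask, cfg)
    seg = result.segmentation

    write_image(result.filtered, outdir / "filtered.png")
    if seg.gradient is not None:
        mag = seg.gradient.magnitude
        scale = 255.0 / mag.max() if mag.max() > 0 else 1.0
        iio.imwrite(outdir / "gradient.png", np.clip(mag * scale, 0, 255).astype(np.uint8))
    iio.imwrite(outdir / "labels.png", seg.label_map.labels.astype(np.uint16))
    write_mask(seg.tumor_mask, outdir / "mask.png")
    iio.imwrite(outdir / "overlay.png", _overlay_contour(image, seg.tumor_mask))

    if cfg.run_sift:
        highlighted = result.filtered.with_pixels(result.filtered.pixels * seg.tumor_mask.pixels)
        kps, _ = detect_and_describe(highlighted, cfg.sift)
        _keypoint_plot(image, kps, outdir / "keypoints.png")
    else:
        _keypoint_plot(image, [], outdir / "keypoints.png")

    result.filter_report.to_csv(outdir / "filter_report.csv")
    result.report.to_csv(outdir / "tumor_report.csv")
    (outdir / "tumor_report.txt").write_text(result.report.to_text())
    return result
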