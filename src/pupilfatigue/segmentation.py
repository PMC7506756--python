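"""Per-frame pupil-candidate segmentation and IoU evaluation.

The mask source is pluggable. Two backends ship:

``threshold``
    A classical dark-pupil baseline: under near-infrared illumination with
    the source off the camera axis, the pupil is the darkest region of the
    frame, so pixels with intensity below ``intensity_thr`` are marked,
    then a morphological opening (speckle removal) followed by closing
    (fills corneal-glint holes inside the pupil) cleans the map.

``external_masks``
    Pass-through for masks produced elsewhere (e.g. a CNN segmenter),
    read from 0/255 PNG files named by frame number.

Mask quality is scored with pixel intersection-over-union (IoU) against a
ground-truth mask, and mIoU — the unweighted mean over a frame set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.morphology import closing, disk, opening

from .io_frames import EyeFrame, SegmentationMask


@dataclass(frozen=True)
class SegmenterConfig:
    """Backend selection plus the threshold-backend knobs.

    intensity_thr: mark pixels strictly darker than this (0–255).
    morph_radius: disk radius for opening-then-closing; 0 disables morphology.
    mask_dir: directory of 0/255 PNGs for the external_masks backend.
    """

    backend: str = "threshold"
    intensity_thr: int = 80
    morph_radius: int = 2
    mask_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.backend not in ("threshold", "external_masks"):
            raise ValueError(f"unknown backend: {self.backend!r}")
        if not 0 <= self.intensity_thr <= 255:
            raise ValueError("intensity_thr must be in [0, 255]")
        if self.morph_radius < 0:
            raise ValueError("morph_radius must be non-negative")
        if self.backend == "external_masks" and self.mask_dir is None:
            raise ValueError("external_masks backend requires mask_dir")


@dataclass(frozen=True)
class IoUReport:
    per_frame_iou: list[float]
    mean_iou: float


def segment_frame(frame: EyeFrame, config: SegmenterConfig) -> SegmentationMask:
    """Produce the binary pupil-candidate mask for one frame."""
    if config.backend == "external_masks":
        return _load_external_mask(frame.index, config)
    binary = frame.pixels < config.intensity_thr
    if config.morph_radius > 0:
        footprint = disk(config.morph_radius)
        binary = opening(binary, footprint)
        binary = closing(binary, footprint)
    return SegmentationMask(index=frame.index, mask=binary.astype(np.uint8))


def _load_external_mask(index: int, config: SegmenterConfig) -> SegmentationMask:
    import imageio.v3 as iio

    mask_dir = Path(config.mask_dir)
    matches = [p for p in mask_dir.glob("*.png") if _stem_number(p) == index]
    if not matches:
        raise FileNotFoundError(f"mask missing for frame {index} in {mask_dir}")
    raw = iio.imread(matches[0])
    if raw.ndim == 3:
        raw = raw[..., 0]
    return SegmentationMask(index=index, mask=(raw > 0).astype(np.uint8))


def _stem_number(path: Path) -> int | None:
    digits = "".join(ch for ch in path.stem if ch.isdigit())
    return int(digits) if digits else None


def segment_sequence(
    frames: list[EyeFrame], config: SegmenterConfig
) -> list[SegmentationMask]:
    return [segment_frame(f, config) for f in frames]


def compute_iou(pred: SegmentationMask, truth: SegmentationMask) -> float:
    """Pixel IoU = |pred ∧ truth| / |pred ∨ truth|.

    When both masks are empty the frames agree there is no pupil (e.g. a
    closed-eye frame) and IoU is defined as 1.0.
    """
    if pred.mask.shape != truth.mask.shape:
        raise ValueError(
            f"shape mismatch: {pred.mask.shape} vs {truth.mask.shape}"
        )
    p = pred.mask.astype(bool)
    t = truth.mask.astype(bool)
    union = np.count_nonzero(p | t)
    if union == 0:
        return 1.0
    return np.count_nonzero(p & t) / union


def compute_miou(
    pairs: list[tuple[SegmentationMask, SegmentationMask]]
) -> IoUReport:
    """Per-frame IoUs and their unweighted arithmetic mean (mIoU)."""
    if not pairs:
        raise ValueError("compute_miou requires at least one (pred, truth) pair")
    ious = [compute_iou(pred, truth) for pred, truth in pairs]
    return IoUReport(per_frame_iou=ious, mean_iou=float(np.mean(ious)))
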