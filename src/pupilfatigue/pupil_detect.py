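"""Pupil detection from a binary mask: contours → filters → ellipse area.

Per frame the chain is:

1. group mask pixels into connected components and take each component's
   outer contour (inner holes are ignored);
2. drop candidates with contour area CA ≤ ``CA_THR`` (default 300 px) —
   speckle and partial reflections are far smaller than a pupil;
3. drop elongated candidates whose bounding-box aspect ratio
   ``min(W, H) / max(W, H)`` is ≤ ``AS_THR`` (default 0.4) — a pupil is
   near-circular, eyelash shadows and lid boundaries are not;
4. if any candidates survive, the largest is the pupil; fit an ellipse to
   its outer contour by least squares and report the ellipse area π·a·b
   as the frame's pupil size. A frame with no surviving candidate has
   pupil size 0 (eye closed or no detectable pupil).

Both threshold comparisons are strict (``>``), and the aspect ratio is
symmetrized via min/max so tall and wide elongations are treated alike; see
the methods note for the reading of the filter directions this adopts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .io_frames import PupilTimeSeries, SegmentationMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    """Candidate filter thresholds.

    CA_THR: keep candidates with contour area strictly greater (pixels).
    AS_THR: keep candidates with min/max bounding-box ratio strictly greater.
    CA_MAX: optional upper area bound (None = disabled), for rigs where a
        mis-segmented eyelid region can dwarf the pupil.
    """

    CA_THR: float = 300.0
    AS_THR: float = 0.4
    CA_MAX: float | None = None

    def __post_init__(self) -> None:
        if self.CA_THR < 0:
            raise ValueError("CA_THR must be >= 0")
        if not 0 < self.AS_THR <= 1:
            raise ValueError("AS_THR must be in (0, 1]")
        if self.CA_MAX is not None and self.CA_MAX <= self.CA_THR:
            raise ValueError("CA_MAX must exceed CA_THR when enabled")


@dataclass(frozen=True, eq=False)
class PupilCandidate:
    """One connected component: outer contour plus its filter statistics."""

    contour: np.ndarray  # (N, 2) array of (row, col) boundary points
    CA: float  # filled area of the outer contour, pixels
    W: int  # bounding-box width (columns)
    H: int  # bounding-box height (rows)

    @property
    def aspect(self) -> float:
        return min(self.W, self.H) / max(self.W, self.H)


@dataclass(frozen=True)
class PupilMeasurement:
    """Per-frame result; ``area`` is 0 and ``ellipse`` is None for no-pupil frames.

    ellipse: (center_col, center_row, semi_axis_a, semi_axis_b, angle_rad).
    """

    index: int
    area: float
    ellipse: tuple[float, float, float, float, float] | None = None


def find_candidates(mask: SegmentationMask) -> list[PupilCandidate]:
    """One candidate per connected component, in frame-scan (label) order.

    CA is the component's hole-filled pixel count — for a raster region the
    filled outer-contour polygon area and the pixel count agree — and W, H
    come from the axis-aligned bounding box.
    """
    labels = measure.label(mask.mask, connectivity=2)
    candidates: list[PupilCandidate] = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        filled = region.image_filled
        # pad so find_contours closes the boundary at image edges
        padded = np.pad(filled, 1).astype(float)
        contours = measure.find_contours(padded, 0.5)
        if not contours:  # single isolated pixel still yields a contour; guard anyway
            continue
        contour = max(contours, key=len) + np.array([r0 - 1, c0 - 1])
        candidates.append(
            PupilCandidate(
                contour=contour,
                CA=float(np.count_nonzero(filled)),
                W=c1 - c0,
                H=r1 - r0,
            )
        )
    return candidates


def filter_candidates(
    cands: list[PupilCandidate], config: DetectorConfig
) -> list[PupilCandidate]:
    """Keep candidates passing the area and aspect tests; order preserved."""
    kept = []
    for c in cands:
        if c.CA <= config.CA_THR:
            continue
        if c.aspect <= config.AS_THR:
            continue
        if config.CA_MAX is not None and c.CA >= config.CA_MAX:
            continue
        kept.append(c)
    return kept


def select_pupil(cands: list[PupilCandidate]) -> PupilCandidate | None:
    """Largest surviving candidate is the pupil; ties keep the first in scan order."""
    if not cands:
        return None
    best = cands[0]
    for c in cands[1:]:
        if c.CA > best.CA:
            best = c
    return best


def fit_ellipse_area(cand: PupilCandidate, index: int = 0) -> PupilMeasurement:
    """Least-squares ellipse fit to the outer contour; pupil size = π·a·b.

    A contour with fewer than 5 points cannot constrain a conic; such frames
    are treated as no-pupil (area 0) with a warning.
    """
    pts = np.asarray(cand.contour, dtype=float)
    if len(pts) < 5:
        logger.warning("degenerate contour (%d points) at frame %d", len(pts), index)
        return PupilMeasurement(index=index, area=0.0)
    # EllipseModel expects (x, y) = (col, row)
    model = measure.EllipseModel.from_estimate(pts[:, ::-1])
    if not model:
        logger.warning("ellipse fit failed at frame %d", index)
        return PupilMeasurement(index=index, area=0.0)
    xc, yc = model.center
    a, b = model.axis_lengths  # semi-axes
    theta = float(model.theta)
    area = math.pi * abs(a) * abs(b)
    if not math.isfinite(area) or area <= 0:
        logger.warning("non-finite ellipse area at frame %d", index)
        return PupilMeasurement(index=index, area=0.0)
    return PupilMeasurement(
        index=index, area=area, ellipse=(xc, yc, abs(a), abs(b), theta)
    )


def detect_frame(mask: SegmentationMask, config: DetectorConfig) -> PupilMeasurement:
    """Full per-frame chain: candidates → filters → largest → ellipse area."""
    cands = filter_candidates(find_candidates(mask), config)
    pupil = select_pupil(cands)
    if pupil is None:
        return PupilMeasurement(index=mask.index, area=0.0)
    return fit_ellipse_area(pupil, index=mask.index)


def measure_sequence(
    masks: list[SegmentationMask], config: DetectorConfig
) -> list[PupilMeasurement]:
    return [detect_frame(m, config) for m in masks]


def detect_sequence(
    masks: list[SegmentationMask],
    config: DetectorConfig = DetectorConfig(),
    fps: float = 30.0,
) -> PupilTimeSeries:
    """Run the detection chain over an ordered mask sequence.

    Returns one pupil size per frame; frames with no surviving candidate
    contribute 0 (eye closed / no detectable pupil).
    """
    measurements = measure_sequence(masks, config)
    return PupilTimeSeries(
        areas=np.array([m.area for m in measurements]), fps=fps
    )
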