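"""Frame, mask and trace I/O for pupillometry recordings.

A recording is one of three source kinds:

* ``images`` — a directory of grayscale infrared eye frames (PNG/TIFF/BMP),
  filenames carrying a zero-padded frame number;
* ``masks`` — a directory of binary pupil-candidate masks (0/255 PNG, one per
  frame), e.g. exported by an external segmentation model;
* ``trace`` — a CSV pupil-size time series (``frame,area``), with area 0
  marking frames where no pupil is visible (eye closed).

Color inputs are converted to grayscale on read with the ITU-R BT.601 luma
weights (see :data:`LUMA_WEIGHTS`); the camera this emulates is IR-monochrome
but fixtures are often RGB PNG.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: RGB→gray conversion weights, fixed for reproducibility (ITU-R BT.601).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_FRAME_NUMBER_RE = re.compile(r"(\d+)(?!.*\d)")  # last digit run in the stem


@dataclass(frozen=True)
class EyeFrame:
    """One grayscale eye image: ``index`` frame number, ``pixels`` uint8 H×W."""

    index: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be non-negative, got {self.index}")
        if self.pixels.ndim != 2:
            raise ValueError("EyeFrame.pixels must be a 2-D grayscale array")


@dataclass(frozen=True)
class SegmentationMask:
    """Binary pupil-candidate map for one frame; values are exactly {0, 1}."""

    index: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("SegmentationMask.mask must be 2-D")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly {0, 1}")


@dataclass(frozen=True)
class PupilTimeSeries:
    """Ordered per-frame pupil areas in pixels; 0 means closed/no-pupil.

    Time of frame ``i`` is ``i / fps`` seconds (0-based convention).
    """

    areas: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", areas)
        if areas.ndim != 1 or areas.size < 1:
            raise ValueError("areas must be a non-empty 1-D sequence")
        if np.any(areas < 0) or np.any(~np.isfinite(areas)):
            raise ValueError("invalid area: areas must be finite and >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return int(self.areas.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps


@dataclass
class Recording:
    """One recording with exactly one populated source kind."""

    fps: float = 30.0
    frames: list[EyeFrame] | None = None
    masks: list[SegmentationMask] | None = None
    trace: PupilTimeSeries | None = None
    source_kind: str = field(init=False)

    def __post_init__(self) -> None:
        populated = [
            kind
            for kind, val in (
                ("images", self.frames),
                ("masks", self.masks),
                ("trace", self.trace),
            )
            if val is not None
        ]
        if len(populated) != 1:
            raise ValueError(
                f"exactly one of frames/masks/trace must be set, got {populated}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.source_kind = populated[0]


def _frame_number(path: Path) -> int:
    m = _FRAME_NUMBER_RE.search(path.stem)
    if m is None:
        raise ValueError(f"no frame number in filename: {path.name}")
    return int(m.group(1))


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3:
        rgb = img[..., :3].astype(float)
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported image dimensionality: {img.ndim}")


def _sorted_files(directory: str | Path, pattern: str) -> list[Path]:
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    files = sorted(directory.glob(pattern), key=_frame_number)
    if not files:
        raise ValueError(f"no frames: nothing matches {pattern!r} in {directory}")
    return files


def read_image_sequence(
    directory: str | Path, pattern: str = "*.png", fps: float = 30.0
) -> Recording:
    """Read a frame-numbered image directory into a Recording.

    Frames are ordered by the frame number embedded in the filename,
    regardless of directory listing order. All frames must share one shape.
    """
    files = _sorted_files(directory, pattern)
    frames: list[EyeFrame] = []
    shape: tuple[int, int] | None = None
    for f in files:
        pixels = _to_gray(iio.imread(f))
        if shape is None:
            shape = pixels.shape
        elif pixels.shape != shape:
            raise ValueError(
                f"shape mismatch: {f.name} is {pixels.shape}, expected {shape}"
            )
        frames.append(EyeFrame(index=_frame_number(f), pixels=pixels))
    return Recording(fps=fps, frames=frames)


def read_mask_sequence(
    directory: str | Path, pattern: str = "*.png", fps: float = 30.0
) -> Recording:
    """Read 0/255 mask PNGs, normalized to 0/1 (any non-zero pixel → 1)."""
    files = _sorted_files(directory, pattern)
    masks: list[SegmentationMask] = []
    shape: tuple[int, int] | None = None
    for f in files:
        raw = _to_gray(iio.imread(f))
        if shape is None:
            shape = raw.shape
        elif raw.shape != shape:
            raise ValueError(
                f"shape mismatch: {f.name} is {raw.shape}, expected {shape}"
            )
        masks.append(
            SegmentationMask(index=_frame_number(f), mask=(raw > 0).astype(np.uint8))
        )
    return Recording(fps=fps, masks=masks)


def write_image_sequence(
    frames: Iterable[EyeFrame], directory: str | Path, prefix: str = ""
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in frames:
        p = directory / f"{prefix}{frame.index:06d}.png"
        iio.imwrite(p, frame.pixels.astype(np.uint8))
        paths.append(p)
    return paths


def write_mask_sequence(
    masks: Iterable[SegmentationMask], directory: str | Path, prefix: str = ""
) -> list[Path]:
    """Write masks as 0/255 PNGs (the on-disk convention)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in masks:
        p = directory / f"{prefix}{m.index:06d}.png"
        iio.imwrite(p, (m.mask * 255).astype(np.uint8))
        paths.append(p)
    return paths


def read_trace_csv(path: str | Path, fps: float = 30.0) -> PupilTimeSeries:
    """Read a ``frame,area`` CSV into a time series.

    The frame column must be contiguous and increasing from its first value;
    gaps or reordering are an error — a missing frame is data loss, never
    silently filled.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"frame", "area"}.issubset(df.columns):
        raise ValueError("trace CSV must have header columns 'frame,area'")
    frames = df["frame"].to_numpy()
    areas = df["area"].to_numpy(dtype=float)
    if np.any(areas < 0):
        raise ValueError("invalid area: negative pupil size in trace")
    if len(frames) > 1 and np.any(np.diff(frames) != 1):
        raise ValueError("unsorted trace: frame numbers must be contiguous increasing")
    return PupilTimeSeries(areas=areas, fps=fps)


def write_trace_csv(series: PupilTimeSeries, path: str | Path) -> None:
    # areas written via repr so the read-back is bit-exact
    df = pd.DataFrame(
        {"frame": np.arange(len(series)), "area": [repr(float(a)) for a in series.areas]}
    )
    df.to_csv(path, index=False)


FEATURE_COLUMNS = [
    "segment_id",
    "condition",
    "accommodation_speed",
    "blink_freq",
    "eye_closed_duration",
]


def write_features_csv(records: Sequence[dict], path: str | Path) -> None:
    """Write per-segment fatigue-feature rows with a fixed column order.

    Each record must carry the :data:`FEATURE_COLUMNS` keys. Floats are
    written at full repr precision so a read-back round-trips exactly.
    """
    if not records:
        raise ValueError("write_features_csv requires at least one record")
    df = pd.DataFrame(list(records))
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature records missing columns: {sorted(missing)}")
    out = df[FEATURE_COLUMNS].copy()
    for col in FEATURE_COLUMNS[2:]:  # float columns, written repr-exact
        out[col] = out[col].map(lambda v: repr(float(v)))
    out.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV missing columns: {sorted(missing)}")
    return df
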