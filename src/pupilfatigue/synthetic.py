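"""Ground-truth-annotated synthetic pupillometry data.

Two generation levels, matching what the pipeline consumes:

* :func:`generate_signal` — a pupil-size time series: a slow sinusoidal
  area oscillation (accommodation, period of several seconds) plus Gaussian
  pixel noise, interrupted by blinks drawn from a Poisson process that zero
  the signal for a uniform-length run of frames.
* :func:`render_frames` — infrared-style eye images for such a series: a
  dark elliptical pupil on a brighter iris disk and skin background, with
  bright corneal-glint speckles; blink frames render a featureless eyelid.

Every generated recording carries a :class:`GroundTruth` (true areas, true
masks via rasterization, blink flags, noise-free inflection frames) so each
downstream stage can be scored against a known answer. All randomness flows
from a single ``numpy`` Generator per spec seed, with a fixed draw order
(blink onsets, blink durations, noise, then per-frame jitter and glints),
so replicates are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .io_frames import EyeFrame, PupilTimeSeries, SegmentationMask


@dataclass(frozen=True)
class SignalSpec:
    """Pupil-size signal parameters.

    Defaults emulate a 30 fps infrared recording: a ~1200 px² pupil
    (radius ≈ 20 px at 640×480) oscillating ±300 px² over 8 s, blinks at
    0.3/s lasting 5–10 frames, and pixel noise at 5% of the oscillation
    amplitude.
    """

    duration_s: float = 60.0
    fps: float = 30.0
    base_area: float = 1200.0
    osc_amplitude: float = 300.0
    osc_period_s: float = 8.0
    blink_rate: float = 0.3  # events/second (Poisson)
    blink_duration_frames: tuple[int, int] = (5, 10)  # uniform inclusive range
    noise_sigma: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if not self.base_area > self.osc_amplitude >= 0:
            raise ValueError("need base_area > osc_amplitude >= 0")
        if self.blink_rate < 0 or self.noise_sigma < 0:
            raise ValueError("blink_rate and noise_sigma must be >= 0")
        lo, hi = self.blink_duration_frames
        if not 1 <= lo <= hi:
            raise ValueError("blink_duration_frames must satisfy 1 <= min <= max")
        if self.osc_period_s <= 0:
            raise ValueError("osc_period_s must be positive")


@dataclass(frozen=True)
class ImageSpec:
    """Rendering parameters for infrared-style eye frames.

    Intensities must satisfy pupil < iris < skin (dark-pupil imaging).
    ``axis_ratio`` is the pupil's minor/major axis ratio: 1 renders circles,
    smaller values exercise the ellipse fit on true ellipses.
    """

    width: int = 640
    height: int = 480
    pupil_intensity: int = 30
    iris_intensity: int = 100
    skin_intensity: int = 170
    pupil_center_jitter: float = 2.0
    glint_count: int = 2
    glint_radius: int = 2
    axis_ratio: float = 1.0
    eyelid_closure_renders_blank: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height) < 64:
            raise ValueError("image dimensions must be >= 64")
        if not 0 <= self.pupil_intensity < self.iris_intensity < self.skin_intensity <= 255:
            raise ValueError("need 0 <= pupil < iris < skin <= 255")
        if not 0 < self.axis_ratio <= 1:
            raise ValueError("axis_ratio must be in (0, 1]")
        if self.glint_count < 0 or self.glint_radius < 0:
            raise ValueError("glint parameters must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame truth for a generated recording."""

    true_areas: np.ndarray  # noise-free pre-blink areas
    blink_flags: np.ndarray  # bool, True where the eye is closed
    inflection_frames: np.ndarray  # interior extrema of the noise-free signal
    mean_abs_slope: float  # mean |ΔS/ΔF| between consecutive noise-free extrema
    true_masks: list[SegmentationMask] = field(default_factory=list)


def _interior_extrema(values: np.ndarray) -> np.ndarray:
    """Sample-level interior extrema via sign changes of the difference."""
    diffs = np.diff(values)
    idx = []
    prev_sign = 0
    prev_arrival = 0
    for k, d in enumerate(diffs):
        s = int(np.sign(d))
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            idx.append(prev_arrival)
        prev_sign = s
        prev_arrival = k + 1
    return np.asarray(idx, dtype=int)


def generate_signal(spec: SignalSpec) -> tuple[PupilTimeSeries, GroundTruth]:
    """Generate a pupil-size series and its ground truth.

    area(t) = base_area + osc_amplitude · sin(2πt / osc_period_s) + ε,
    ε ~ N(0, noise_sigma²), clipped at 0; blink onsets from a Poisson
    process at ``blink_rate`` each zero a uniform-length frame run.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    clean = spec.base_area + spec.osc_amplitude * np.sin(
        2 * np.pi * t / spec.osc_period_s
    )

    # blink onsets: exponential inter-arrival gaps at blink_rate events/s.
    # Two blinks cannot fuse into one closure (the lids reopen between
    # events), so an onset landing inside the previous blink is deferred to
    # one open frame after it; the event count stays Poisson(rate·duration).
    blink = np.zeros(n, dtype=bool)
    lo, hi = spec.blink_duration_frames
    if spec.blink_rate > 0:
        onsets = []
        t_event = rng.exponential(1.0 / spec.blink_rate)
        while t_event < spec.duration_s:
            onsets.append(t_event)
            t_event += rng.exponential(1.0 / spec.blink_rate)
        durations = rng.integers(lo, hi + 1, size=len(onsets))
        prev_end = -2
        for onset, dur in zip(onsets, durations):
            start = max(int(onset * spec.fps), prev_end + 2)
            blink[start : start + int(dur)] = True
            prev_end = start + int(dur) - 1

    noise = rng.normal(0.0, spec.noise_sigma, size=n) if spec.noise_sigma > 0 else 0.0
    areas = np.clip(clean + noise, 0.0, None)
    areas[blink] = 0.0

    extrema = _interior_extrema(clean)
    if len(extrema) >= 2:
        dS = np.abs(np.diff(clean[extrema]))
        dF = np.diff(extrema)
        mean_abs_slope = float(np.mean(dS / dF))
    else:
        mean_abs_slope = 0.0

    series = PupilTimeSeries(areas=areas, fps=spec.fps)
    truth = GroundTruth(
        true_areas=clean,
        blink_flags=blink,
        inflection_frames=extrema,
        mean_abs_slope=mean_abs_slope,
    )
    return series, truth


def render_frames(
    series: PupilTimeSeries, spec: ImageSpec
) -> tuple[list[EyeFrame], list[SegmentationMask]]:
    """Render eye frames plus rasterized truth masks for a size series.

    Non-zero frames draw a filled pupil ellipse of the requested area
    (semi-axes a = √(area/(π·q)), b = q·a for axis ratio q) at a jittered
    center on an iris disk over skin background, plus bright glints inside
    the pupil; blink frames are uniform skin intensity with an empty mask.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    center = np.array([h / 2, w / 2])
    iris_radius = min(h, w) / 3
    frames: list[EyeFrame] = []
    masks: list[SegmentationMask] = []
    for i, area in enumerate(series.areas):
        img = np.full((h, w), spec.skin_intensity, dtype=np.uint8)
        mask = np.zeros((h, w), dtype=np.uint8)
        if area > 0:
            a = np.sqrt(area / (np.pi * spec.axis_ratio))
            b = spec.axis_ratio * a
            jitter = rng.normal(0.0, spec.pupil_center_jitter, size=2)
            cy, cx = center + jitter
            if a + spec.pupil_center_jitter * 3 > iris_radius:
                raise ValueError(
                    f"pupil semi-axis {a:.1f} px exceeds iris radius "
                    f"{iris_radius:.1f} px at frame {i}"
                )
            rr, cc = draw_disk((center[0], center[1]), iris_radius, shape=(h, w))
            img[rr, cc] = spec.iris_intensity
            # rotation fixed at 0: area, not orientation, is what the
            # pipeline measures
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w))
            img[rr, cc] = spec.pupil_intensity
            mask[rr, cc] = 1
            for _ in range(spec.glint_count):
                gr = rng.uniform(cy - b / 2, cy + b / 2)
                gc = rng.uniform(cx - b / 2, cx + b / 2)
                rr, cc = draw_disk((gr, gc), max(spec.glint_radius, 1), shape=(h, w))
                img[rr, cc] = 255
        elif not spec.eyelid_closure_renders_blank:
            rr, cc = draw_disk((center[0], center[1]), iris_radius, shape=(h, w))
            img[rr, cc] = spec.iris_intensity
        frames.append(EyeFrame(index=i, pixels=img))
        masks.append(SegmentationMask(index=i, mask=mask))
    return frames, masks
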