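"""Fatigue features from a pupil-size time series.

Three features quantify visual fatigue from the per-frame pupil-size signal
(0 = eye closed / no detectable pupil):

* **Pupil accommodation speed** ``P`` — the mean absolute rate of size
  change between consecutive *inflection points* of the signal,

      P = (1/N) · Σₙ |S₍ₙ₊₁₎ − Sₙ| / (F₍ₙ₊₁₎ − Fₙ),   N = #points − 1,

  where Sₙ is the pupil size and Fₙ the frame number of the n-th accepted
  inflection point. Fatigued iris muscles adjust the pupil more slowly, so
  P drops with fatigue. Reported in pixels/frame with a pixels/second
  convenience (P·fps).

* **Blink frequency** — maximal runs of zero-size frames, counted as one
  blink each, divided by the recording duration in seconds.

* **Eye-closed duration** — total zero-size frames, also expressed in
  seconds and as average closed time per second of recording.

Inflection points are found in two stages: every sample-level extremum of
the (optionally median-smoothed) signal is a *candidate*, computed within
each maximal non-zero segment independently so no pseudo-extremum spans a
blink; candidates are then accepted greedily when (1) the size change from
the previously accepted point alternates in sign and (2) its magnitude
exceeds ``delta_thr``, which discards insignificant wiggles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .io_frames import PupilTimeSeries

__all__ = [
    "InflectionPoint",
    "InflectionConfig",
    "FatigueFeatures",
    "zero_runs",
    "nonzero_segments",
    "find_inflection_candidates",
    "select_inflections",
    "accommodation_speed",
    "blink_frequency",
    "eye_closed_duration",
    "extract_features",
]


@dataclass(frozen=True)
class InflectionPoint:
    """(frame number, pupil size) pair; lives inside a non-zero segment."""

    F: int
    S: float


@dataclass(frozen=True)
class InflectionConfig:
    """delta_thr: minimum |ΔS| from the previous accepted point, in pixels,
    or "auto" = max(5% of the interquartile range of the non-zero sizes,
    5·σ̂) where σ̂ is a robust noise scale estimated from successive
    differences within non-zero segments (1.4826·median|Δ|/√2). The IQR
    term makes the gate scale-adaptive across pixel and normalized traces;
    the noise floor keeps frame-to-frame jitter from being promoted to
    accommodation swings.
    smoothing_window: odd moving-median width in frames; 1 disables it.
    """

    delta_thr: float | str = "auto"
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.delta_thr, str):
            if self.delta_thr != "auto":
                raise ValueError("delta_thr must be a number or 'auto'")
        elif self.delta_thr < 0:
            raise ValueError("delta_thr must be >= 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 1")

    def resolve_delta_thr(self, series: PupilTimeSeries) -> float:
        if self.delta_thr != "auto":
            return float(self.delta_thr)
        nz = series.areas[series.areas > 0]
        if nz.size == 0:
            return 0.0
        q75, q25 = np.percentile(nz, [75, 25])
        diffs = np.concatenate(
            [
                np.diff(series.areas[s : s + ln])
                for s, ln in nonzero_segments(series.areas)
                if ln > 1
            ]
            or [np.zeros(1)]
        )
        sigma_hat = 1.4826 * float(np.median(np.abs(diffs))) / np.sqrt(2.0)
        return max(0.05 * float(q75 - q25), 5.0 * sigma_hat)


@dataclass(frozen=True)
class FatigueFeatures:
    """The three fatigue features plus diagnostic counts for one segment."""

    P: float  # accommodation speed, pixels/frame
    P_per_second: float  # P · fps, pixels/second
    blink_freq: float  # blinks per second
    eye_closed: float  # average closed seconds per second of recording
    closed_seconds: float
    n_inflections: int
    n_blinks: int
    closed_frames: int


def zero_runs(areas: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero values as (start_index, length) pairs."""
    closed = np.asarray(areas) == 0
    padded = np.concatenate(([False], closed, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def nonzero_segments(areas: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of non-zero values as (start_index, length) pairs."""
    open_ = np.asarray(areas) != 0
    padded = np.concatenate(([False], open_, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _segment_extrema(values: np.ndarray) -> list[int]:
    """Indices of sample-level extrema within one segment, endpoints included.

    Interior extrema are sign changes of the discrete difference; plateaus
    contribute their first sample. Monotone or constant segments yield the
    endpoints only.
    """
    m = len(values)
    idx = [0]
    diffs = np.diff(values)
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
    if m - 1 not in idx:
        idx.append(m - 1)
    return idx


def find_inflection_candidates(
    series: PupilTimeSeries, config: InflectionConfig = InflectionConfig()
) -> list[InflectionPoint]:
    """All sample-level extrema of the signal, per non-zero segment.

    Zero-runs (blinks) are excised first and each segment is processed
    independently: a 0-size sample is sensor dropout, not pupil size, and
    no inflection may span a blink. Segment endpoints count as candidates.
    """
    if len(series) < 3:
        raise ValueError("series must have at least 3 frames")
    areas = series.areas
    out: list[InflectionPoint] = []
    for start, length in nonzero_segments(areas):
        seg = areas[start : start + length].astype(float)
        if config.smoothing_window > 1 and length >= config.smoothing_window:
            seg = median_filter(seg, size=config.smoothing_window, mode="nearest")
        if length == 1:
            out.append(InflectionPoint(F=start, S=float(seg[0])))
            continue
        for i in _segment_extrema(seg):
            out.append(InflectionPoint(F=start + i, S=float(seg[i])))
    return out


def select_inflections(
    cands: list[InflectionPoint], delta_thr: float
) -> list[InflectionPoint]:
    """Greedy left-to-right acceptance of significant alternating extrema.

    The first candidate anchors the scan. A candidate is accepted when the
    size difference from the previously accepted point (1) alternates in
    sign relative to the previously accepted difference (the first accepted
    difference sets the reference) and (2) exceeds ``delta_thr`` in
    magnitude. Among consecutive same-direction candidates the most extreme
    is retained: a candidate continuing the current direction replaces the
    previously accepted point rather than being dropped, so each accepted
    point is the true turning extremum.

    The output therefore has strictly alternating difference signs and every
    consecutive |ΔS| > delta_thr.
    """
    if not cands:
        return []
    accepted = [cands[0]]
    direction = 0  # sign of the last accepted difference
    for c in cands[1:]:
        d = c.S - accepted[-1].S
        s = int(np.sign(d))
        if s == 0:
            continue
        if direction == 0:
            if abs(d) > delta_thr:
                accepted.append(c)
                direction = s
        elif s == direction:
            # still moving the same way: this is the more extreme turning point
            accepted[-1] = c
        elif abs(d) > delta_thr:
            accepted.append(c)
            direction = s
    return accepted


def accommodation_speed(infl: list[InflectionPoint]) -> float:
    """Mean absolute slope between consecutive inflection points (px/frame).

    Fewer than two points give no between-point interval; P is 0 by
    convention.
    """
    if len(infl) < 2:
        return 0.0
    total = 0.0
    for a, b in zip(infl, infl[1:]):
        dF = b.F - a.F
        if dF == 0:
            raise ValueError("zero frame gap between inflection points")
        total += abs((b.S - a.S) / dF)
    return total / (len(infl) - 1)


def blink_frequency(series: PupilTimeSeries) -> float:
    """Maximal zero-runs per second. Leading/trailing zero-runs count too:
    a blink truncated by the recording boundary is still a blink."""
    return len(zero_runs(series.areas)) / series.duration_s


def eye_closed_duration(series: PupilTimeSeries) -> tuple[int, float, float]:
    """(closed_frames, closed_seconds, average closed time per second)."""
    closed_frames = int(np.count_nonzero(series.areas == 0))
    closed_seconds = closed_frames / series.fps
    return closed_frames, closed_seconds, closed_seconds / series.duration_s


def extract_features(
    series: PupilTimeSeries, config: InflectionConfig = InflectionConfig()
) -> FatigueFeatures:
    """Compute all three fatigue features for one recording segment."""
    if len(series) < 3:
        raise ValueError("series must have at least 3 frames")
    delta_thr = config.resolve_delta_thr(series)
    cands = find_inflection_candidates(series, config)
    infl = select_inflections(cands, delta_thr)
    P = accommodation_speed(infl)
    closed_frames, closed_seconds, avg_closed = eye_closed_duration(series)
    n_blinks = len(zero_runs(series.areas))
    return FatigueFeatures(
        P=P,
        P_per_second=P * series.fps,
        blink_freq=n_blinks / series.duration_s,
        eye_closed=avg_closed,
        closed_seconds=closed_seconds,
        n_inflections=len(infl),
        n_blinks=n_blinks,
        closed_frames=closed_frames,
    )
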