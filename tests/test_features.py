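"""Inflection points, accommodation speed, blink and eye-closure features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilfatigue.features import (
    FatigueFeatures,
    InflectionConfig,
    InflectionPoint,
    accommodation_speed,
    blink_frequency,
    extract_features,
    eye_closed_duration,
    find_inflection_candidates,
    select_inflections,
    zero_runs,
)
from pupilfatigue.io_frames import PupilTimeSeries

from conftest import build_blink_series


def _series(values, fps=30.0):
    return PupilTimeSeries(areas=np.asarray(values, dtype=float), fps=fps)


class TestInflectionCandidates:
    def test_constant_series_endpoints_only(self):
        cands = find_inflection_candidates(_series([500] * 10))
        assert [c.F for c in cands] == [0, 9]

    def test_single_peak(self):
        cands = find_inflection_candidates(_series([100, 150, 200, 150, 100]))
        assert [(c.F, c.S) for c in cands] == [(0, 100.0), (2, 200.0), (4, 100.0)]

    def test_sinusoid_matches_discrete_derivative_oracle(self):
        t = np.arange(600)
        vals = 1000 + 300 * np.sin(2 * np.pi * t / 120)
        cands = find_inflection_candidates(_series(vals))
        interior = [c.F for c in cands if c.F not in (0, 599)]
        # brute-force oracle: sign change of the first difference
        d = np.sign(np.diff(vals))
        oracle = [
            i
            for i in range(1, 599)
            if d[i - 1] != 0 and d[i] != 0 and d[i - 1] != d[i]
        ]
        assert abs(len(interior) - len(oracle)) <= 1
        # 600 frames of period 120 contain ~10 extrema
        assert len(interior) in (9, 10, 11)

    def test_zero_runs_excised_no_candidate_in_blink(self):
        vals = [100, 200, 100, 0, 0, 0, 100, 300, 100]
        cands = find_inflection_candidates(_series(vals))
        assert all(c.S > 0 for c in cands)
        assert all(not 3 <= c.F <= 5 for c in cands)
        # both segments contribute their own extrema
        assert {c.F for c in cands} == {0, 1, 2, 6, 7, 8}

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            find_inflection_candidates(_series([1, 2]))


def _points(sizes, frames=None):
    frames = frames if frames is not None else range(0, 10 * len(sizes), 10)
    return [InflectionPoint(F=f, S=float(s)) for f, s in zip(frames, sizes)]


class TestSelectInflections:
    def test_alternating_large_swings_all_kept(self):
        out = select_inflections(_points([100, 200, 100]), delta_thr=50)
        assert [p.S for p in out] == [100, 200, 100]

    def test_small_swing_leaves_anchor_only(self):
        out = select_inflections(_points([100, 130, 100]), delta_thr=50)
        assert len(out) == 1
        assert out[0].S == 100

    def test_same_direction_keeps_most_extreme(self):
        # rising run 100->180->260: only the final extreme is the turning point
        out = select_inflections(_points([100, 180, 260, 100]), delta_thr=50)
        assert [p.S for p in out] == [100, 260, 100]

    def test_noisy_triangle_recovers_vertices(self):
        rng = np.random.default_rng(21)
        period, amp, n = 60, 300, 600
        tri = amp * np.abs((np.arange(n) % period) / (period / 2) - 1)
        noisy = tri + rng.normal(0, 10, n) + 500
        series = _series(noisy)
        cands = find_inflection_candidates(series)
        out = select_inflections(cands, delta_thr=50)
        # vertices of the noise-free triangle every period/2 frames, plus the
        # trailing segment endpoint (a truncated descent is still a swing)
        true_vertices = list(range(0, n, period // 2)) + [n - 1]
        assert len(out) == len(true_vertices)
        for p, v in zip(out, true_vertices):
            assert abs(p.F - v) <= 3

    def test_output_alternates_and_exceeds_threshold(self):
        rng = np.random.default_rng(22)
        sizes = rng.uniform(100, 1000, 200)
        out = select_inflections(_points(sizes), delta_thr=75)
        diffs = np.diff([p.S for p in out])
        assert np.all(np.abs(diffs) > 75)
        assert np.all(np.sign(diffs)[1:] != np.sign(diffs)[:-1])


class TestAccommodationSpeed:
    def test_worked_substitution(self):
        pts = _points([100, 200, 100], frames=[0, 30, 60])
        assert accommodation_speed(pts) == pytest.approx(10 / 3)

    def test_single_point_is_zero(self):
        assert accommodation_speed(_points([100], frames=[0])) == 0.0

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(23)
        frames = np.sort(rng.choice(10000, size=20, replace=False))
        sizes = rng.uniform(100, 2000, 20)
        pts = _points(sizes, frames)
        # independently coded re-summation
        expected = np.mean(
            [
                abs(sizes[i + 1] - sizes[i]) / (frames[i + 1] - frames[i])
                for i in range(19)
            ]
        )
        assert accommodation_speed(pts) == pytest.approx(expected, rel=1e-12)

    def test_zero_frame_gap_is_error(self):
        pts = _points([100, 200], frames=[5, 5])
        with pytest.raises(ValueError, match="zero frame gap"):
            accommodation_speed(pts)


class TestBlinkAndClosure:
    def test_worked_example_blink_frequency(self, worked_example_series):
        assert blink_frequency(worked_example_series) == 0.5

    def test_worked_example_closure(self, worked_example_series):
        closed_frames, closed_seconds, avg = eye_closed_duration(worked_example_series)
        assert closed_frames == 26
        assert closed_seconds == pytest.approx(26 / 30)
        # printed values truncate: 0.8667 s -> 0.86, 0.0867 -> 0.086
        assert int(closed_seconds * 100) / 100 == 0.86
        assert int(avg * 1000) / 1000 == 0.086

    def test_all_nonzero_series(self):
        assert blink_frequency(_series([100] * 60)) == 0.0

    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    @settings(max_examples=25, deadline=None)
    def test_random_runs_match_rle_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        areas = np.full(1000, 500.0)
        # place k non-adjacent zero-runs
        starts = np.sort(rng.choice(np.arange(0, 980, 20), size=k, replace=False))
        for s in starts:
            areas[s : s + rng.integers(1, 10)] = 0.0
        series = _series(areas)
        runs = zero_runs(series.areas)
        assert len(runs) == k
        assert blink_frequency(series) == pytest.approx(k / (1000 / 30))

    def test_conservation_of_frames(self, worked_example_series):
        closed_frames, _, _ = eye_closed_duration(worked_example_series)
        nonzero = np.count_nonzero(worked_example_series.areas)
        assert closed_frames + nonzero == len(worked_example_series)


class TestExtractFeatures:
    def test_all_zero_series_conventions(self):
        f = extract_features(_series([0] * 300))
        assert f.P == 0.0
        assert f.n_blinks == 1
        assert f.blink_freq == pytest.approx(1 / 10.0)
        assert f.eye_closed == 1.0

    def test_worked_example_composition(self, worked_example_series):
        f = extract_features(worked_example_series)
        assert f.blink_freq == 0.5
        assert f.closed_frames == 26

    def test_scaling_nonzero_areas_scales_p_only(self):
        series = build_blink_series(open_area=1.0)
        rng = np.random.default_rng(31)
        areas = series.areas.copy()
        areas[areas > 0] = rng.uniform(500, 1500, np.count_nonzero(areas))
        base = _series(areas)
        scaled = _series(areas * 3.0)
        cfg = InflectionConfig(delta_thr=10.0)
        f1 = extract_features(base, cfg)
        f2 = extract_features(scaled, InflectionConfig(delta_thr=30.0))
        assert f2.blink_freq == f1.blink_freq
        assert f2.eye_closed == f1.eye_closed
        assert f2.P == pytest.approx(3.0 * f1.P, rel=1e-9)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(32)
        areas = rng.uniform(100, 2000, 300)
        areas[rng.integers(0, 300, 15)] = 0.0
        cfg = InflectionConfig(delta_thr=100.0)
        fwd = extract_features(_series(areas), cfg)
        rev = extract_features(_series(areas[::-1].copy()), cfg)
        assert rev.blink_freq == fwd.blink_freq
        assert rev.closed_frames == fwd.closed_frames

    def test_sinusoid_speed_matches_true_slope(self):
        t = np.arange(1800)
        amp, period = 300.0, 240
        vals = 1200 + amp * np.sin(2 * np.pi * t / period)
        f = extract_features(_series(vals), InflectionConfig(delta_thr=50.0))
        # between adjacent extrema the sinusoid traverses 2*amp in period/2 frames
        true_slope = 2 * amp / (period / 2)
        assert f.P == pytest.approx(true_slope, rel=0.10)
        assert f.blink_freq == 0.0
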