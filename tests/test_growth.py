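"""Smoothing, tracking, cubic growth fits, division and lag extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cellflow import growth, measure, pipeline, segment, synth
from cellflow.growth import (
    CellTrack,
    CubicGrowthModel,
    DivisionRecord,
    SmoothingConfig,
    detect_division,
    exp_smooth,
    fit_cubic,
    growth_rate,
    lag_phase,
    track_cells,
)
from conftest import single_cell_scene


def make_track(raw, smoothed=None, interval=5.0, event="censored", cell_id=1):
    raw = np.asarray(raw, float)
    times = interval * np.arange(raw.size)
    end = times[-1] + (interval if event in ("division", "lost") else 0.0)
    return CellTrack(
        cell_id=cell_id, times=times, raw_volumes=raw,
        smoothed=None if smoothed is None else np.asarray(smoothed, float),
        attachment_time=0.0, end_event=event, end_time=end,
    )


class TestExpSmooth:
    def test_constant_series_fixed_point(self):
        assert np.allclose(exp_smooth([27.0, 27.0, 27.0], 0.1), [27, 27, 27])

    def test_one_step_recursion(self):
        assert np.allclose(exp_smooth([0.0, 10.0], 0.1), [0.0, 1.0])

    def test_two_step_recursion(self):
        assert np.allclose(exp_smooth([10.0, 20.0, 30.0], 0.5), [10.0, 15.0, 22.5])

    @given(st.integers(min_value=0, max_value=999))
    def test_bounds_for_random_series(self, seed):
        y = np.random.default_rng(seed).uniform(5.0, 150.0, size=30)
        s = exp_smooth(y, 0.1)
        assert np.all(s >= y.min() - 1e-12) and np.all(s <= y.max() + 1e-12)

    def test_alpha_to_one_limit_returns_raw(self):
        y = np.random.default_rng(1).uniform(10, 20, size=20)
        assert np.allclose(exp_smooth(y, 1 - 1e-9), y, rtol=1e-7)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.3, 2.0])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            exp_smooth([1.0, 2.0], alpha)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            exp_smooth([], 0.1)
        with pytest.raises(ValueError):
            exp_smooth([1.0, np.nan], 0.1)


class TestCubicFit:
    def test_exact_recovery_table_rows(self):
        t = np.arange(0.0, 8001.0, 5.0)
        for a, b, c, d in [(1.6e-10, 1.0e-3, 0.8e-2, 25.0), (2.0e-10, 0.22e-3, 0.0, 27.0)]:
            v = ((a * t + b) * t + c) * t + d
            res = fit_cubic(t, v)
            assert res.d == pytest.approx(d, rel=1e-6)
            assert res.a == pytest.approx(a, rel=1e-4)
            assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    @given(
        st.floats(min_value=-2e-10, max_value=4e-10),
        st.floats(min_value=-2e-3, max_value=4e-3),
        st.floats(min_value=-1e-2, max_value=1.2e-2),
        st.floats(min_value=20.0, max_value=55.0),
    )
    def test_exact_cubic_recovery_property(self, a, b, c, d):
        t = np.arange(0.0, 2001.0, 5.0)
        v = ((a * t + b) * t + c) * t + d
        if np.any(v <= 0):
            return
        res = fit_cubic(t, v)
        assert res.d == pytest.approx(d, rel=1e-6)
        assert res.rsquared >= 1.0 - 1e-9

    def test_constant_series_convention(self):
        res = fit_cubic(np.arange(5.0), np.full(5, 27.0))
        assert res.params[:3] == pytest.approx([0, 0, 0], abs=1e-9)
        assert res.d == pytest.approx(27.0)
        assert res.rsquared == 1.0
        assert res.constant_target

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 points"):
            fit_cubic([0, 5, 10], [1, 2, 3])

    def test_repeated_times_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_cubic([0, 5, 5, 10], [1, 2, 2, 3])

    def test_noise_shrinks_into_standard_errors(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 2001.0, 5.0)
        v = 27.0 + 0.01 * t + rng.normal(0, 1.0, t.size)
        res = fit_cubic(t, v)
        assert abs(res.d - 27.0) < 4 * res.bse[3]
        assert 0.9 < res.rsquared <= 1.0

    def test_summary_mentions_all_coefficients(self):
        res = fit_cubic(np.arange(8.0), 27.0 + 0.5 * np.arange(8.0))
        text = res.summary()
        for token in ("R-squared", "a", "b", "c", "d"):
            assert token in text

    def test_from_track_uses_smoothed_series(self):
        tr = make_track(27.0 + 0.5 * np.arange(10.0))
        res = CubicGrowthModel.from_track(tr).fit()
        assert tr.smoothed is not None
        assert res.nobs == 10


class TestGrowthRate:
    def test_linear_model_constant_rate(self):
        res = fit_cubic(np.arange(6.0), 27.0 + 0.8 * np.arange(6.0))
        assert growth_rate(res, 0.0) == pytest.approx(0.8, abs=1e-9)
        assert growth_rate(res, 100.0) == pytest.approx(0.8, abs=1e-6)

    def test_closed_form_polynomial(self):
        res = fit_cubic([0, 1, 2, 3, 4], [0, 3, 14, 39, 84])  # t^3+t^2+t
        assert growth_rate(res, 2.0) == pytest.approx(17.0, rel=1e-9)

    def test_constant_volume_zero_rate(self):
        res = fit_cubic(np.arange(5.0), np.full(5, 27.0))
        assert growth_rate(res, 123.0) == pytest.approx(0.0, abs=1e-9)


def detection(r, c, vol, det_id=1):
    return segment.Detection(
        det_id=det_id, centroid=(r, c), area_px2=50.0, major_px=10.0,
        minor_px=6.0, orientation_rad=0.0, volume_um3=vol,
    )


def dsets_from(spec):
    """spec: list of (t, [(r, c, vol), ...])"""
    out = []
    for t, dets in spec:
        ds = segment.DetectionSet(t_min=float(t))
        for i, (r, c, v) in enumerate(dets, start=1):
            ds.detections.append(detection(r, c, v, det_id=i))
        out.append(ds)
    return out


class TestTracking:
    def test_stationary_cell_single_track(self):
        spec = [(5.0 * i, [(50.0, 50.0, 30.0 + i)]) for i in range(10)]
        tracks = track_cells(dsets_from(spec))
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.times.size == 10
        assert tr.end_event == "censored"
        assert tr.end_time == 45.0

    def test_lost_cell_ends_with_loss_event(self):
        spec = [(5.0 * i, [(50.0, 50.0, 30.0)]) for i in range(5)]
        spec += [(5.0 * i, []) for i in range(5, 8)]
        tracks = track_cells(dsets_from(spec))
        assert tracks[0].end_event == "lost"
        assert tracks[0].end_time == 25.0  # last seen at 20 + interval

    def test_division_fixture_from_renderer(self, trained_classifier, default_config):
        """A rendered division (two daughters at 45 % volume) ends the
        parent track with a division event at the split frame."""
        scene = single_cell_scene(volume=90.0, division_time=100.0, seed=13)
        frames, _ = synth.generate_timelapse(scene, 0.0, 120.0, 5.0)
        dsets = pipeline.process_frames(frames, trained_classifier, default_config)
        tracks = track_cells(dsets)
        parent = min(tracks, key=lambda t: t.attachment_time)
        assert parent.end_event == "division"
        assert parent.end_time == 100.0
        daughters = [t for t in tracks if t.attachment_time == 100.0]
        assert len(daughters) == 2

    def test_new_detection_opens_track(self):
        spec = [(0.0, [(50.0, 50.0, 30.0)]),
                (5.0, [(50.0, 50.0, 30.0), (120.0, 120.0, 25.0)]),
                (10.0, [(50.0, 50.0, 30.0), (120.0, 120.0, 25.0)])]
        tracks = track_cells(dsets_from(spec))
        assert len(tracks) == 2
        assert sorted(t.attachment_time for t in tracks) == [0.0, 5.0]

    def test_non_uniform_grid_rejected(self):
        spec = [(0.0, [(50.0, 50.0, 30.0)]), (5.0, [(50.0, 50.0, 30.0)]),
                (12.0, [(50.0, 50.0, 30.0)])]
        with pytest.raises(ValueError, match="uniform"):
            track_cells(dsets_from(spec))

    def test_unannotated_detections_rejected(self):
        ds = segment.DetectionSet(t_min=0.0)
        ds.detections.append(segment.Detection(
            det_id=1, centroid=(5, 5), area_px2=10, major_px=4, minor_px=3,
            orientation_rad=0.0))
        with pytest.raises(ValueError, match="volume-annotated"):
            track_cells([ds])


class TestDivisionDetection:
    def test_monotone_track_has_no_division(self):
        tr = make_track(np.linspace(27, 80, 12), smoothed=np.linspace(27, 80, 12))
        assert detect_division(tr) is None

    def test_constructed_drop(self):
        s = [50.0, 80.0, 100.0, 45.0, 46.0]
        tr = make_track(s, smoothed=s)
        rec = detect_division(tr, drop_fraction=0.30)
        assert rec is not None
        assert rec.division_t_min == 15.0  # the falling step
        assert rec.volume_at_division_um3 == 100.0
        assert rec.growth_period_min == 15.0

    def test_tracker_event_takes_precedence(self):
        s = np.linspace(27, 100, 10)
        tr = make_track(s, smoothed=s, event="division")
        rec = detect_division(tr)
        assert rec.division_t_min == 50.0
        assert rec.volume_at_division_um3 == pytest.approx(100.0)
        assert rec.growth_period_d == pytest.approx(50.0 / 1440.0)

    def test_raw_series_option_avoids_smoother_lag(self):
        raw = np.linspace(27, 100, 10)
        tr = make_track(raw, event="division").smooth(0.1)
        rec = detect_division(tr, use_smoothed=False)
        assert rec.volume_at_division_um3 == pytest.approx(100.0)

    def test_detected_division_volume_matches_generator(
        self, trained_classifier, default_config
    ):
        """On a rendered division fixture the detected size at division
        matches the generating polynomial's value one frame before the
        split, within measurement error."""
        scene = single_cell_scene(volume=85.0, growth_rate=0.02,
                                  division_time=100.0, seed=17)
        frames, _ = synth.generate_timelapse(scene, 0.0, 120.0, 5.0)
        dsets = pipeline.process_frames(frames, trained_classifier, default_config)
        tracks = track_cells(dsets)
        parent = min(tracks, key=lambda t: t.attachment_time)
        rec = detect_division(parent, use_smoothed=False)
        expected = scene.cells[0].volume(95.0)
        assert rec.volume_at_division_um3 == pytest.approx(expected, rel=0.05)


class TestLagPhase:
    def test_constant_track_never_rises(self):
        tr = make_track(np.full(10, 27.0), smoothed=np.full(10, 27.0))
        assert lag_phase(tr) is None

    def test_ten_percent_rise(self):
        s = [27.0, 27.0, 30.0, 33.0]
        tr = make_track(s, smoothed=s)
        assert lag_phase(tr, rise_fraction=0.10) == 10.0  # 30 > 29.7

    def test_zero_rise_fraction_boundary(self):
        s = [27.0, 27.0, 27.1, 30.0]
        tr = make_track(s, smoothed=s)
        assert lag_phase(tr, rise_fraction=0.0) == 10.0


class TestTrackContainer:
    def test_non_uniform_times_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            CellTrack(cell_id=1, times=[0, 5, 12], raw_volumes=[1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CellTrack(cell_id=1, times=[0, 5], raw_volumes=[1, 2, 3])

    def test_export_round_trip_lengths(self):
        tr = make_track([27, 28, 29, 30.0]).smooth(0.1)
        df = growth.tracks_to_frame([tr])
        assert len(df) == 4
        assert df.event.iloc[-1] == "censored"
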