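"""Tablet kinematics: stroke segmentation, velocity chain, and outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorkit import synthetic_data as sd
from tremorkit.core import PenTrace, count_strict_peaks
from tremorkit.tablet_kinematics import (
    MIN_FILTER_SAMPLES,
    Stroke,
    compute_tablet_metrics,
    detect_pauses,
    mean_velocity,
    pointwise_distance,
    pointwise_velocity,
    resample_uniform,
    segment_strokes,
    smooth_velocity,
    task_duration,
    velocity_profiles,
)

from conftest import brute_force_peaks, make_wavy_trace


def _trace(t, x, y, pen):
    return PenTrace(np.asarray(t, float), np.asarray(x, float), np.asarray(y, float),
                    np.asarray(pen, int))


class TestSegmentation:
    def test_pen_runs_define_strokes(self):
        tr = _trace([0, 1, 2, 3, 4, 5], range(6), np.zeros(6), [1, 1, 0, 0, 1, 1])
        strokes = segment_strokes(tr)
        assert [len(s) for s in strokes] == [2, 2]
        assert strokes[0].t.tolist() == [0, 1]
        assert strokes[1].t.tolist() == [4, 5]

    def test_all_pen_down_is_one_stroke(self):
        tr = _trace(range(5), range(5), np.zeros(5), np.ones(5))
        strokes = segment_strokes(tr)
        assert len(strokes) == 1 and len(strokes[0]) == 5

    def test_no_pen_down_raises(self):
        tr = _trace([0, 1], [0, 0], [0, 0], [0, 0])
        with pytest.raises(ValueError, match="no pen-down"):
            segment_strokes(tr)

    def test_generated_handwriting_has_word_count_strokes(self):
        path = sd.generate_task_path(sd.TaskSpec("handwriting", word_count=5), seed=2)
        traj = sd.time_parameterize(path, 150.0, 0.5)
        trace = sd.sample_pen_trace(traj, seed=0)
        assert len(segment_strokes(trace)) == 5


class TestDurationAndPauses:
    def test_single_stroke_duration(self):
        s = [Stroke(np.array([0.0, 1.5, 3.0]), np.zeros(3), np.zeros(3))]
        assert task_duration(s) == 3.0
        assert detect_pauses(s) == (0, 0.0)

    def test_duration_includes_pause(self):
        s = [
            Stroke(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2)),
            Stroke(np.array([1.5, 2.5]), np.zeros(2), np.zeros(2)),
        ]
        assert task_duration(s) == 2.5
        n, t = detect_pauses(s)
        assert n == 1 and t == pytest.approx(0.5)

    def test_multiple_gaps_sum(self):
        s = [
            Stroke(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2)),
            Stroke(np.array([1.5, 2.0]), np.zeros(2), np.zeros(2)),
            Stroke(np.array([2.6, 3.0]), np.zeros(2), np.zeros(2)),
        ]
        n, t = detect_pauses(s)
        assert n == 2 and t == pytest.approx(0.5 + 0.6)

    def test_overlapping_strokes_rejected(self):
        s = [
            Stroke(np.array([0.0, 2.0]), np.zeros(2), np.zeros(2)),
            Stroke(np.array([1.0, 3.0]), np.zeros(2), np.zeros(2)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            detect_pauses(s)

    def test_programmed_task_duration_recovered(self):
        spec = sd.TaskSpec("spiral", base_speed=150.0)
        path = sd.generate_task_path(spec)
        traj = sd.time_parameterize(path, spec.base_speed, spec.inter_stroke_pause)
        trace = sd.sample_pen_trace(traj, seed=0)
        strokes = segment_strokes(trace)
        assert task_duration(strokes) == pytest.approx(traj.duration, abs=1 / 142)


class TestDistanceAndVelocity:
    def test_three_four_five(self):
        s = Stroke(np.array([0.0, 1.0]), np.array([0.0, 3.0]), np.array([0.0, 4.0]))
        assert pointwise_distance(s).tolist() == [5.0]

    def test_stationary_pen_zero_distance(self):
        s = Stroke(np.arange(4.0), np.ones(4), np.ones(4))
        assert pointwise_distance(s).tolist() == [0.0, 0.0, 0.0]

    def test_closed_rectangle_perimeter(self):
        xy = np.array([[0, 0], [100, 0], [100, 50], [0, 50], [0, 0]], float)
        s = Stroke(np.arange(5.0), xy[:, 0], xy[:, 1])
        assert pointwise_distance(s).sum() == pytest.approx(300.0)

    def test_degenerate_stroke_raises(self):
        with pytest.raises(ValueError, match="2 samples"):
            pointwise_distance(Stroke(np.array([0.0]), np.array([1.0]), np.array([1.0])))

    def test_resample_exact_on_linear_data(self):
        t = np.array([0.0, 0.3, 0.55, 1.0])
        grid, v = resample_uniform(t, 2.0 * t + 1.0, fs=142.0)
        assert len(grid) == 143
        np.testing.assert_allclose(v, 2.0 * grid + 1.0, rtol=1e-12)

    def test_resample_sinusoid_error_bounded_by_curvature(self):
        # linear interpolation error <= max|f''| * dt^2 / 8
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 2, 300))
        t[0], t[-1] = 0.0, 2.0
        f = 3.0
        x = np.sin(2 * np.pi * f * t)
        grid, v = resample_uniform(t, x, fs=142.0)
        dt_max = np.max(np.diff(t))
        bound = (2 * np.pi * f) ** 2 * dt_max**2 / 8
        assert np.max(np.abs(v - np.sin(2 * np.pi * f * grid))) <= bound + 1e-12

    def test_resample_rejects_bad_fs(self):
        with pytest.raises(ValueError):
            resample_uniform(np.array([0.0, 1.0]), np.array([0.0, 1.0]), fs=0.0)

    def test_velocity_arithmetic(self):
        v = pointwise_velocity(np.array([2.0]), 1.0 / 142.0)
        assert v[0] == pytest.approx(284.0)
        assert pointwise_velocity(np.zeros(5), 0.01).tolist() == [0.0] * 5

    def test_velocity_rejects_zero_interval(self):
        with pytest.raises(ValueError, match="positive"):
            pointwise_velocity(np.array([1.0]), 0.0)


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        v = np.full(500, 37.5)
        for zp in (False, True):
            np.testing.assert_allclose(smooth_velocity(v, zero_phase=zp), v, atol=1e-9)

    def test_low_frequency_amplitude_preserved(self):
        fs, f = 142.0, 0.5
        t = np.arange(0, 60, 1 / fs)
        v = np.sin(2 * np.pi * f * t)
        out = smooth_velocity(v, fs=fs)
        mid = slice(int(10 * fs), int(50 * fs))
        amp = np.sqrt(2.0) * np.std(out[mid])
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_seven_hz_strongly_attenuated_single_pass(self):
        fs, f = 142.0, 7.0
        t = np.arange(0, 60, 1 / fs)
        out = smooth_velocity(np.sin(2 * np.pi * f * t), fs=fs)
        mid = slice(int(10 * fs), int(50 * fs))
        amp = np.sqrt(2.0) * np.std(out[mid])
        assert amp < 0.04

    def test_short_stroke_rejected(self):
        with pytest.raises(ValueError, match=str(MIN_FILTER_SAMPLES)):
            smooth_velocity(np.ones(MIN_FILTER_SAMPLES - 1))

    def test_short_stroke_flagged_not_dropped(self, wavy_trace):
        # a second stroke of ~0.05 s is too short to filter but still counted
        trace, _ = wavy_trace(n_strokes=1, stroke_duration=4.0)
        t_gap = trace.t[-1] + np.array([0.1, 0.2])
        t_extra = trace.t[-1] + 0.5 + np.arange(5) / 142.0
        x_extra = trace.x[-1] + 10.0 + np.arange(5.0)
        tr = PenTrace(
            np.concatenate([trace.t, t_gap, t_extra]),
            np.concatenate([trace.x, np.full(2, trace.x[-1]), x_extra]),
            np.concatenate([trace.y, np.zeros(7)]),
            np.concatenate([trace.pen, np.zeros(2, int), np.ones(5, int)]),
        )
        with pytest.warns(UserWarning, match="too short to smooth"):
            prof = velocity_profiles(tr)
        assert prof.unsmoothed_strokes == [1]
        m = compute_tablet_metrics(tr)
        assert m.n_strokes == 2 and m.n_unsmoothed_strokes >= 1


class TestPeaksAndMeanVelocity:
    @pytest.mark.parametrize(
        "series, expected",
        [([0, 1, 0, 2, 0], 2), ([1, 2, 3, 4, 5], 0), ([2, 2, 2], 0), ([0, 1, 1, 0], 0)],
    )
    def test_peak_examples(self, series, expected):
        assert count_strict_peaks(np.array(series, float)) == expected

    def test_sinusoidal_velocity_one_peak_per_cycle(self):
        t = np.arange(0, 10, 1 / 142.0)
        # phase offset so maxima do not fall exactly midway between samples
        # (two equal neighbours would defeat the strict-inequality rule)
        v = 100 + 10 * np.sin(2 * np.pi * 1.0 * t + 0.4)
        assert abs(count_strict_peaks(v) - 10) <= 1

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=0, max_size=60))
    def test_peak_counter_matches_brute_force(self, series):
        assert count_strict_peaks(np.array(series)) == brute_force_peaks(series)

    def test_mean_velocity_examples(self):
        from tremorkit.tablet_kinematics import VelocityProfile

        p = VelocityProfile(fs=142.0, v=[np.full(100, 100.0)])
        assert mean_velocity(p) == 100.0
        p2 = VelocityProfile(fs=142.0, v=[np.full(50, 50.0), np.full(50, 150.0)])
        assert mean_velocity(p2) == 100.0

    def test_tremor_free_spiral_recovers_base_speed(self):
        spec = sd.TaskSpec("spiral", base_speed=120.0)
        traj = sd.time_parameterize(sd.generate_task_path(spec), 120.0, 0.5)
        trace = sd.sample_pen_trace(traj, seed=1)
        m = compute_tablet_metrics(trace)
        assert m.mean_velocity == pytest.approx(120.0, rel=0.02)


class TestMetricsPipeline:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_strokes=1, stroke_duration=4.0, speed=120.0),
            dict(n_strokes=2, stroke_duration=4.0, speed=120.0, pause=0.5),
            dict(n_strokes=3, stroke_duration=2.0, speed=200.0, wave_freq=0.5, pause=0.25),
            dict(n_strokes=2, stroke_duration=5.0, speed=150.0, wave_freq=0.8, amp_frac=0.2),
        ],
    )
    def test_hand_computed_metrics(self, kw):
        trace, exp = make_wavy_trace(**kw)
        m = compute_tablet_metrics(trace)
        assert m.duration == pytest.approx(exp["duration"], abs=1e-9)
        assert m.pause_count == exp["pause_count"]
        assert m.pause_time == pytest.approx(exp["pause_time"], abs=1e-9)
        assert m.mean_velocity == pytest.approx(exp["mean_velocity"], rel=0.01)
        assert m.peak_count == exp["peak_count"]
        assert m.scaled_peaks == m.peak_count / m.duration

    def test_determinism(self, wavy_trace):
        trace, _ = wavy_trace()
        assert compute_tablet_metrics(trace) == compute_tablet_metrics(trace)

    def test_pause_plus_stroke_durations_equal_duration(self, wavy_trace):
        trace, _ = wavy_trace(n_strokes=3, stroke_duration=2.0, wave_freq=0.5, pause=0.4)
        strokes = segment_strokes(trace)
        m = compute_tablet_metrics(trace)
        stroke_time = sum(s.t[-1] - s.t[0] for s in strokes)
        assert m.pause_time + stroke_time == pytest.approx(m.duration, abs=1 / 142.0)

    def test_tremor_raises_raw_but_not_smoothed_velocity_variance(self):
        # 6.5 Hz pen tremor lies above the 3.5 Hz cutoff: it should inflate
        # the raw velocity variance but be removed by smoothing
        spec = sd.TaskSpec("spiral", base_speed=150.0)
        path = sd.generate_task_path(spec)
        var_raw, var_smooth = [], []
        for amp in (0.0, 2.0, 4.0):
            traj = sd.add_tremor(
                sd.time_parameterize(path, 150.0, 0.5),
                sd.TremorSpec(frequency=6.5, amplitude_px=amp),
            )
            trace = sd.sample_pen_trace(traj, seed=4)
            var_raw.append(np.var(velocity_profiles(trace, smooth=False).all_samples()))
            var_smooth.append(np.var(velocity_profiles(trace, smooth=True).all_samples()))
        assert var_raw[0] < var_raw[1] < var_raw[2]
        # smoothed variance moves far less than the raw inflation
        raw_rise = var_raw[2] - var_raw[0]
        smooth_rise = abs(var_smooth[2] - var_smooth[0])
        assert smooth_rise < 0.1 * raw_rise
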