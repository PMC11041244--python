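"""Synthetic generators: geometry, tremor injection, sampling, streams, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from tremorkit import synthetic_data as sd
from tremorkit.core import ACCEL_FS


class TestTaskGeometry:
    def test_closed_rectangle_perimeter(self):
        path = sd.generate_task_path(sd.TaskSpec("rectangle", size_px=100.0))
        assert len(path) == 1
        assert sd.arc_length(path[0]) == pytest.approx(300.0, rel=1e-9)

    def test_open_rectangle_has_four_segments(self):
        path = sd.generate_task_path(sd.TaskSpec("rectangle", rectangle_closed=False))
        assert len(path) == 4

    def test_spiral_arc_length_matches_quadrature(self):
        turns = 3
        spec = sd.TaskSpec("spiral", size_px=10.0 * 2 * np.pi * turns, turns=turns)
        path = sd.generate_task_path(spec)
        b = spec.size_px / (2 * np.pi * turns)
        exact = sd.spiral_arc_length(b, 2 * np.pi * turns)
        assert sd.arc_length(path[0]) == pytest.approx(exact, rel=1e-3)

    def test_star_is_single_closed_stroke_with_alternating_radius(self):
        path = sd.generate_task_path(sd.TaskSpec("star", size_px=100.0))
        assert len(path) == 1
        r = np.hypot(path[0][:, 0], path[0][:, 1])
        assert r.max() == pytest.approx(100.0, rel=1e-6)
        assert r.min() < 50.0

    def test_elelelel_single_stroke(self):
        path = sd.generate_task_path(sd.TaskSpec("elelelel", loops=4))
        assert len(path) == 1
        assert sd.arc_length(path[0]) > 0

    def test_handwriting_stroke_count(self):
        path = sd.generate_task_path(sd.TaskSpec("handwriting", word_count=5), seed=0)
        assert len(path) == 5

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            sd.TaskSpec("spiral", size_px=-1.0)
        with pytest.raises(ValueError):
            sd.TaskSpec("handwriting", word_count=1)
        with pytest.raises(ValueError):
            sd.TaskSpec("nonsense")

    def test_vertices_finite(self):
        for task in ("rectangle", "spiral", "star", "elelelel", "handwriting"):
            for stroke in sd.generate_task_path(sd.TaskSpec(task), seed=3):
                assert np.isfinite(stroke).all()


class TestTremorInjection:
    def _line_traj(self, speed=100.0):
        path = [np.column_stack([np.linspace(0, 1000, 2001), np.zeros(2001)])]
        return sd.time_parameterize(path, speed, 0.5)

    def test_zero_amplitude_is_identity(self):
        traj = self._line_traj()
        out = sd.add_tremor(traj, sd.TremorSpec(amplitude_px=0.0))
        for (t0, x0, y0), (t1, x1, y1) in zip(traj.strokes, out.strokes):
            np.testing.assert_array_equal(x0, x1)
            np.testing.assert_array_equal(y0, y1)

    def test_horizontal_line_gets_pure_sinusoid_in_y(self):
        traj = self._line_traj()
        out = sd.add_tremor(traj, sd.TremorSpec(frequency=6.0, amplitude_px=5.0, phase=0.0))
        t, _, y = out.strokes[0]
        np.testing.assert_allclose(y, 5.0 * np.sin(2 * np.pi * 6.0 * t), atol=1e-8)

    def test_rms_deviation_scales_with_amplitude(self):
        spec = sd.TaskSpec("spiral")
        path = sd.generate_task_path(spec)
        traj = sd.time_parameterize(path, 150.0, 0.5)
        devs = []
        for amp in (3.0, 6.0):
            out = sd.add_tremor(traj, sd.TremorSpec(amplitude_px=amp))
            d = []
            for (t, x, y), (_, xi, yi) in zip(out.strokes, traj.strokes):
                d.append(np.hypot(x - xi, y - yi))
            devs.append(np.sqrt(np.mean(np.concatenate(d) ** 2)))
        assert devs[1] / devs[0] == pytest.approx(2.0, rel=0.05)

    def test_single_point_stroke_rejected(self):
        traj = sd.Trajectory([(np.array([0.0]), np.array([1.0]), np.array([1.0]))], 100.0)
        with pytest.raises(ValueError):
            sd.add_tremor(traj, sd.TremorSpec(amplitude_px=1.0))


class TestPenSampling:
    def test_sample_count_on_uniform_grid(self):
        path = [np.column_stack([np.linspace(0, 1420, 5001), np.zeros(5001)])]
        traj = sd.time_parameterize(path, 142.0, 0.5)  # exactly 10 s stroke
        trace = sd.sample_pen_trace(traj, target_fs=142.0, jitter_sd=0.0)
        assert len(trace) == 1 + int(np.floor(10.0 * 142.0))

    def test_jittered_sampling_is_deterministic(self):
        path = sd.generate_task_path(sd.TaskSpec("star"), seed=0)
        traj = sd.time_parameterize(path, 150.0, 0.5)
        a = sd.sample_pen_trace(traj, jitter_sd=0.5e-3, seed=11)
        b = sd.sample_pen_trace(traj, jitter_sd=0.5e-3, seed=11)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.x, b.x)

    def test_median_rate_near_target(self):
        path = sd.generate_task_path(sd.TaskSpec("spiral"), seed=0)
        traj = sd.time_parameterize(path, 150.0, 0.5)
        trace = sd.sample_pen_trace(traj, jitter_sd=0.5e-3, seed=2)
        dt = np.diff(trace.t[trace.pen == 1])
        dt = dt[dt < 0.2]  # exclude the lift gap
        assert 1.0 / np.median(dt) == pytest.approx(142.0, rel=0.01)

    def test_two_strokes_one_gap(self):
        path = [
            np.column_stack([np.linspace(0, 100, 300), np.zeros(300)]),
            np.column_stack([np.linspace(0, 100, 300), np.ones(300) * 50]),
        ]
        traj = sd.time_parameterize(path, 100.0, 0.5)
        trace = sd.sample_pen_trace(traj, jitter_sd=0.0)
        from tremorkit.tablet_kinematics import detect_pauses, segment_strokes

        n, ptime = detect_pauses(segment_strokes(trace))
        assert n == 1
        assert ptime == pytest.approx(0.5, abs=2 / 142.0)


class TestAccelStream:
    def test_silent_stream_outside_claps(self):
        st = sd.generate_accel_stream(
            6.0, sd.TremorSpec(amplitude_g=0.0), claps=sd.ClapSpec(clap_times=(1.0,)),
            voluntary=None, noise_sd=0.0, seed=0, task_onset=4.0,
        )
        i0, i1 = int(1.0 * 128), int(1.0 * 128) + 120
        outside = np.ones(len(st), bool)
        outside[i0:i1] = False
        assert np.all(st.axes[outside] == 0.0)
        assert np.all(np.abs(st.axes[i0:i1, 0]) > 0)

    def test_periodogram_peak_at_tremor_frequency(self):
        st = sd.generate_accel_stream(
            16.0, sd.TremorSpec(frequency=6.3, amplitude_g=0.2), noise_sd=0.01, seed=1
        )
        f, p = sps.periodogram(st.axes[:, 0], fs=ACCEL_FS)
        assert abs(f[np.argmax(p)] - 6.3) <= 0.2

    def test_clap_burst_power_and_position(self):
        st = sd.generate_accel_stream(
            8.0, sd.TremorSpec(amplitude_g=0.1),
            claps=sd.ClapSpec(clap_times=(2.0,), clap_duration_samples=120, clap_power=0.3),
            voluntary=sd.VoluntarySpec(), noise_sd=0.03, seed=5, task_onset=4.0,
        )
        from tremorkit.accel_features import clap_power_series

        power = clap_power_series(st)
        i0 = int(round(2.0 * 128))
        assert np.all(power[i0 : i0 + 110] >= 0.17)

    def test_clap_overlapping_task_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            sd.generate_accel_stream(
                8.0, sd.TremorSpec(), claps=sd.ClapSpec(clap_times=(2.0,)),
                noise_sd=0.0, task_onset=1.0,
            )

    def test_clap_spec_validation(self):
        with pytest.raises(ValueError):
            sd.ClapSpec(clap_power=0.1)
        with pytest.raises(ValueError):
            sd.ClapSpec(clap_duration_samples=50)


class TestCohort:
    def _small_spec(self, seed=0, **kw):
        defaults = dict(
            n_participants=2,
            tasks=(sd.TaskSpec("rectangle", base_speed=200.0),
                   sd.TaskSpec("handwriting", word_count=2, base_speed=200.0)),
            repetitions=1,
            seed=seed,
        )
        defaults.update(kw)
        return sd.CohortSpec(**defaults)

    def test_file_counts(self, tmp_path):
        manifest = sd.generate_cohort(self._small_spec(), tmp_path)
        assert len(manifest) == 2 * 2 * 3
        for col in ("pen_file", "accel_file"):
            for f in manifest[col]:
                assert (tmp_path / f).exists()
        truth = pd.read_csv(tmp_path / "ground_truth.csv")
        assert len(truth) == len(manifest)

    def test_null_cohort_parameters_identical_across_conditions(self, tmp_path):
        spec = self._small_spec(intercept_sd=0.0, residual_sd=0.0)
        sd.generate_cohort(spec, tmp_path)
        truth = pd.read_csv(tmp_path / "ground_truth.csv")
        amps = truth.groupby("condition")["amplitude_px"].unique()
        for cond in amps.index:
            np.testing.assert_allclose(sorted(amps[cond]), sorted(amps["none"]))

    def test_same_seed_byte_identical_manifest(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.generate_cohort(self._small_spec(seed=42), d1)
        sd.generate_cohort(self._small_spec(seed=42), d2)
        assert (d1 / "manifest.csv").read_bytes() == (d2 / "manifest.csv").read_bytes()
        assert (d1 / "ground_truth.csv").read_bytes() == (d2 / "ground_truth.csv").read_bytes()
        pen = d1 / pd.read_csv(d1 / "manifest.csv")["pen_file"].iloc[0]
        pen2 = d2 / pd.read_csv(d2 / "manifest.csv")["pen_file"].iloc[0]
        assert pen.read_bytes() == pen2.read_bytes()


class TestOutcomeSimulator:
    def test_shape_and_determinism(self):
        a = sd.simulate_trial_outcomes(n_participants=9, seed=3)
        b = sd.simulate_trial_outcomes(n_participants=9, seed=3)
        assert len(a) == 27
        pd.testing.assert_frame_equal(a, b)

    def test_condition_shift_applied(self):
        df = sd.simulate_trial_outcomes(
            n_participants=200, intercept_sd=0.0, residual_sd=0.1,
            condition_effects={"high": 5.0}, seed=1,
        )
        means = df.groupby("condition", observed=True)["value"].mean()
        assert means["high"] - means["none"] == pytest.approx(5.0, abs=0.1)
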