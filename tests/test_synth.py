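import numpy as np
import pytest

from widecal import (
    SimParams,
    make_ground_truth,
    render_eyelid,
    render_movie,
    render_traces,
    transient_kernel,
)
from widecal.synth import bleach_profile, illumination_field, kernel_peak_time


class TestGroundTruth:
    def test_zero_cells_still_generates_schedule(self):
        params = SimParams(frame_height=32, frame_width=32, n_frames=10, n_cells=0,
                           n_trials=5, n_correct=3, seed=0)
        gt = make_ground_truth(params)
        assert gt.n_cells == 0
        assert gt.trial_schedule.n_trials == 5
        assert (gt.trial_outcomes == "correct").sum() == 3

    def test_deterministic_given_seed(self):
        params = SimParams(frame_height=64, frame_width=64, n_frames=40, n_cells=5,
                           soma_radius=4.0, n_trials=3, n_correct=2, seed=123)
        a = make_ground_truth(params)
        b = make_ground_truth(params)
        np.testing.assert_array_equal(a.cell_centers, b.cell_centers)
        np.testing.assert_array_equal(a.motion_trace, b.motion_trace)
        for ea, eb in zip(a.event_times, b.event_times):
            np.testing.assert_array_equal(ea, eb)
        ma = render_movie(a, params)
        mb = render_movie(b, params)
        np.testing.assert_array_equal(ma.frames, mb.frames)

    def test_cell_separation_and_disjoint_masks(self):
        params = SimParams(frame_height=128, frame_width=128, n_frames=10, n_cells=30,
                           soma_radius=4.0, n_trials=2, n_correct=1, seed=2)
        gt = make_ground_truth(params)
        from scipy.spatial.distance import pdist

        assert pdist(gt.cell_centers).min() >= 2 * params.soma_radius
        # every labeled pixel belongs to exactly one cell by construction
        areas = np.bincount(gt.cell_labels.ravel())[1:]
        assert len(areas) == 30
        assert np.all(areas > 0.8 * np.pi * params.soma_radius**2)

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError):
            SimParams(frame_height=32, frame_width=32, n_frames=10, n_cells=100,
                      soma_radius=4.0)

    def test_background_event_count_within_3_sd(self):
        # 100 cells x 0.05 events/s x 200 s -> Poisson(1000)
        params = SimParams(
            frame_height=256, frame_width=256, n_frames=4000, n_cells=100,
            soma_radius=4.0, background_rate=0.05, frac_positive=0.0,
            frac_negative=0.0, n_trials=1, n_correct=0, trial_start_s=10.0,
            seed=6,
        )
        gt = make_ground_truth(params)
        assert gt.session_duration_s == 200.0
        total = sum(len(e) for e in gt.event_times)
        assert abs(total - 1000) <= 3 * np.sqrt(1000)

    def test_positive_cells_receive_tone_locked_events(self):
        params = SimParams(
            frame_height=128, frame_width=128, n_frames=10, n_cells=10,
            soma_radius=4.0, background_rate=0.0, frac_positive=1.0,
            frac_negative=0.0, p_on=1.0, n_trials=8, n_correct=8, seed=7,
        )
        gt = make_ground_truth(params)
        for events in gt.event_times:
            assert len(events) == 8
            rel = events - gt.trial_schedule.tone_onset_s
            assert np.all((rel >= 0) & (rel < 0.6))

    def test_negative_cells_suppressed_after_tone(self):
        params = SimParams(
            frame_height=160, frame_width=160, n_frames=10, n_cells=40,
            soma_radius=4.0, background_rate=1.0, frac_positive=0.0,
            frac_negative=1.0, suppression_factor=0.0, n_trials=10,
            n_correct=10, seed=8,
        )
        gt = make_ground_truth(params)
        for events in gt.event_times:
            for tone in gt.trial_schedule.tone_onset_s:
                in_window = (events >= tone) & (events < tone + 2.0)
                assert not in_window.any()


class TestRenderMovie:
    def test_center_pixel_follows_kernel_exactly(self):
        params = SimParams(
            frame_height=64, frame_width=64, n_frames=60, n_cells=1,
            soma_radius=4.0, read_noise_sigma=0.0, shot_noise=False,
            quantize=False, resp_amplitude=0.0, jump_rate=0.0,
            illum_amplitude=0.0, bleach_end_fraction=1.0, background_rate=0.0,
            frac_positive=0.0, frac_negative=0.0, n_trials=1, n_correct=0,
            seed=3,
        )
        gt = make_ground_truth(params)
        gt.event_times[0] = np.array([1.0])  # one planted event
        movie = render_movie(gt, params)
        cy, cx = gt.cell_centers[0]
        trace = movie.frames[:, int(round(cy)), int(round(cx))].astype(float)
        t = np.arange(params.n_frames) / params.frame_rate
        # the soma profile at the (sub-pixel) centre is not exactly 1
        rho = np.hypot(round(cy) - cy, round(cx) - cx) / params.soma_radius
        profile = 1.0 / (1.0 + rho**6)
        expected = trace[0] + params.transient_amplitude * profile * transient_kernel(
            t - 1.0, params.tau_rise, params.tau_decay
        )
        np.testing.assert_allclose(trace, expected, atol=1e-6)

    def test_no_dynamics_means_constant_frames(self):
        params = SimParams(
            frame_height=48, frame_width=48, n_frames=20, n_cells=3,
            soma_radius=4.0, read_noise_sigma=0.0, shot_noise=False,
            quantize=False, resp_amplitude=0.0, jump_rate=0.0,
            bleach_end_fraction=1.0, background_rate=0.0, frac_positive=0.0,
            frac_negative=0.0, n_trials=1, n_correct=0, seed=4,
        )
        gt = make_ground_truth(params)
        movie = render_movie(gt, params)
        for t in range(1, 20):
            np.testing.assert_array_equal(movie.frames[t], movie.frames[0])

    def test_constant_mean_without_bleach(self):
        params = SimParams(
            frame_height=48, frame_width=48, n_frames=30, n_cells=2,
            soma_radius=4.0, bleach_end_fraction=1.0, background_rate=0.0,
            frac_positive=0.0, frac_negative=0.0, resp_amplitude=0.0,
            jump_rate=0.0, n_trials=1, n_correct=0, seed=5,
        )
        movie = render_movie(make_ground_truth(params), params)
        means = movie.frames.mean(axis=(1, 2))
        assert means.std() / means.mean() < 0.005

    def test_illumination_ratio_matches_constructed_field(self):
        params = SimParams(
            frame_height=64, frame_width=64, n_frames=10, n_cells=0,
            illum_amplitude=0.2, read_noise_sigma=0.0, shot_noise=False,
            quantize=False, resp_amplitude=0.0, jump_rate=0.0,
            bleach_end_fraction=1.0, n_trials=1, n_correct=0, seed=6,
        )
        gt = make_ground_truth(params)
        movie = render_movie(gt, params)
        field = illumination_field(params)
        ratio_movie = movie.frames[0, 0, 0] / movie.frames[0, 32, 32]
        ratio_field = field[0, 0] / field[32, 32]
        assert ratio_movie == pytest.approx(ratio_field, rel=1e-6)  # float32 storage

    def test_bleach_profile_endpoints(self):
        params = SimParams(frame_height=32, frame_width=32, n_frames=50,
                           n_cells=0, bleach_end_fraction=0.9, n_trials=1,
                           n_correct=0)
        prof = bleach_profile(params)
        assert prof[0] == 1.0
        assert prof[-1] == pytest.approx(0.9)
        assert np.all(np.diff(prof) < 0)


class TestKernel:
    def test_kernel_zero_before_event_and_peak_time(self):
        t = np.linspace(-0.5, 3.0, 1000)
        k = transient_kernel(t, 0.045, 0.40)
        assert np.all(k[t < 0] == 0)
        peak = kernel_peak_time(0.045, 0.40)
        assert t[np.argmax(k)] == pytest.approx(peak, abs=0.01)
        assert 0.05 < peak < 0.25  # sub-second GCaMP6f-like kinetics


class TestRenderTraces:
    def test_traces_cover_all_trials(self):
        params = SimParams(frame_height=64, frame_width=64, n_frames=10,
                           n_cells=3, soma_radius=4.0, n_trials=4, n_correct=3,
                           seed=9)
        gt = make_ground_truth(params)
        tm = render_traces(gt, params)
        assert tm.raw.shape[0] == 3
        assert tm.times[-1] >= gt.trial_schedule.tone_onset_s[-1] + 8.0


class TestRenderEyelid:
    def test_deterministic_and_covers_schedule(self):
        params = SimParams(frame_height=32, frame_width=32, n_frames=10,
                           n_cells=0, n_trials=6, n_correct=4, seed=10)
        gt = make_ground_truth(params)
        a = render_eyelid(gt, params)
        b = render_eyelid(gt, params)
        np.testing.assert_array_equal(a.reflection, b.reflection)
        assert len(a.reflection) >= (gt.trial_schedule.tone_onset_s[-1] + 1) * 20
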