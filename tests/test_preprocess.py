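import numpy as np
import pytest
from scipy import ndimage
from scipy.ndimage import fourier_shift

from widecal import (
    RegistrationParams,
    VideoSequence,
    apply_shift,
    correct_sequence,
    estimate_displacement,
    homomorphic_enhance,
)
from widecal.preprocess import update_template


def periodic_texture(shape=(64, 64), seed=1, smooth=1.5):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(0, 1, shape), smooth, mode="wrap")


class TestHomomorphicEnhance:
    def test_constant_frame_stays_constant(self):
        out = homomorphic_enhance(np.full((32, 32), 500.0), 8)
        np.testing.assert_allclose(out, out[0, 0], rtol=1e-9)

    def test_illumination_ramp_flattened(self):
        # flat tissue under a 0.8x..1.2x illumination ramp
        ramp = np.linspace(0.8, 1.2, 512)[None, :] * np.full((512, 1), 100.0)
        out = homomorphic_enhance(ramp, 32)
        cov_in = ramp.std() / ramp.mean()
        cov_out = out.std() / out.mean()
        assert cov_in / cov_out >= 10

    def test_small_feature_contrast_preserved(self):
        img = np.full((256, 256), 100.0) * np.linspace(0.8, 1.2, 256)[None, :]
        img[126:131, 126:131] *= 3.0

        def contrast(a):
            return a[126:131, 126:131].mean() / a[114:119, 126:131].mean()

        out = homomorphic_enhance(img, 32)
        assert contrast(out) == pytest.approx(contrast(img), rel=0.05)

    def test_nonfinite_rejected(self):
        frame = np.ones((8, 8))
        frame[0, 0] = np.nan
        with pytest.raises(ValueError):
            homomorphic_enhance(frame, 4)


class TestEstimateDisplacement:
    def test_self_registration_is_zero(self):
        f = periodic_texture()
        dx, dy, peak = estimate_displacement(f, f, RegistrationParams(max_shift=15))
        assert (dx, dy) == (0.0, 0.0)
        assert peak > 0.5

    def test_integer_roll_recovered_exactly(self):
        f = periodic_texture()
        g = np.roll(f, (-2, 3), axis=(0, 1))  # content moves up 2, right 3
        params = RegistrationParams(subpixel=False, max_shift=15, edge_taper=0.0)
        dx, dy, _ = estimate_displacement(g, f, params)
        assert (dx, dy) == (3.0, -2.0)

    @pytest.mark.parametrize("true", [(0.5, 0.25), (0.25, 0.5), (0.1, 0.9)])
    def test_subpixel_within_quarter_pixel(self, true):
        f = ndimage.gaussian_filter(
            np.random.default_rng(0).normal(1000, 50, (128, 128)), 2
        )
        g = np.fft.ifftn(fourier_shift(np.fft.fftn(f), true)).real
        dx, dy, _ = estimate_displacement(g, f, RegistrationParams(max_shift=15))
        assert dy == pytest.approx(true[0], abs=0.25)
        assert dx == pytest.approx(true[1], abs=0.25)

    def test_matches_reference_implementation(self):
        # independent oracle: scikit-image's phase cross-correlation
        from skimage.registration import phase_cross_correlation

        f = periodic_texture(seed=9)
        g = np.roll(f, (4, -5), axis=(0, 1))
        # skimage returns the shift registering moving onto reference,
        # i.e. the negative of the content displacement estimated here
        ref, _, _ = phase_cross_correlation(f, g, upsample_factor=20)
        dx, dy, _ = estimate_displacement(
            g, f, RegistrationParams(max_shift=15, edge_taper=0.0)
        )
        assert dy == pytest.approx(-ref[0], abs=0.25)
        assert dx == pytest.approx(-ref[1], abs=0.25)

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_displacement(np.zeros((32, 32)), np.zeros((32, 32)))

    def test_equal_peak_tie_prefers_smallest_shift(self):
        # a 2D pattern with period 8 has equal correlation peaks at all
        # multiples of 8; the zero shift must win
        tile = np.random.default_rng(3).normal(0, 1, (8, 8))
        f = np.tile(tile, (8, 8))
        params = RegistrationParams(subpixel=False, max_shift=20, edge_taper=0.0)
        dx, dy, _ = estimate_displacement(f, f, params)
        assert (dx, dy) == (0.0, 0.0)


class TestApplyShift:
    def test_zero_shift_identity(self):
        f = periodic_texture((16, 16))
        np.testing.assert_array_equal(apply_shift(f, 0, 0), f)

    def test_integer_shift_then_inverse_restores_interior(self):
        f = periodic_texture((32, 32), seed=5)
        back = apply_shift(apply_shift(f, 3, -2), -3, 2)
        np.testing.assert_allclose(back[4:-4, 4:-4], f[4:-4, 4:-4], atol=1e-12)

    def test_half_pixel_shift_of_ramp_is_neighbor_midpoint(self):
        ramp = np.tile(np.arange(16.0), (4, 1))
        out = apply_shift(ramp, 0.5, 0)
        np.testing.assert_allclose(out[:, 5], (ramp[:, 4] + ramp[:, 5]) / 2)


class TestUpdateTemplate:
    def test_first_frame_seeds_template(self):
        f = periodic_texture((8, 8))
        t = update_template(None, f, 0, RegistrationParams())
        np.testing.assert_array_equal(t, f)

    def test_identical_frames_leave_template_unchanged(self):
        f = periodic_texture((8, 8))
        params = RegistrationParams()
        t = update_template(None, f, 0, params)
        t = update_template(t, f, 1, params)
        np.testing.assert_allclose(t, f, atol=1e-12)

    def test_window_two_running_mean(self):
        params = RegistrationParams(template_window=2)
        a = np.full((4, 4), 2.0)
        b = np.full((4, 4), 6.0)
        t = update_template(None, a, 0, params)
        t = update_template(t, b, 1, params)
        np.testing.assert_allclose(t, np.full((4, 4), 4.0))


class TestCorrectSequence:
    def test_known_motion_recovered(self, registration_movie):
        params, gt, movie = registration_movie
        corrected, disp = correct_sequence(
            movie, RegistrationParams(max_shift=20, filter_sigma=16)
        )
        est = np.column_stack([disp.dx, disp.dy])
        err = est - gt.motion_trace
        err -= err[0]  # absolute reference is frame 0
        rmse = float(np.sqrt((err**2).mean()))
        assert rmse <= 0.25

    def test_motion_free_movie_reports_near_zero_displacement(self, clean_movie_params):
        from widecal import make_ground_truth, render_movie

        gt = make_ground_truth(clean_movie_params)
        movie = render_movie(gt, clean_movie_params)
        _, disp = correct_sequence(movie, RegistrationParams(max_shift=10, filter_sigma=12))
        assert disp.magnitude_um.mean() <= 0.1

    def test_jump_frames_corrected(self):
        from widecal import SimParams, make_ground_truth, render_movie

        params = SimParams(
            frame_height=128, frame_width=128, n_frames=60, n_cells=8,
            soma_radius=4.5, read_noise_sigma=0.0, shot_noise=False,
            quantize=False, jump_rate=1.0, bleach_end_fraction=1.0,
            n_trials=2, n_correct=1, seed=5,
        )
        gt = make_ground_truth(params)
        movie = render_movie(gt, params)
        reg = RegistrationParams(max_shift=20, filter_sigma=16)
        corrected, disp = correct_sequence(movie, reg)
        jump_frames = np.nonzero(
            np.abs(gt.motion_trace).max(axis=1) > 2.0
        )[0]
        assert len(jump_frames) > 0
        # residual displacement of corrected jump frames vs final mean image
        template = homomorphic_enhance(
            corrected.frames.mean(axis=0), reg.filter_sigma
        )
        for t in jump_frames:
            e = homomorphic_enhance(corrected.frames[t], reg.filter_sigma)
            dx, dy, _ = estimate_displacement(e, template, reg)
            assert np.hypot(dx, dy) <= 0.5

    def test_correction_is_idempotent(self, registration_movie):
        params, gt, movie = registration_movie
        reg = RegistrationParams(max_shift=20, filter_sigma=16)
        corrected, disp1 = correct_sequence(movie, reg)
        _, disp2 = correct_sequence(corrected, reg)
        assert disp2.magnitude_um.mean() <= disp1.magnitude_um.mean()

    def test_enhancement_does_not_shift_unmoved_content(self, registration_movie):
        params, gt, movie = registration_movie
        f = np.asarray(movie.frames[0], dtype=float)
        reg = RegistrationParams(max_shift=10, filter_sigma=16)
        e = homomorphic_enhance(f, reg.filter_sigma)
        dx, dy, _ = estimate_displacement(e, homomorphic_enhance(f, reg.filter_sigma), reg)
        assert np.hypot(dx, dy) <= 0.1

    def test_two_pass_fixed_template_mode_runs(self, registration_movie):
        params, gt, movie = registration_movie
        reg = RegistrationParams(
            max_shift=20, filter_sigma=16, template_mode="two_pass_fixed",
            template_window=10,
        )
        corrected, disp = correct_sequence(movie, reg)
        est = np.column_stack([disp.dx, disp.dy])
        err = est - gt.motion_trace
        err -= err[0]
        assert float(np.sqrt((err**2).mean())) <= 0.5
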