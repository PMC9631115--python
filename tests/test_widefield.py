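"""Widefield chain: compression, correction, normalization, mapping."""

import numpy as np
import pytest
from scipy import ndimage, signal

from visuomotor import widefield as wf
from visuomotor.synth import (
    BehaviorRegime,
    DelayGrid,
    default_widefield_truth,
    simulate_retinotopy,
    simulate_session,
    simulate_widefield,
)
from visuomotor.synth.retinotopy import RetinotopyPhantom, two_area_phantom


@pytest.fixture(scope="module")
def widefield_data():
    session = simulate_session(
        BehaviorRegime(mode="associated"), DelayGrid(), n_trials=6, seed=55
    )
    stack, truth = simulate_widefield(session, default_widefield_truth(), seed=56)
    return session, stack, truth


def band_power(x, fs, band=(5.0, 15.0)):
    f, p = signal.welch(x - x.mean(axis=1, keepdims=True), fs=fs, axis=1, nperseg=512)
    sel = (f >= band[0]) & (f <= band[1])
    return p[:, sel].sum(axis=1).mean()


class TestFrameStack:
    def test_rejects_non_alternating_labels(self):
        frames = np.zeros((4, 2, 2))
        times = np.arange(4.0)
        with pytest.raises(ValueError, match="alternate"):
            wf.FrameStack(frames, times, np.array(["blue", "blue", "violet", "blue"]))

    def test_synthetic_stack_alternates(self, widefield_data):
        _, stack, _ = widefield_data
        assert np.all(stack.illumination[::2] == "blue")
        assert np.all(stack.illumination[1::2] == "violet")

    def test_constant_frames_without_sources(self):
        session = simulate_session(
            BehaviorRegime(mode="null", bout_rate=0.0), DelayGrid(), 1, seed=1,
            response_timeout=5.0,
        )
        truth = default_widefield_truth(shape=(8, 8), noise_scale=0.0)
        truth.heartbeat_gain_blue = truth.heartbeat_gain_violet = 0.0
        truth.visual_amplitude = truth.motor_amplitude = 0.0
        stack, _ = simulate_widefield(session, truth, seed=2)
        assert np.ptp(stack.frames) == 0

    def test_heartbeat_band_peak_present(self, widefield_data):
        _, stack, truth = widefield_data
        blue, bt = stack.channel("blue")
        fs = 1.0 / np.median(np.diff(bt))
        trace = blue[np.argmax(truth.heartbeat_gain_map.ravel())]
        f, p = signal.periodogram(trace - trace.mean(), fs=fs)
        peak = f[np.argmax(p)]
        assert 5.0 <= peak <= 15.0


class TestSVDCompress:
    def test_rank_one_movie_exact(self, rng):
        x = np.outer(rng.normal(size=40), rng.normal(size=120))
        comps = wf.svd_compress(x, k=1)
        assert np.allclose(comps.reconstruct(), x, atol=1e-10)

    def test_planted_rank_captured(self, rng):
        u = rng.normal(size=(60, 5))
        v = rng.normal(size=(5, 300))
        x = u @ v + 0.01 * rng.normal(size=(60, 300))
        comps = wf.svd_compress(x, k=5)
        # oracle: the full decomposition's top-5 energy share
        s_full = np.linalg.svd(x, compute_uv=False)
        captured = (comps.singular_values**2).sum() / (s_full**2).sum()
        assert captured == pytest.approx((s_full[:5] ** 2).sum() / (s_full**2).sum())
        assert captured > 0.99

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            wf.svd_compress(rng.normal(size=(10, 20)), k=0)


class TestHemodynamicCorrection:
    def test_zero_violet_leaves_blue_unchanged(self, rng):
        n_pix, n_t = 36, 400
        blue = rng.normal(100, 1, size=(n_pix, n_t))
        violet = np.zeros((n_pix, n_t))
        bt = np.arange(n_t) / 35.0
        vt = bt + 0.5 / 35.0
        with pytest.warns(UserWarning, match="violet"):
            corrected, model = wf.hemodynamic_correct(blue, violet, bt, vt, shape=(6, 6))
        assert np.allclose(corrected, blue)
        assert np.all(model.scale == 0)

    def test_planted_artifact_removed_slow_signal_kept(self, widefield_data):
        _, stack, truth = widefield_data
        blue, bt = stack.channel("blue")
        violet, vt = stack.channel("violet")
        fs = 1.0 / np.median(np.diff(bt))
        corrected, _ = wf.hemodynamic_correct(blue, violet, bt, vt, shape=stack.shape)
        attenuation = 1.0 - band_power(corrected, fs) / band_power(blue, fs)
        assert attenuation > 0.9
        # projection of the planted visual trace recovers its amplitude
        vis = truth.visual_trace - truth.visual_trace.mean()
        px = np.argmax(truth.visual_map.ravel())
        gain_before = (blue[px] - blue[px].mean()) @ vis / (vis @ vis)
        gain_after = (corrected[px] - corrected[px].mean()) @ vis / (vis @ vis)
        assert gain_after / gain_before > 0.95

    def test_violet_channel_not_modified(self, widefield_data):
        _, stack, _ = widefield_data
        blue, bt = stack.channel("blue")
        violet, vt = stack.channel("violet")
        before = violet.copy()
        wf.hemodynamic_correct(blue, violet, bt, vt, shape=stack.shape)
        assert np.array_equal(violet, before)

    def test_idempotent_second_pass(self, widefield_data):
        _, stack, _ = widefield_data
        blue, bt = stack.channel("blue")
        violet, vt = stack.channel("violet")
        once, _ = wf.hemodynamic_correct(blue, violet, bt, vt, shape=stack.shape)
        twice, _ = wf.hemodynamic_correct(once, violet, bt, vt, shape=stack.shape)
        change = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once**2))
        assert change < 0.01


class TestNormalizeDff:
    def test_constant_input_maps_to_zero(self):
        traces = np.full((5, 600), 37.0)
        out = wf.normalize_dff(traces, fs=35.0)
        assert np.allclose(out.dff, 0.0, atol=1e-12)
        assert out.f0 == pytest.approx([37.0] * 5)

    def test_linear_ramp_removed(self, rng):
        t = np.arange(2000) / 35.0
        base = rng.normal(100, 1, size=(4, 1))
        traces = base + 0.5 * t
        out = wf.normalize_dff(traces, fs=35.0)
        slopes = np.polyfit(t, out.dff.T, 1)[0]
        assert np.all(np.abs(slopes) < 1e-4)

    def test_all_zero_input_warns(self):
        with pytest.warns(UserWarning, match="baseline"):
            out = wf.normalize_dff(np.zeros((3, 200)), fs=35.0)
        assert np.allclose(out.dff, 0.0)

    def test_softening_is_median_f0(self, rng):
        traces = rng.uniform(10, 200, size=(9, 1)) * np.ones((9, 300))
        out = wf.normalize_dff(traces, fs=35.0)
        assert out.softening == pytest.approx(np.median(traces[:, 0]))


@pytest.fixture(scope="module")
def kernel():
    fs = 35.0
    k = np.exp(-np.arange(0, 2, 1 / fs) / 0.3)
    return wf.DeconvKernel(k / k.sum(), fs)


class TestDeconvolve:
    def test_delta_kernel_is_identity(self, rng):
        y = rng.normal(size=(3, 200))
        out = wf.deconvolve(y, wf.DeconvKernel([1.0], 35.0), fs=35.0, lam=0.0)
        assert np.allclose(out, y, atol=1e-10)

    def test_recovers_impulse_train(self, rng, kernel):
        imp = np.zeros(700)
        imp[rng.integers(50, 650, 12)] = rng.uniform(0.5, 2.0, 12)
        y = np.convolve(imp, kernel.samples)[:700] + rng.normal(0, 0.002, 700)
        x = wf.deconvolve(y, kernel, fs=35.0, lam=1e-4)[0]
        assert np.corrcoef(x, imp)[0, 1] > 0.9

    def test_component_space_equals_pixel_space(self, rng, kernel):
        u, _ = np.linalg.qr(rng.normal(size=(30, 6)))
        sv = rng.normal(size=(6, 250))
        via_sv = u @ wf.deconvolve(sv, kernel, fs=35.0)
        via_pix = wf.deconvolve(u @ sv, kernel, fs=35.0)
        assert np.allclose(via_sv, via_pix, atol=1e-9)

    def test_kernel_resampling(self, kernel):
        resampled = kernel.resampled(70.0)
        assert resampled.sample_rate == 70.0
        assert resampled.samples.size == pytest.approx(2 * kernel.samples.size, abs=2)


class TestRecast:
    def test_same_basis_is_identity(self, rng):
        u, _ = np.linalg.qr(rng.normal(size=(80, 8)))
        sv = rng.normal(size=(8, 40))
        assert np.allclose(wf.recast_to_master(u, u, sv), sv, atol=1e-10)

    def test_contained_subspace_reconstructs_exactly(self, rng):
        u_exp, _ = np.linalg.qr(rng.normal(size=(80, 6)))
        u_master, _ = np.linalg.qr(np.hstack([u_exp, rng.normal(size=(80, 4))]))
        sv = rng.normal(size=(6, 40))
        recast = wf.recast_to_master(u_master, u_exp, sv)
        assert np.allclose(u_master @ recast, u_exp @ sv, atol=1e-10)

    def test_partial_overlap_residual_is_orthogonal_projection(self, rng):
        u_exp, _ = np.linalg.qr(rng.normal(size=(80, 6)))
        u_master, _ = np.linalg.qr(rng.normal(size=(80, 5)))
        sv = rng.normal(size=(6, 40))
        recast = wf.recast_to_master(u_master, u_exp, sv)
        residual = u_exp @ sv - u_master @ recast
        # oracle: explicit orthogonal-complement projector
        proj = np.eye(80) - u_master @ u_master.T
        assert np.allclose(residual, proj @ (u_exp @ sv), atol=1e-9)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            wf.recast_to_master(rng.normal(size=(10, 2)), rng.normal(size=(12, 2)), rng.normal(size=(2, 5)))


@pytest.fixture(scope="module")
def vasculature():
    rng = np.random.default_rng(88)
    return ndimage.gaussian_filter(rng.normal(size=(80, 80)), 2.0)


class TestAlignDays:
    def test_identical_images_identity_transform(self, vasculature):
        tfms = wf.align_days([vasculature, vasculature.copy()])
        assert tfms[1].angle == pytest.approx(0.0, abs=0.2)
        assert np.hypot(*tfms[1].shift) < 0.2

    def test_known_transform_recovered(self, vasculature):
        from skimage.transform import rotate

        moved = ndimage.shift(
            rotate(vasculature, -2.0, preserve_range=True), (-3.2, 1.7), mode="constant"
        )
        tfms = wf.align_days([vasculature, moved])
        assert tfms[1].angle == pytest.approx(2.0, abs=0.5)
        assert tfms[1].shift[0] == pytest.approx(3.2, abs=0.5)
        assert tfms[1].shift[1] == pytest.approx(-1.7, abs=0.5)

    def test_flat_image_rejected(self, vasculature):
        with pytest.raises(ValueError, match="flat"):
            wf.align_days([vasculature, np.zeros_like(vasculature)])


def hemisphere_traces(rng=None, noise=0.0, v_l=1.0, v_r=0.2, m_l=0.8, m_r=1.0):
    n = 6000
    v_trace = np.zeros(n)
    m_trace = np.zeros(n)
    stim_idx = np.arange(200, n - 300, 497)
    mov_idx = np.arange(350, n - 300, 613)
    for i in stim_idx:
        v_trace[i : i + 20] += np.hanning(20)
    for i in mov_idx:
        m_trace[i : i + 25] += np.hanning(25)
    f_l = v_l * v_trace + m_l * m_trace
    f_r = v_r * v_trace + m_r * m_trace
    if noise and rng is not None:
        f_l = f_l + rng.normal(0, noise, n)
        f_r = f_r + rng.normal(0, noise, n)
    epochs = [i for i in mov_idx if not np.any(np.abs(stim_idx - i) < 60)]
    return f_l, f_r, v_trace, m_trace, np.array(stim_idx), np.array(epochs)


class TestHemisphereSubtraction:
    def test_equal_hemispheres_give_unit_ratio_and_zero_output(self):
        f_l, f_r, *_ , epochs = hemisphere_traces(v_l=0.0, v_r=0.0, m_l=1.0, m_r=1.0)
        model = wf.fit_hemisphere_ratio(f_l, f_r, epochs, window=(0, 25))
        assert model.ratio == pytest.approx(1.0)
        assert np.allclose(wf.hemisphere_subtract(f_l, f_r, model), 0.0, atol=1e-12)

    def test_scaled_hemisphere_ratio(self):
        f_l, f_r, *_, epochs = hemisphere_traces(v_l=0.0, v_r=0.0, m_l=1.0, m_r=1.25)
        model = wf.fit_hemisphere_ratio(f_l, f_r, epochs, window=(0, 25))
        assert model.ratio == pytest.approx(0.8)

    def test_planted_gains_recovered_with_noise(self, rng):
        f_l, f_r, *_, epochs = hemisphere_traces(rng=rng, noise=0.01)
        model = wf.fit_hemisphere_ratio(f_l, f_r, epochs, window=(0, 25))
        assert model.ratio == pytest.approx(0.8, rel=0.05)

    def test_movement_cancels_visual_coefficient_correct(self):
        f_l, f_r, v_trace, m_trace, stim_idx, epochs = hemisphere_traces()
        model = wf.fit_hemisphere_ratio(f_l, f_r, epochs, window=(0, 25))
        asym = wf.hemisphere_subtract(f_l, f_r, model)
        leakage = np.abs(asym[epochs + 12]).max() / m_trace.max()
        assert leakage < 0.01
        # remaining signal is (v_L - m_L v_R / m_R) V = 0.84 V
        peak = stim_idx[0] + 10
        assert asym[peak] / v_trace[peak] == pytest.approx(0.84, abs=1e-6)

    def test_too_few_epochs_rejected(self):
        f_l, f_r, *_ = hemisphere_traces()
        with pytest.raises(ValueError, match="epochs"):
            wf.fit_hemisphere_ratio(f_l, f_r, [100], window=(0, 25))


class TestFieldSign:
    def test_orthogonal_gradients_give_plus_one(self):
        responses, positions, _ = simulate_retinotopy(seed=61)
        fsm = wf.field_sign_map(responses, positions, seed=62)
        interior = fsm.sign_map[4:-4, 4:-4]
        assert np.nanmean(interior) > 0.9

    def test_mirrored_area_gives_minus_one(self):
        phantom = RetinotopyPhantom(areas=[(slice(None), True)])
        responses, positions, _ = simulate_retinotopy(phantom, seed=61)
        fsm = wf.field_sign_map(responses, positions, seed=62)
        assert np.nanmean(fsm.sign_map[4:-4, 4:-4]) < -0.9

    def test_two_area_border_localized(self):
        phantom = two_area_phantom()  # border at column 24
        responses, positions, _ = simulate_retinotopy(phantom, noise=0.05, seed=63)
        fsm = wf.field_sign_map(responses, positions, seed=64, smoothing_sigma=2.0)
        col_mean = np.nanmean(fsm.sign_map[4:-4], axis=0)
        crossings = np.flatnonzero(np.diff(np.sign(col_mean)))
        assert crossings.size >= 1
        assert np.min(np.abs(crossings - 24)) <= 3  # within the smoothing radius

    def test_noise_free_center_of_mass_matches_planted_map(self):
        phantom = RetinotopyPhantom()
        responses, positions, _ = simulate_retinotopy(phantom, noise=0.0, seed=65)
        fsm = wf.field_sign_map(responses, positions, n_boot=1, smoothing_sigma=0.5, seed=66)
        az_true, _, _ = phantom.maps()
        az_spacing = (phantom.azimuth_range[1] - phantom.azimuth_range[0]) / 9
        err = np.abs(fsm.azimuth_map - az_true)[4:-4, 6:-6]
        assert np.median(err) < az_spacing

    def test_rotation_invariance_of_sign(self):
        """Rotating cortical coordinates rotates both gradients, not the sign."""
        responses, positions, _ = simulate_retinotopy(
            RetinotopyPhantom(shape=(30, 30)), seed=67
        )
        fsm = wf.field_sign_map(responses, positions, n_boot=1, seed=68)
        rotated = np.stack([np.rot90(r) for r in responses])
        fsm_rot = wf.field_sign_map(rotated, positions, n_boot=1, seed=68)
        a = fsm.sign_map[5:-5, 5:-5]
        b = np.rot90(fsm_rot.sign_map, -1)[5:-5, 5:-5]
        assert np.nanmax(np.abs(a - b)) < 0.05

    def test_too_few_squares_rejected(self, rng):
        responses = rng.normal(size=(6, 10, 10))
        positions = np.tile([[0.0, 0.0], [1.0, 0.0]], (3, 1))
        with pytest.raises(ValueError, match="few"):
            wf.field_sign_map(responses, positions)


class TestRoiTrace:
    def test_single_pixel_and_full_image(self, rng):
        u, _ = np.linalg.qr(rng.normal(size=(25, 4)))
        sv = rng.normal(size=(4, 50))
        movie = u @ sv
        mask = np.zeros(25, bool)
        mask[7] = True
        assert np.allclose(wf.roi_trace(u, sv, mask), movie[7])
        assert np.allclose(wf.roi_trace(u, sv, np.ones(25, bool)), movie.mean(axis=0))

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            wf.roi_trace(rng.normal(size=(25, 4)), rng.normal(size=(4, 5)), np.zeros(25, bool))
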