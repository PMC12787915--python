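"""Activation maps, kymographs, wavefront fitting and transmission delay."""

from dataclasses import replace

import numpy as np
import pytest

import wavegraft as wg
from wavegraft.wave_mapping import NoWavefrontError, _first_crossing_times
from conftest import single_wave_scenario


def brute_force_activation(frames: np.ndarray, pct: float) -> np.ndarray:
    """Reference per-pixel scan: explicit loop over frames with the relative
    threshold rule and linear interpolation at the straddling pair."""
    T, H, W = frames.shape
    out = np.full((H, W), np.nan)
    for r in range(H):
        for c in range(W):
            v = frames[:, r, c].astype(float)
            if v.max() == v.min():
                continue
            thr = (1 + pct / 100.0) * v.mean()
            for t in range(T):
                if v[t] >= thr:
                    if t == 0:
                        out[r, c] = 0.0
                    else:
                        out[r, c] = t - 1 + (thr - v[t - 1]) / (v[t] - v[t - 1])
                    break
    return out


class TestActivationMap:
    def test_constant_stack_never_activates(self):
        stack = wg.FrameStack(np.full((20, 8, 8), 5.0), 0.03)
        amap = wg.activation_map(stack)
        assert not amap.finite_mask().any()

    def test_matches_brute_force_scan(self, rng):
        frames = rng.uniform(10, 200, size=(30, 8, 8))
        amap = wg.activation_map(wg.FrameStack(frames, 0.03), threshold_pct=20.0)
        np.testing.assert_allclose(
            amap.activation_time, brute_force_activation(frames, 20.0), atol=1e-9
        )

    def test_recovers_programmed_arrival_times(self):
        """ΔF/F0 + blur + relative threshold lands within 1 frame of the
        simulator's wave arrival for nearly all swept pixels (amp/sigma > 3)."""
        sc = single_wave_scenario(seed=4)
        stack, truth = wg.simulate_movie(sc)
        clean = wg.gaussian_blur(wg.subtract_background(stack), 2.0)
        amap = wg.activation_map(clean)
        true_frames = (truth.stim_onsets_s[0] + truth.arrival_offset_s) / sc.frame_interval_s
        mono = ~wg.DiskRoi(sc.graft_center_row, sc.graft_center_col,
                           sc.graft_radius_px + 1.5).mask(sc.height_px, sc.width_px)
        err = amap.activation_time - true_frames[None, :]
        hit = np.isfinite(err[mono]) & (np.abs(err[mono]) <= 1.0)
        assert hit.mean() >= 0.99

    def test_upstream_before_downstream_before_graft(self):
        """Left-to-right propagation: upstream region activates first, the
        delayed graft last."""
        sc = wg.MovieScenario(height_px=64, width_px=64, n_frames=120,
                              wave_velocity_px_per_frame=2.0, stim_n_pulses=1,
                              stim_t0_s=0.3, stim_period_s=4.0, noise_sigma=10.0,
                              graft_center_row=32, graft_center_col=48, graft_radius_px=4,
                              p_transmit=1.0, delay_s=10 / 34.6, spont_period_s=100.0, seed=2)
        stack, _ = wg.simulate_movie(sc)
        clean = wg.gaussian_blur(wg.subtract_background(stack), 2.0)
        amap = wg.activation_map(clean)
        up = np.nanmedian(amap.activation_time[28:36, 4:12])
        down = np.nanmedian(amap.activation_time[28:36, 56:63])
        graft = np.nanmedian(amap.activation_time[wg.DiskRoi(32, 48, 2.5).mask(64, 64)])
        assert up < down
        assert graft > np.nanmedian(amap.activation_time[28:36, 44:52][
            ~wg.DiskRoi(32, 48, 4.5).mask(64, 64)[28:36, 44:52]])

    def test_empty_window_rejected(self, small_stack):
        with pytest.raises(ValueError):
            wg.activation_map(small_stack, window=(10, 10))


class TestKymograph:
    def test_height_one_region_is_raw_time_series(self, small_stack):
        region = wg.RectRegion(3, 2, 1, 10)
        kymo = wg.reslice_kymograph(small_stack, region)
        np.testing.assert_allclose(kymo.intensity, small_stack.frames[:, 3, 2:12].T)

    def test_height_averaging_reduces_noise_variance(self, rng):
        height = 16
        frames = rng.normal(0, 1, size=(200, 24, 12))
        stack = wg.FrameStack(frames + 10, 0.03)
        kymo = wg.reslice_kymograph(stack, wg.RectRegion(2, 0, height, 12))
        ratio = frames.var() / kymo.intensity.var()
        assert ratio == pytest.approx(height, rel=0.2)

    def test_space_sum_commutes_with_averaging(self, small_stack):
        region = wg.RectRegion(2, 1, 6, 12)
        kymo = wg.reslice_kymograph(small_stack, region)
        block = small_stack.frames[:, 2:8, 1:13]
        np.testing.assert_allclose(
            kymo.intensity.sum(axis=0), block.mean(axis=1).sum(axis=1), rtol=1e-6
        )

    def test_region_outside_image_rejected(self, small_stack):
        with pytest.raises(ValueError):
            wg.reslice_kymograph(small_stack, wg.RectRegion(10, 10, 8, 12))


class TestFitWavefront:
    @pytest.mark.parametrize("velocity", [1.0, 2.0, 4.0])
    def test_recovers_programmed_velocity(self, velocity):
        sc = single_wave_scenario(seed=3, velocity=velocity, noise_sigma=5.0,
                                  n_frames=int(64 / velocity) + 40)
        stack, _ = wg.simulate_movie(sc)
        clean = wg.gaussian_blur(wg.subtract_background(stack), 1.0)
        kymo = wg.reslice_kymograph(clean, wg.RectRegion(5, 0, 10, 64))
        fit = wg.fit_wavefront(kymo)
        assert fit.slope_px_per_frame == pytest.approx(velocity, rel=0.10)
        assert not fit.degenerate
        # calibrated velocity in um/s follows the pixel/frame slope
        expected = velocity * sc.pixel_size_um / sc.frame_interval_s
        assert fit.velocity_um_per_s == pytest.approx(expected, rel=0.10)

    def test_instantaneous_wave_flagged_degenerate(self):
        sc = single_wave_scenario(seed=6, velocity=1000.0, noise_sigma=2.0, n_frames=60)
        stack, _ = wg.simulate_movie(sc)
        clean = wg.subtract_background(stack)
        kymo = wg.reslice_kymograph(clean, wg.RectRegion(5, 0, 10, 64))
        fit = wg.fit_wavefront(kymo)
        assert fit.degenerate
        assert np.isinf(fit.slope_px_per_frame)

    def test_velocity_magnitude_invariant_to_propagation_direction(self):
        forward = single_wave_scenario(seed=8, velocity=2.0, noise_sigma=5.0, n_frames=80)
        backward = replace(forward, wave_velocity_px_per_frame=-2.0, wave_origin_col=63.0)
        fits = []
        for sc in (forward, backward):
            stack, _ = wg.simulate_movie(sc)
            clean = wg.gaussian_blur(wg.subtract_background(stack), 1.0)
            fit = wg.fit_wavefront(wg.reslice_kymograph(clean, wg.RectRegion(5, 0, 10, 64)))
            fits.append(fit.slope_px_per_frame)
        assert fits[0] == pytest.approx(fits[1], rel=0.05)

    def test_flat_kymograph_has_no_front(self):
        kymo = wg.Kymograph(np.full((16, 40), 3.0), 0.03, None, wg.RectRegion(0, 0, 1, 16))
        with pytest.raises(NoWavefrontError):
            wg.fit_wavefront(kymo)


class TestTransmissionDelay:
    def _delay_scenario(self, delay_s: float, seed: int = 7) -> wg.MovieScenario:
        return wg.MovieScenario(height_px=64, width_px=64, n_frames=500,
                                wave_velocity_px_per_frame=4.0, noise_sigma=8.0,
                                stim_n_pulses=12, graft_center_row=20, graft_center_col=40,
                                graft_radius_px=4, p_transmit=1.0, delay_s=delay_s,
                                spont_period_s=100.0, seed=seed)

    def test_zero_delay_recovered(self):
        sc = self._delay_scenario(0.0)
        stack, _ = wg.simulate_movie(sc)
        mono = wg.roi_mean_trace(stack, wg.RectRegion(30, 35, 8, 10))
        graft = wg.roi_mean_trace(stack, sc.graft_roi)
        est = wg.transmission_delay((mono, graft))
        assert abs(est.mean_frames) <= 1.0

    def test_programmed_delay_recovered(self):
        delay = 10 / 34.6
        sc = self._delay_scenario(delay)
        stack, _ = wg.simulate_movie(sc)
        mono = wg.roi_mean_trace(stack, wg.RectRegion(30, 35, 8, 10))
        graft = wg.roi_mean_trace(stack, sc.graft_roi)
        est = wg.transmission_delay((mono, graft))
        assert est.mean_frames == pytest.approx(10.0, abs=1.0)
        assert est.median_frames == pytest.approx(10.0, abs=1.0)

    def test_seconds_and_frames_are_consistent(self):
        est = wg.DelayEstimate(np.array([0.2, 0.3, 0.25]), 0.05)
        np.testing.assert_allclose(est.delays_frames * 0.05, est.delays_s)
        assert est.mean_s == pytest.approx(est.mean_frames * 0.05)


def test_first_crossing_interpolates_linearly():
    values = np.array([[0.0], [1.0], [2.0]])
    t = _first_crossing_times(values, np.array([1.5]))
    assert t[0] == pytest.approx(1.5)
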