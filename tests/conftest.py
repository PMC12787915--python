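import numpy as np
import pytest

import wavegraft as wg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """A 30-frame 16×16 random positive stack at 34.6 fps."""
    frames = rng.uniform(50, 200, size=(30, 16, 16))
    return wg.FrameStack(frames, 1 / 34.6, pixel_size_um=10.0)


def single_wave_scenario(seed: int, velocity: float = 2.0, noise_sigma: float = 20.0,
                         n_frames: int = 80, grid: int = 64) -> wg.MovieScenario:
    """One stimulus sweeping a planar wave across a small grid; inert graft."""
    return wg.MovieScenario(
        height_px=grid, width_px=grid, n_frames=n_frames,
        wave_velocity_px_per_frame=velocity, stim_n_pulses=1, stim_t0_s=0.3,
        stim_period_s=4.0, noise_sigma=noise_sigma,
        graft_center_row=grid // 2, graft_center_col=grid // 2, graft_radius_px=3,
        p_transmit=0.0, spont_period_s=100.0, seed=seed,
    )
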