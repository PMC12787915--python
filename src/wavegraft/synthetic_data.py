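"""Seeded synthetic calcium-imaging data with ground-truth manifests.

The movie generator emulates the statistical structure the analysis assumes:
a confluent monolayer swept by stimulus-locked planar calcium waves at a
known conduction velocity; a spatially distinct graft ROI that follows each
wave with Bernoulli probability ``p_transmit`` after a fixed delay, and
otherwise free-runs on its own jittered pacemaker clock; Gaussian camera
read noise with optional shot noise.  The raster generator emulates a slow
confocal scan of a periodically firing sheet, row by row.

Every simulation is driven by a single integer seed and returns a
GroundTruth answer key (arrival times, transmitted flags, firing times, true
velocity/delay/fraction) so recovery tests can compare against programmed
truth rather than against the pipeline itself.

Calcium transients use a difference-of-exponentials kernel
``K(t) = (1 - e^(-t/τ_rise)) · e^(-t/τ_decay)`` (t >= 0), normalized to unit
peak — the standard minimal transient shape.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .stacks_io import DiskRoi, FrameStack, RasterScanFrame, StimulusTrain, build_stimulus_train

__all__ = [
    "MovieScenario",
    "RasterScenario",
    "GroundTruth",
    "RasterGroundTruth",
    "transient_kernel",
    "simulate_movie",
    "simulate_raster",
    "scenario_presets",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

#: Frame rate of the EMCCD acquisition the movie scenarios emulate.
DEFAULT_FRAME_INTERVAL_S = 1.0 / 34.6


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MovieScenario:
    """Complete parameterization of one synthetic optical-mapping movie."""

    height_px: int = 128
    width_px: int = 128
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    n_frames: int = 1500
    pixel_size_um: float | None = 10.0

    wave_velocity_px_per_frame: float = 4.0
    wave_origin_col: float = 0.0
    stim_period_s: float = 1.0
    stim_pulse_s: float = 0.02
    stim_n_pulses: int = 42
    stim_t0_s: float = 0.5

    amplitude: float = 0.35  # peak ΔF/F0 of a transient
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.3
    baseline_F0: float = 190.0

    graft_center_row: float = 64.0
    graft_center_col: float = 96.0
    graft_radius_px: float = 5.0
    p_transmit: float = 0.5
    delay_s: float = 10.0 * DEFAULT_FRAME_INTERVAL_S
    spont_period_s: float = 2.2
    spont_jitter_s: float = 0.1
    refractory_s: float = 0.25

    noise_sigma: float = 10.0
    shot_noise: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 <= self.p_transmit <= 1:
            raise ValueError("p_transmit must be in [0, 1]")
        for name in ("tau_rise_s", "tau_decay_s", "spont_period_s", "frame_interval_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.wave_velocity_px_per_frame == 0:
            raise ValueError("wave velocity must be nonzero")
        roi = self.graft_roi
        if not (
            roi.radius_px <= roi.center_row <= self.height_px - 1 - roi.radius_px
            and roi.radius_px <= roi.center_col <= self.width_px - 1 - roi.radius_px
        ):
            raise ValueError("graft ROI extends outside the grid")

    @property
    def graft_roi(self) -> DiskRoi:
        return DiskRoi(self.graft_center_row, self.graft_center_col, self.graft_radius_px)

    @property
    def stim(self) -> StimulusTrain:
        return build_stimulus_train(
            self.stim_period_s, self.stim_pulse_s, self.stim_n_pulses, self.stim_t0_s
        )


@dataclass(frozen=True)
class RasterScenario:
    """Parameterization of one synthetic confocal raster-scan frame."""

    sheet_period_s: float = 0.74
    transient_duration_s: float = 0.3
    height_px: int = 1024
    width_px: int = 256
    frame_time_s: float = 36.0
    phase_s: float = 0.2
    amplitude: float = 0.5
    baseline: float = 150.0
    noise_sigma: float = 5.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not self.sheet_period_s > 0:
            raise ValueError("sheet_period_s must be > 0")
        if not 0 < self.transient_duration_s < self.sheet_period_s:
            raise ValueError("need 0 < transient_duration_s < sheet_period_s")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """Answer key for one simulated movie."""

    arrival_offset_s: np.ndarray  # per-column wave travel time from stimulus onset
    stim_onsets_s: np.ndarray
    transmitted: np.ndarray  # bool per stimulus
    graft_fire_times_s: np.ndarray  # all graft firings (transmitted + spontaneous)
    true_velocity_px_per_frame: float
    true_delay_s: float
    seed: int

    @property
    def true_fraction(self) -> float:
        return float(np.mean(self.transmitted))

    @property
    def n_transmitted(self) -> int:
        return int(np.count_nonzero(self.transmitted))

    def arrival_field_s(self, k: int, height_px: int) -> np.ndarray:
        """2D wave-arrival time (s) for stimulus k (planar: constant per column)."""
        row = self.stim_onsets_s[k] + self.arrival_offset_s
        return np.broadcast_to(row, (height_px, row.size)).copy()


@dataclass(frozen=True)
class RasterGroundTruth:
    """Answer key for one simulated raster frame."""

    sheet_period_s: float
    transient_duration_s: float
    expected_band_spacing_px: float
    fire_times_s: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


def transient_kernel(
    t_s: np.ndarray, tau_rise_s: float = 0.05, tau_decay_s: float = 0.3
) -> np.ndarray:
    """Unit-peak calcium transient: (1 - e^(-t/τr)) e^(-t/τd), 0 for t < 0."""
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    raw = (1.0 - np.exp(-tp / tau_rise_s)) * np.exp(-tp / tau_decay_s)
    t_peak = tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)
    peak = (1.0 - np.exp(-t_peak / tau_rise_s)) * np.exp(-t_peak / tau_decay_s)
    out[pos] = raw / peak
    return out


def _kernel_fwhm(tau_rise_s: float, tau_decay_s: float) -> float:
    """Full width at half maximum of the unit-peak transient kernel."""
    t = np.linspace(0, 20 * tau_decay_s, 20_000)
    k = transient_kernel(t, tau_rise_s, tau_decay_s)
    above = np.nonzero(k >= 0.5)[0]
    return float(t[above[-1]] - t[above[0]])


# ---------------------------------------------------------------------------
# Movie simulation
# ---------------------------------------------------------------------------


def _graft_event_times(
    scenario: MovieScenario,
    transmitted_arrivals_s: np.ndarray,
    t_end_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spontaneous pacemaker firings of the graft, with overdrive reset.

    The intrinsic clock runs at ``spont_period_s`` with Gaussian jitter and a
    uniform starting phase; every transmitted wave resets it (the pacemaker
    is overdriven by the driven beat), so a well-coupled graft shows no
    spontaneous beats while an uncoupled one free-runs.
    """
    period = scenario.spont_period_s
    trans = np.sort(transmitted_arrivals_s)
    events: list[float] = []
    t_next = float(rng.uniform(0.0, period))
    ti = 0
    last = -np.inf
    while True:
        t_trans = trans[ti] if ti < trans.size else np.inf
        if t_trans <= t_next:
            # driven beat: reset the clock, do not emit a spontaneous event
            last = t_trans
            t_next = t_trans + period + float(rng.normal(0.0, scenario.spont_jitter_s))
            ti += 1
            continue
        if t_next > t_end_s:
            break
        if t_next - last >= scenario.refractory_s:
            events.append(t_next)
            last = t_next
        t_next = t_next + period + float(rng.normal(0.0, scenario.spont_jitter_s))
    return np.asarray(events)


def simulate_movie(scenario: MovieScenario) -> tuple[FrameStack, GroundTruth]:
    """Render one synthetic optical-mapping movie plus its answer key.

    Monolayer pixel (r, c): ``F = F0 · (1 + A · Σ_k K(t − a_k(c)))`` with
    planar arrival ``a_k(c) = onset_k + (c − origin_col)/v · Δt``.  Graft ROI
    pixels replace the monolayer signal with their own firing times:
    transmitted waves arrive with the programmed delay, spontaneous beats
    come from the jittered pacemaker clock.  Gaussian read noise (and
    optional Poisson shot noise) is added last; all randomness derives from
    the scenario seed.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    dt = sc.frame_interval_s
    t = np.arange(sc.n_frames) * dt
    onsets = sc.stim.onset_times_s
    v = sc.wave_velocity_px_per_frame
    a_col = (np.arange(sc.width_px) - sc.wave_origin_col) / v * dt  # seconds

    # monolayer field depends on (t, col) only — planar wave
    mono = np.zeros((sc.n_frames, sc.width_px))
    for onset in onsets:
        mono += transient_kernel(t[:, None] - onset - a_col[None, :], sc.tau_rise_s, sc.tau_decay_s)
    f_mono = sc.baseline_F0 * (1.0 + sc.amplitude * mono)

    frames = np.broadcast_to(f_mono[:, None, :], (sc.n_frames, sc.height_px, sc.width_px)).copy()

    # graft firing program
    transmitted = rng.random(onsets.size) < sc.p_transmit
    roi = sc.graft_roi
    arrival_center = np.interp(roi.center_col, np.arange(sc.width_px), a_col)
    trans_arrivals = onsets[transmitted] + arrival_center + sc.delay_s
    spont = _graft_event_times(sc, trans_arrivals, t[-1], rng)

    # graft pixels: transmitted firings keep the per-pixel planar arrival
    # (plus delay); spontaneous beats are whole-cell (common-mode)
    g_cols = np.zeros((sc.n_frames, sc.width_px))
    for onset in onsets[transmitted]:
        g_cols += transient_kernel(
            t[:, None] - onset - a_col[None, :] - sc.delay_s, sc.tau_rise_s, sc.tau_decay_s
        )
    g_common = np.zeros(sc.n_frames)
    for e in spont:
        g_common += transient_kernel(t - e, sc.tau_rise_s, sc.tau_decay_s)
    f_graft = sc.baseline_F0 * (1.0 + sc.amplitude * (g_cols + g_common[:, None]))

    mask = roi.mask(sc.height_px, sc.width_px)
    rr, cc = np.nonzero(mask)
    frames[:, rr, cc] = f_graft[:, cc]

    if sc.noise_sigma > 0:
        frames += sc.noise_sigma * rng.standard_normal(frames.shape)
    if sc.shot_noise:
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(np.float64)
    frames = np.clip(frames, 0.0, None).astype(np.float32)

    stack = FrameStack(frames, dt, sc.pixel_size_um)
    truth = GroundTruth(
        arrival_offset_s=a_col,
        stim_onsets_s=onsets,
        transmitted=transmitted,
        graft_fire_times_s=np.sort(np.concatenate([trans_arrivals, spont])),
        true_velocity_px_per_frame=v,
        true_delay_s=sc.delay_s,
        seed=sc.seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Raster simulation
# ---------------------------------------------------------------------------


def simulate_raster(scenario: RasterScenario) -> tuple[RasterScanFrame, RasterGroundTruth]:
    """Render one synthetic confocal raster frame of a firing sheet.

    Row ℓ is sampled at ``phase_s + ℓ · frame_time_s / height_px``.  The
    sheet's fluorescence is a periodic transient (the movie kernel with its
    time axis rescaled so the full width at half maximum equals the stated
    transient duration), so bands appear with row spacing
    ``sheet_period_s · height_px / frame_time_s``.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    tau_r, tau_d = 0.05, 0.3
    scale = sc.transient_duration_s / _kernel_fwhm(tau_r, tau_d)
    line_dt = sc.frame_time_s / sc.height_px
    t_rows = sc.phase_s + np.arange(sc.height_px) * line_dt
    tm = np.mod(t_rows, sc.sheet_period_s)
    # current transient plus the tail of the previous one
    g = transient_kernel(tm / scale, tau_r, tau_d) + transient_kernel(
        (tm + sc.sheet_period_s) / scale, tau_r, tau_d
    )
    rows = sc.baseline * (1.0 + sc.amplitude * g)
    image = np.tile(rows[:, None], (1, sc.width_px))
    if sc.noise_sigma > 0:
        image = image + sc.noise_sigma * rng.standard_normal(image.shape)
    image = np.clip(image, 0.0, None).astype(np.float32)

    n_fires = int(np.ceil((t_rows[-1]) / sc.sheet_period_s)) + 1
    fires = np.arange(n_fires) * sc.sheet_period_s
    truth = RasterGroundTruth(
        sheet_period_s=sc.sheet_period_s,
        transient_duration_s=sc.transient_duration_s,
        expected_band_spacing_px=sc.sheet_period_s * sc.height_px / sc.frame_time_s,
        fire_times_s=fires,
        seed=sc.seed,
    )
    return RasterScanFrame(image, sc.frame_time_s), truth


# ---------------------------------------------------------------------------
# Presets and YAML round-trip
# ---------------------------------------------------------------------------


def scenario_presets(seed: int = 7) -> dict[str, MovieScenario | RasterScenario]:
    """Named study-condition presets.

    - ``paper-like-graft``: 1 Hz × 42 stimuli at 34.6 fps on a 128×128 grid
      (the 512×512 acquisition geometry downscaled 4×), graft transmission
      probability 0.5 with a 10-frame delay.
    - ``perfect-coupling``: every wave transmitted with zero delay.
    - ``uncoupled``: the graft never follows the monolayer; its pacemaker
      free-runs.
    - ``confocal-0.74s``: 1024-row raster frame scanned over 36 s of a sheet
      firing every 0.74 s.
    """
    base = MovieScenario(seed=seed)
    return {
        "paper-like-graft": base,
        "perfect-coupling": replace(
            base, p_transmit=1.0, delay_s=0.0, spont_period_s=5.0, noise_sigma=0.0
        ),
        "uncoupled": replace(base, p_transmit=0.0),
        "confocal-0.74s": RasterScenario(seed=seed),
    }


def scenario_to_yaml(scenario: MovieScenario | RasterScenario) -> str:
    kind = "movie" if isinstance(scenario, MovieScenario) else "raster"
    data = {"kind": kind}
    for f in scenario.__dataclass_fields__:
        data[f] = getattr(scenario, f)
    return yaml.safe_dump(data, sort_keys=False)


def scenario_from_yaml(text: str) -> MovieScenario | RasterScenario:
    data = dict(yaml.safe_load(text))
    kind = data.pop("kind", "movie")
    cls = MovieScenario if kind == "movie" else RasterScenario
    return cls(**data)
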