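"""Activation maps, kymographs, conduction velocity and transmission delay.

The activation map uses a per-pixel *relative* threshold: a pixel counts as
activated at the first time its intensity exceeds its own temporal mean by a
fixed percentage.  Compared with a single absolute threshold this adapts to
heterogeneous staining and illumination across the field of view.

Conduction velocity comes from the kymograph (space×time reslice of the movie
along the propagation direction): a planar wave appears as a tilted bright
line, and with space on the vertical axis and time on the horizontal axis the
line's slope in px/frame is the conduction velocity, i.e. v = tan(α) with α
measured between the wavefront line and the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stacks_io import DiskRoi, FrameStack, RectRegion, StimulusTrain
from .preprocess import Trace, normalize_trace, roi_mean_trace

__all__ = [
    "ActivationMap",
    "Kymograph",
    "WavefrontFit",
    "DelayEstimate",
    "activation_map",
    "reslice_kymograph",
    "fit_wavefront",
    "transmission_delay",
    "NoWavefrontError",
    "NoTransmittedWaveError",
    "DEFAULT_THRESHOLD_PCT",
]

#: Default rise criterion: activation when a pixel exceeds its temporal mean
#: by this percentage.
DEFAULT_THRESHOLD_PCT = 20.0


class NoWavefrontError(ValueError):
    """No wavefront could be extracted from the kymograph."""


class NoTransmittedWaveError(ValueError):
    """No monolayer wave was matched to a graft response."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationMap:
    """Per-pixel first-activation times in (fractional) frames.

    ``activation_time`` holds NaN for pixels that never meet the rise
    criterion within the analyzed window.
    """

    activation_time: np.ndarray
    threshold_pct: float
    window: tuple[int, int]
    frame_interval_s: float

    @property
    def activation_time_s(self) -> np.ndarray:
        return self.activation_time * self.frame_interval_s

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.activation_time)


@dataclass(frozen=True)
class Kymograph:
    """Space×time intensity map, indexed (space_px, time_frame)."""

    intensity: np.ndarray
    frame_interval_s: float
    pixel_size_um: float | None
    source_region: RectRegion

    @property
    def n_space(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]


@dataclass(frozen=True)
class WavefrontFit:
    """Least-squares wavefront line fit on a kymograph.

    ``slope_px_per_frame`` is the conduction velocity in pixels per frame
    (tan of the angle α between the front line and the time axis);
    ``velocity_um_per_s`` is the calibrated velocity when the pixel size is
    known, else None.  An (effectively) instantaneous wave — total traversal
    below one frame — is flagged degenerate with infinite velocity.
    """

    slope_px_per_frame: float
    alpha_deg: float
    velocity_um_per_s: float | None
    fit_residual_frames: float
    n_waves: int
    degenerate: bool = False


@dataclass(frozen=True)
class DelayEstimate:
    """Per-wave monolayer→graft transmission delays with summary statistics.

    The median is the robust headline delay: an intrinsic pacemaker beat that
    happens to land inside a matching window contributes an arbitrary delay,
    which contaminates the mean but not the bulk of the distribution.
    """

    delays_s: np.ndarray
    frame_interval_s: float

    @property
    def n_waves(self) -> int:
        return self.delays_s.size

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.delays_s))

    @property
    def sd_s(self) -> float:
        return float(np.std(self.delays_s, ddof=1)) if self.n_waves > 1 else 0.0

    @property
    def median_s(self) -> float:
        return float(np.median(self.delays_s))

    @property
    def median_frames(self) -> float:
        return self.median_s / self.frame_interval_s

    @property
    def delays_frames(self) -> np.ndarray:
        return self.delays_s / self.frame_interval_s

    @property
    def mean_frames(self) -> float:
        return self.mean_s / self.frame_interval_s

    @property
    def sd_frames(self) -> float:
        return self.sd_s / self.frame_interval_s


# ---------------------------------------------------------------------------
# First-crossing core (shared by activation maps and wavefront extraction)
# ---------------------------------------------------------------------------


def _first_crossing_times(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """First index (fractional, linearly interpolated) where each series
    crosses its threshold.

    ``values`` is (T, ...) and ``thresholds`` broadcasts over the trailing
    axes.  Returns fractional indices relative to the start of ``values``;
    NaN where the threshold is never reached.  Series with zero temporal
    range (constant) never activate.
    """
    values = np.asarray(values, dtype=float)
    above = values >= thresholds
    ever = above.any(axis=0)
    # constant series: no rise, never activated
    flat = values.max(axis=0) == values.min(axis=0)
    ever &= ~flat
    first = above.argmax(axis=0)

    out = np.full(values.shape[1:], np.nan)
    crossed_mid = ever & (first > 0)
    if np.any(crossed_mid):
        idx = first[crossed_mid]
        flat_vals = values.reshape(values.shape[0], -1)
        flat_sel = crossed_mid.ravel()
        cols = np.nonzero(flat_sel)[0]
        cur = flat_vals[idx.ravel(), cols]
        prev = flat_vals[idx.ravel() - 1, cols]
        thr = np.broadcast_to(thresholds, values.shape[1:]).ravel()[cols] if np.ndim(thresholds) else np.full(cols.size, float(thresholds))
        denom = cur - prev
        frac = np.where(denom > 0, (thr - prev) / np.where(denom == 0, 1.0, denom), 0.0)
        out.ravel()[cols] = idx.ravel() - 1 + np.clip(frac, 0.0, 1.0)
    crossed_at_start = ever & (first == 0)
    out[crossed_at_start] = 0.0
    return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def activation_map(
    stack: FrameStack,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    window: tuple[int, int] | None = None,
) -> ActivationMap:
    """Per-pixel first-activation time with the relative-threshold rule.

    A pixel activates at the first frame t in ``window`` (half-open) with
    ``I(t) >= (1 + threshold_pct/100) * mean_t(I)`` where the mean is that
    pixel's temporal mean over the window; the crossing is refined by linear
    interpolation between the straddling frames.  Pixels that never cross are
    NaN.
    """
    if threshold_pct <= 0:
        raise ValueError(f"threshold_pct must be > 0, got {threshold_pct}")
    t0, t1 = window if window is not None else (0, stack.n_frames)
    if not (0 <= t0 < t1 <= stack.n_frames):
        raise ValueError(f"invalid window ({t0}, {t1}) for {stack.n_frames} frames")
    sub = stack.frames[t0:t1].astype(np.float64)
    thr = (1.0 + threshold_pct / 100.0) * sub.mean(axis=0)
    times = _first_crossing_times(sub, thr)
    return ActivationMap(times + t0, threshold_pct, (t0, t1), stack.frame_interval_s)


def reslice_kymograph(stack: FrameStack, region: RectRegion) -> Kymograph:
    """Build a kymograph by reslicing the movie along a rectangle's long axis.

    For each position s along the region's long axis and each frame t, the
    intensity is averaged across the region's short axis (its height),
    yielding a (space, time) map.  Rotated rectangles are sampled bilinearly.
    """
    region.check_inside(stack.height_px, stack.width_px)
    if region.orientation_deg == 0:
        r0, c0 = region.origin_row, region.origin_col
        block = stack.frames[:, r0 : r0 + region.height_px, c0 : c0 + region.width_px]
        kymo = block.astype(np.float64).mean(axis=1).T  # (space, time)
    else:
        rows, cols = region.sample_grid()
        kymo = np.empty((region.width_px, stack.n_frames))
        for t in range(stack.n_frames):
            samp = ndimage.map_coordinates(
                stack.frames[t].astype(np.float64), [rows, cols], order=1
            )
            kymo[:, t] = samp.mean(axis=0)
    return Kymograph(kymo, stack.frame_interval_s, stack.pixel_size_um, region)


def _front_times(
    kymo_block: np.ndarray, threshold_pct: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rising-edge time per spatial row of a kymograph window.

    Returns (positions, fractional frame times) for rows where the relative
    threshold is crossed.
    """
    # rows are spatial positions; time runs along axis 1
    values = kymo_block.T  # (T, space)
    thr = (1.0 + threshold_pct / 100.0) * values.mean(axis=0)
    times = _first_crossing_times(values, thr)
    ok = np.isfinite(times)
    return np.nonzero(ok)[0], times[ok]


def fit_wavefront(
    kymo: Kymograph,
    stim: StimulusTrain | None = None,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    max_residual_frames: float = 3.0,
) -> WavefrontFit:
    """Estimate conduction velocity from wavefront lines in a kymograph.

    Per wavefront (one per stimulus pulse when ``stim`` is given, otherwise a
    single front over the whole record), the rising-edge time at each spatial
    position is detected with the same relative-threshold rule as the
    activation map, and a straight line ``time = s / v + c`` is fitted by
    least squares.  Velocities are averaged across fronts.

    A front whose total traversal across the kymograph is below one frame is
    an (effectively) instantaneous wave: the fit is flagged degenerate and
    the velocity reported as infinite.  A residual above
    ``max_residual_frames`` likewise flags a degenerate fit.
    """
    dt = kymo.frame_interval_s
    if stim is None:
        windows = [(0, kymo.n_frames)]
    else:
        windows = []
        for onset in stim.onset_times_s:
            f0 = int(np.floor(onset / dt))
            f1 = int(np.ceil((onset + stim.period_s) / dt))
            f0, f1 = max(f0, 0), min(f1, kymo.n_frames)
            if f1 - f0 >= 2:
                windows.append((f0, f1))
        if not windows:
            raise NoWavefrontError("no stimulus window overlaps the recording")

    slopes, residuals = [], []
    n_degenerate = 0
    for f0, f1 in windows:
        pos, times = _front_times(kymo.intensity[:, f0:f1], threshold_pct)
        if pos.size < 3:
            continue
        a, b = np.polyfit(pos, times, 1)  # time = a*s + b, a in frames/px
        pred = a * pos + b
        rms = float(np.sqrt(np.mean((times - pred) ** 2)))
        traversal = abs(a) * (kymo.n_space - 1)
        if traversal < 1.0:
            n_degenerate += 1
            slopes.append(np.inf)
        else:
            slopes.append(1.0 / abs(a))
        residuals.append(rms)
    if not slopes:
        raise NoWavefrontError("no detectable wavefront in any window")

    finite = [s for s in slopes if np.isfinite(s)]
    if not finite:  # every front effectively instantaneous
        return WavefrontFit(np.inf, 90.0, None, float(np.mean(residuals)), len(slopes), True)
    v = float(np.mean(finite))
    residual = float(np.mean(residuals))
    degenerate = n_degenerate > 0 or residual > max_residual_frames
    alpha = float(np.degrees(np.arctan(v)))
    vel_um_s = v * kymo.pixel_size_um / dt if kymo.pixel_size_um else None
    return WavefrontFit(v, alpha, vel_um_s, residual, len(slopes), degenerate)


def transmission_delay(
    source: FrameStack | tuple[Trace, Trace],
    monolayer_region: RectRegion | DiskRoi | None = None,
    graft_roi: DiskRoi | None = None,
    window_s: float | None = None,
    min_prominence: float = 0.3,
) -> DelayEstimate:
    """Monolayer→graft transmission delay, per transmitted wave.

    Accepts either a movie plus two ROIs (a monolayer region adjacent to the
    graft, and the graft ROI) or a pre-extracted ``(monolayer, graft)`` trace
    pair.  Waves are the monolayer fluorescence peaks; a wave counts as
    transmitted when a graft peak follows it within ``window_s`` (default
    0.8× the median monolayer period), using the same greedy earliest-first
    matching as the synchronization report.  Each matched pair contributes
    ``delay = graft peak time − monolayer peak time``.
    """
    from .synchrony_efficiency import detect_peaks, match_events

    if isinstance(source, FrameStack):
        if monolayer_region is None or graft_roi is None:
            raise ValueError("movie input needs monolayer_region and graft_roi")
        mono = roi_mean_trace(source, monolayer_region, origin="monolayer")
        graft = roi_mean_trace(source, graft_roi, origin="graft")
    else:
        mono, graft = source

    mono_peaks = detect_peaks(normalize_trace(mono), min_prominence=min_prominence)
    graft_peaks = detect_peaks(normalize_trace(graft), min_prominence=min_prominence)
    if mono_peaks.peak_times_s.size == 0:
        raise NoTransmittedWaveError("no monolayer waves detected")
    if window_s is None:
        if mono_peaks.peak_times_s.size < 2:
            raise ValueError("window_s required when fewer than two monolayer waves")
        window_s = 0.8 * float(np.median(np.diff(mono_peaks.peak_times_s)))
    # a one-frame lower slack keeps instant coupling (true delay 0) matched
    # when quantization or noise nudges the graft peak slightly early
    matches = match_events(
        mono_peaks.peak_times_s,
        graft_peaks.peak_times_s,
        window_s,
        lower_s=-1.5 * mono.frame_interval_s,
    )
    if not matches:
        raise NoTransmittedWaveError("no graft peak matched any monolayer wave")
    delays = np.array([g - r for r, g in matches])
    return DelayEstimate(delays, mono.frame_interval_s)
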