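"""Denoising chain, trace extraction and histogram-band SNR.

The chain mirrors common calcium-imaging practice: a per-pixel temporal
percentile baseline turns raw counts into ΔF/F0, a fixed-gain recursive
(Kalman-type) temporal filter suppresses frame-to-frame read noise, and a 2D
Gaussian blur suppresses spatial noise.  An external denoiser (e.g. a trained
neural network) can be slotted into the same chain as an opaque TIFF→TIFF
command via :func:`run_external_denoiser`.

Signal quality is scored with a histogram-band SNR: the ratio of pixel counts
inside a designated signal-intensity band to counts inside designated noise
bands of the frame's intensity histogram.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stacks_io import DiskRoi, FrameStack, RectRegion, read_stack, write_stack

__all__ = [
    "SnrBands",
    "Trace",
    "DEFAULT_SNR_BANDS",
    "subtract_background",
    "kalman_filter",
    "gaussian_blur",
    "snr_histogram",
    "normalize_trace",
    "roi_mean_trace",
    "run_external_denoiser",
    "EmptyNoiseBandError",
    "ConstantTraceError",
]

BASELINE_EPS = 1e-6


class EmptyNoiseBandError(ValueError):
    """No pixel fell inside any noise band; the SNR ratio is undefined."""


class ConstantTraceError(ValueError):
    """A constant trace cannot be normalized to [0, 1]."""


@dataclass(frozen=True)
class SnrBands:
    """Closed intensity intervals defining histogram signal and noise bands."""

    signal_band: tuple[float, float]
    noise_bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        lo, hi = self.signal_band
        if not lo < hi:
            raise ValueError(f"empty signal band {self.signal_band}")
        for nlo, nhi in self.noise_bands:
            if not nlo < nhi:
                raise ValueError(f"empty noise band ({nlo}, {nhi})")
            if nlo < hi and lo < nhi and not (nhi <= lo or nlo >= hi):
                # closed intervals may share an endpoint but not an interior
                if max(lo, nlo) < min(hi, nhi):
                    raise ValueError("signal band overlaps a noise band")


#: Bands matching the arbitrary-unit intensity scale of EMCCD recordings:
#: signal 230–280, noise 150–230 and 280–400.
DEFAULT_SNR_BANDS = SnrBands((230.0, 280.0), ((150.0, 230.0), (280.0, 400.0)))


@dataclass(frozen=True)
class Trace:
    """A 1D fluorescence time series extracted from an ROI."""

    values: np.ndarray
    frame_interval_s: float
    origin: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("trace must be a non-empty 1D series")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace contains non-finite values")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        object.__setattr__(self, "values", values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval_s


# ---------------------------------------------------------------------------
# Denoising chain
# ---------------------------------------------------------------------------


def subtract_background(stack: FrameStack, baseline_percentile: float = 10.0) -> FrameStack:
    """Per-pixel ΔF/F0 conversion against a temporal-percentile baseline.

    For every pixel, F0 is its own temporal ``baseline_percentile`` over the
    movie and the output is ``(F - F0) / F0``.  The output stack is
    dimensionless; pixels below their baseline go negative.  A pixel whose
    baseline is at or below the epsilon guard keeps the raw difference
    (denominator 1) rather than exploding — so an all-zero pixel yields 0,
    never an exception, and re-applying the operation to a stack whose
    baseline is already 0 is the identity.
    """
    if stack.n_frames < 5:
        raise ValueError(f"need >= 5 frames to estimate a baseline, got {stack.n_frames}")
    if not 0 <= baseline_percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {baseline_percentile}")
    frames = stack.frames.astype(np.float64)
    f0 = np.percentile(frames, baseline_percentile, axis=0)
    denom = np.where(f0 > BASELINE_EPS, f0, 1.0)
    out = (frames - f0) / denom
    return stack.with_frames(out)


def kalman_filter(stack: FrameStack, gain: float = 0.8) -> FrameStack:
    """Fixed-gain recursive temporal filter (Kalman stack filter).

    Causal per-pixel recursion ``E_0 = X_0``, ``E_t = g·E_{t-1} + (1-g)·X_t``
    with gain g in [0, 1).  Gain 0 is the identity; larger gains trade
    temporal resolution for noise suppression (steady-state variance of
    i.i.d. noise is reduced by the factor (1-g)/(1+g)).
    """
    if not 0 <= gain < 1:
        raise ValueError(f"gain must be in [0, 1), got {gain}")
    if stack.n_frames < 2:
        raise ValueError("need >= 2 frames to filter temporally")
    x = stack.frames.astype(np.float64)
    out = np.empty_like(x)
    out[0] = x[0]
    for t in range(1, x.shape[0]):
        out[t] = gain * out[t - 1] + (1.0 - gain) * x[t]
    return stack.with_frames(out)


def gaussian_blur(stack: FrameStack, sigma_px: float = 2.0) -> FrameStack:
    """Per-frame isotropic 2D Gaussian blur with reflective boundaries.

    Sigma 0 is the identity.  The reflective boundary conserves per-frame
    total intensity.
    """
    if sigma_px < 0:
        raise ValueError(f"sigma_px must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return stack.with_frames(stack.frames.astype(np.float64))
    out = ndimage.gaussian_filter(
        stack.frames.astype(np.float64), sigma=(0.0, sigma_px, sigma_px), mode="reflect"
    )
    return stack.with_frames(out)


def run_external_denoiser(stack: FrameStack, command: list[str]) -> FrameStack:
    """Run an opaque external TIFF→TIFF denoiser over the stack.

    ``command`` is a argv list in which the placeholders ``{in}`` and
    ``{out}`` are replaced by temporary input/output TIFF paths.  The tool's
    output is read back with the input stack's calibration.  This is the
    plug-in point for learned denoisers trained outside this package.
    """
    with tempfile.TemporaryDirectory() as tmp:
        src = Path(tmp) / "in.tif"
        dst = Path(tmp) / "out.tif"
        write_stack(stack, src)
        argv = [a.replace("{in}", str(src)).replace("{out}", str(dst)) for a in command]
        subprocess.run(argv, check=True)
        return read_stack(dst, {"frame_interval_s": stack.frame_interval_s,
                                "pixel_size_um": stack.pixel_size_um})


# ---------------------------------------------------------------------------
# Quality metrics and traces
# ---------------------------------------------------------------------------


def snr_histogram(frame: np.ndarray, bands: SnrBands = DEFAULT_SNR_BANDS) -> float:
    """Histogram-band SNR of one frame.

    Counts the pixels whose intensity falls in the (closed) signal band and
    divides by the count in the union of the noise bands.  Raises
    :class:`EmptyNoiseBandError` when no pixel falls in any noise band.
    """
    frame = np.asarray(frame, dtype=float)
    lo, hi = bands.signal_band
    n_signal = int(np.count_nonzero((frame >= lo) & (frame <= hi)))
    noise_mask = np.zeros(frame.shape, dtype=bool)
    for nlo, nhi in bands.noise_bands:
        noise_mask |= (frame >= nlo) & (frame <= nhi)
    n_noise = int(np.count_nonzero(noise_mask))
    if n_noise == 0:
        raise EmptyNoiseBandError("no pixels in any noise band; SNR undefined")
    return n_signal / n_noise


def normalize_trace(trace: Trace) -> Trace:
    """Affine rescale of a trace to [0, 1] (min → 0, max → 1)."""
    lo = trace.values.min()
    hi = trace.values.max()
    if hi == lo:
        raise ConstantTraceError("constant trace cannot be normalized")
    return Trace((trace.values - lo) / (hi - lo), trace.frame_interval_s, trace.origin)


def roi_mean_trace(stack: FrameStack, roi: DiskRoi | RectRegion, origin: str = "") -> Trace:
    """Mean-intensity time series over an ROI (disk or rectangle)."""
    if isinstance(roi, DiskRoi):
        mask = roi.mask(stack.height_px, stack.width_px)
        if not mask.any():
            raise ValueError("ROI covers no pixels")
        values = stack.frames[:, mask].mean(axis=1)
    else:
        roi.check_inside(stack.height_px, stack.width_px)
        if roi.orientation_deg == 0:
            r0, c0 = roi.origin_row, roi.origin_col
            values = stack.frames[:, r0 : r0 + roi.height_px, c0 : c0 + roi.width_px].mean(axis=(1, 2))
        else:
            rows, cols = roi.sample_grid()
            values = np.array(
                [
                    ndimage.map_coordinates(f.astype(float), [rows, cols], order=1).mean()
                    for f in stack.frames
                ]
            )
    return Trace(np.asarray(values, dtype=float), stack.frame_interval_s, origin)
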