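"""Temporal decoding of single confocal raster-scan frames.

A slow raster scan of a periodically firing cell sheet converts time into
vertical position: each of the H rows is acquired ``frame_time/H`` seconds
after the previous one, so a sheet that lights up every T seconds paints
horizontal bright bands ``T·H/frame_time`` rows apart.  Reading the band
spacing (and band width) off the image therefore decodes the firing period
(and the calcium-transient duration) from a single frame — e.g. a 21-pixel
band spacing in a 1024-row frame scanned over 36 s decodes to a 0.74 s
period.

Within-row acquisition time is ignored (a row is treated as an instant);
the per-pixel dwell correction is below one line time and is a documented
approximation of this calculus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .stacks_io import RasterScanFrame, RectRegion

__all__ = [
    "BandSet",
    "DecodedTime",
    "Commensurability",
    "side_projection",
    "detect_bands",
    "line_time",
    "decode_period",
    "decode_duration",
    "decode_frame",
    "check_commensurability",
]


@dataclass(frozen=True)
class BandSet:
    """Bright fluorescence bands found in a side-projection profile."""

    band_centers_px: np.ndarray
    band_widths_px: np.ndarray
    projection: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.band_centers_px, dtype=float)
        w = np.asarray(self.band_widths_px, dtype=float)
        if c.shape != w.shape or c.ndim != 1:
            raise ValueError("centers and widths must be matching 1D arrays")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(w <= 0):
            raise ValueError("band widths must be positive")
        object.__setattr__(self, "band_centers_px", c)
        object.__setattr__(self, "band_widths_px", w)

    @property
    def spacings_px(self) -> np.ndarray:
        return np.diff(self.band_centers_px)


class DecodedTime(NamedTuple):
    """Full-precision decoded time plus its conventionally rounded report value."""

    value_s: float
    rounded_s: float


@dataclass(frozen=True)
class Commensurability:
    """Verdict on whether the scan time is an integer multiple of the
    stimulation period (the condition for vertically aligned bands)."""

    aligned: bool
    nearest_multiple: int
    residual: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def side_projection(frame: RasterScanFrame, region: RectRegion | None = None) -> np.ndarray:
    """Row-wise mean intensity over a rectangular region (whole frame if None).

    Returns one value per row of the region — the averaged side-projection in
    which periodic firing shows up as peaks.
    """
    if region is None:
        return frame.image.astype(float).mean(axis=1)
    region.check_inside(frame.height_px, frame.width_px)
    r0, c0 = region.origin_row, region.origin_col
    block = frame.image[r0 : r0 + region.height_px, c0 : c0 + region.width_px]
    return block.astype(float).mean(axis=1)


def detect_bands(
    profile: np.ndarray, min_prominence: float = 0.3, subpixel: bool = True
) -> BandSet:
    """Find fluorescence bands in a side-projection profile.

    Local maxima with prominence >= ``min_prominence`` (fraction of the
    profile's range) become band centers; centers are refined to sub-pixel
    precision by a parabolic fit through the peak and its neighbours unless
    ``subpixel=False`` (integer-pixel reading as from an on-screen cursor).
    Band widths are measured at half prominence.  An empty band set is valid.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile must have length >= 3")
    span = profile.max() - profile.min()
    if span == 0:
        return BandSet(np.empty(0), np.empty(0), profile)
    idx, _ = find_peaks(profile, prominence=min_prominence * span)
    if idx.size == 0:
        return BandSet(np.empty(0), np.empty(0), profile)
    widths = peak_widths(profile, idx, rel_height=0.5)[0]
    centers = idx.astype(float)
    if subpixel:
        for k, p in enumerate(idx):
            if 0 < p < profile.size - 1:
                y0, y1, y2 = profile[p - 1], profile[p], profile[p + 1]
                denom = y0 - 2 * y1 + y2
                if denom < 0:
                    centers[k] = p + 0.5 * (y0 - y2) / denom
    return BandSet(centers, widths, profile)


def line_time(frame: RasterScanFrame) -> float:
    """Seconds to acquire one scan line: ``frame_time_s / height_px``.

    Row ℓ (0-based, top to bottom) is treated as acquired instantaneously at
    ``ℓ · line_time``.
    """
    return frame.frame_time_s / frame.height_px


def decode_period(band_spacing_px: float, frame: RasterScanFrame) -> DecodedTime:
    """Firing period from the row spacing of adjacent bands.

    ``period = spacing × line_time``; the report value is rounded to 2
    decimals (21 px in a 1024-row, 36 s frame → 0.7383 s, reported 0.74 s).
    """
    if band_spacing_px < 0:
        raise ValueError(f"band spacing must be >= 0, got {band_spacing_px}")
    value = band_spacing_px * line_time(frame)
    return DecodedTime(value, round(value, 2))


def decode_duration(band_width_px: float, frame: RasterScanFrame) -> DecodedTime:
    """Calcium-transient duration from a band's row width.

    ``duration = width × line_time``; the report value is rounded to 1
    decimal (29 px in a 1024-row, 36 s frame → 1.0195 s, reported 1.0 s).
    """
    if not band_width_px > 0:
        raise ValueError(f"band width must be > 0, got {band_width_px}")
    value = band_width_px * line_time(frame)
    return DecodedTime(value, round(value, 1))


def decode_frame(
    frame: RasterScanFrame,
    region: RectRegion | None = None,
    min_prominence: float = 0.3,
    subpixel: bool = True,
) -> dict:
    """Full single-frame decoding: projection → bands → period & duration.

    The period is the median over all adjacent band spacings; the duration is
    the median band width.  Returns a dict with the band set and the decoded
    times (full precision and rounded).
    """
    profile = side_projection(frame, region)
    bands = detect_bands(profile, min_prominence, subpixel)
    out: dict = {"bands": bands, "period": None, "duration": None}
    if bands.band_centers_px.size >= 2:
        spacing = float(np.median(bands.spacings_px))
        out["period"] = decode_period(spacing, frame)
    if bands.band_widths_px.size >= 1:
        width = float(np.median(bands.band_widths_px))
        out["duration"] = decode_duration(width, frame)
    return out


def check_commensurability(t1_s: float, t2_s: float, tol: float = 0.01) -> Commensurability:
    """Is the frame scan time t₂ an integer multiple of the stimulation
    period t₁?

    When it is, successive frames sample the firing cycle at the same phases
    and the raster bands align vertically across frames; otherwise the band
    pattern drifts and is disordered.  Aligned iff
    ``|t2/t1 − round(t2/t1)| ≤ tol · round(t2/t1)`` with the multiple ≥ 1.
    """
    if not (t1_s > 0 and t2_s > 0):
        raise ValueError("both periods must be positive")
    ratio = t2_s / t1_s
    nearest = int(round(ratio))
    residual = abs(ratio - nearest)
    aligned = nearest >= 1 and residual <= tol * nearest
    return Commensurability(aligned, max(nearest, 1), residual)
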