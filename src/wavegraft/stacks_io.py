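"""Image-stack I/O and the core movie data model.

Fluorescence movies are handled as :class:`FrameStack` objects — a time-ordered
3D grid of intensities with the acquisition metadata (frame interval, optional
pixel size) that every downstream calculation needs.  Movies travel on disk as
multi-page grayscale TIFF plus a JSON sidecar holding the metadata, because
microscope-specific TIFF tags are not portable.

Coordinate convention, fixed once for the whole package: arrays are indexed
``(t, row, col)``, 0-based, row 0 at the image top, half-open ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FrameStack",
    "RasterScanFrame",
    "StimulusTrain",
    "RectRegion",
    "DiskRoi",
    "StackIOError",
    "MissingStackError",
    "NotGrayscaleError",
    "BadMetadataError",
    "read_stack",
    "write_stack",
    "build_stimulus_train",
    "sidecar_path",
]

TOOL_VERSION = "0.1.0"


class StackIOError(Exception):
    """Base class for stack I/O failures."""


class MissingStackError(StackIOError, FileNotFoundError):
    """The stack file does not exist or is unreadable."""


class NotGrayscaleError(StackIOError, ValueError):
    """The TIFF pages are not single-channel grayscale of one common shape."""


class BadMetadataError(StackIOError, ValueError):
    """Acquisition metadata is missing or invalid (e.g. frame interval <= 0)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameStack:
    """Time-ordered 2D intensity frames with acquisition calibration.

    Parameters
    ----------
    frames
        3D array indexed ``(t, row, col)``; arbitrary intensity units.  Raw
        acquisitions are non-negative integers; derived stacks (ΔF/F0) are
        floating point and may be negative.
    frame_interval_s
        Seconds between successive frames (> 0).
    pixel_size_um
        Micrometers per pixel, or ``None`` when the recording is uncalibrated
        (downstream velocities are then reported in px/frame only).
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise BadMetadataError(
                f"frames must be a (t, row, col) array with >= 1 frame, got shape {frames.shape}"
            )
        if not self.frame_interval_s > 0:
            raise BadMetadataError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise BadMetadataError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if np.issubdtype(frames.dtype, np.floating) and not np.all(np.isfinite(frames)):
            raise BadMetadataError("frames contain non-finite values")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """A copy of this stack carrying new pixel data, same calibration."""
        return FrameStack(frames, self.frame_interval_s, self.pixel_size_um)


@dataclass(frozen=True)
class RasterScanFrame:
    """A single confocal raster-scan frame.

    The scanner acquires rows top-to-bottom over ``frame_time_s`` seconds, so
    a row's vertical position doubles as a time stamp — the basis of the
    line-scan temporal decoding in :mod:`wavegraft.confocal_decode`.
    """

    image: np.ndarray
    frame_time_s: float

    def __post_init__(self) -> None:
        image = np.asarray(self.image)
        if image.ndim != 2 or image.shape[0] < 2:
            raise BadMetadataError(
                f"image must be 2D with >= 2 rows, got shape {image.shape}"
            )
        if not self.frame_time_s > 0:
            raise BadMetadataError(f"frame_time_s must be > 0, got {self.frame_time_s}")
        object.__setattr__(self, "image", image)

    @property
    def height_px(self) -> int:
        return self.image.shape[0]

    @property
    def width_px(self) -> int:
        return self.image.shape[1]


@dataclass(frozen=True)
class StimulusTrain:
    """Field-stimulation pulse train (onsets in seconds)."""

    onset_times_s: np.ndarray
    pulse_duration_s: float
    period_s: float
    amplitude_V: float | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times_s, dtype=float)
        if onsets.ndim != 1 or onsets.size < 1:
            raise BadMetadataError("onset_times_s must be a non-empty 1D sequence")
        if np.any(np.diff(onsets) <= 0):
            raise BadMetadataError("onset times must be strictly increasing")
        if not (self.period_s > self.pulse_duration_s > 0):
            raise BadMetadataError(
                f"need period_s > pulse_duration_s > 0, got {self.period_s}, {self.pulse_duration_s}"
            )
        object.__setattr__(self, "onset_times_s", onsets)

    @property
    def n_pulses(self) -> int:
        return self.onset_times_s.size


@dataclass(frozen=True)
class RectRegion:
    """Axis-anchored rectangular ROI, optionally rotated.

    ``width_px`` measures extent along the rectangle's long axis and
    ``height_px`` across it.  ``orientation_deg`` is the angle of the long
    axis relative to image columns (0 = long axis runs left→right).
    """

    origin_row: int
    origin_col: int
    height_px: int
    width_px: int
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 2:
            raise ValueError("need height_px >= 1 and width_px >= 2")

    def sample_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) sample coordinates, each shaped (height_px, width_px).

        Axis order: first axis walks the short axis, second the long axis.
        """
        theta = np.deg2rad(self.orientation_deg)
        # unit vector along the long axis, and its in-plane normal
        u = np.array([np.sin(theta), np.cos(theta)])
        n = np.array([np.cos(theta), -np.sin(theta)])
        s = np.arange(self.width_px)
        h = np.arange(self.height_px)
        rows = self.origin_row + h[:, None] * n[0] + s[None, :] * u[0]
        cols = self.origin_col + h[:, None] * n[1] + s[None, :] * u[1]
        return rows, cols

    def check_inside(self, height_px: int, width_px: int) -> None:
        rows, cols = self.sample_grid()
        if rows.min() < 0 or cols.min() < 0 or rows.max() > height_px - 1 or cols.max() > width_px - 1:
            raise ValueError(
                f"region extends outside the {height_px}x{width_px} image "
                f"(rows {rows.min():.1f}..{rows.max():.1f}, cols {cols.min():.1f}..{cols.max():.1f})"
            )


@dataclass(frozen=True)
class DiskRoi:
    """Circular ROI (e.g. the graft cell on its fiber)."""

    center_row: float
    center_col: float
    radius_px: float

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ValueError("radius_px must be > 0")

    def mask(self, height_px: int, width_px: int) -> np.ndarray:
        rr, cc = np.ogrid[:height_px, :width_px]
        return (rr - self.center_row) ** 2 + (cc - self.center_col) ** 2 <= self.radius_px**2


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def sidecar_path(path: str | Path) -> Path:
    """Location of the JSON metadata sidecar for a TIFF stack."""
    return Path(str(path) + ".json")


def read_stack(path: str | Path, meta: dict | None = None) -> FrameStack:
    """Read a multi-page grayscale TIFF into a :class:`FrameStack`.

    Intensities are preserved bit-exactly (the stored dtype is kept).
    Metadata comes from ``meta`` if given, else from the JSON sidecar written
    by :func:`write_stack`.  ``meta`` must supply ``frame_interval_s`` and may
    supply ``pixel_size_um``.
    """
    path = Path(path)
    if not path.is_file():
        raise MissingStackError(f"no such stack file: {path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:  # single-page file
        frames = frames[None, :, :]
    if frames.ndim != 3:
        raise NotGrayscaleError(
            f"expected single-channel grayscale pages, got array of shape {frames.shape}"
        )
    if meta is None:
        sc = sidecar_path(path)
        if not sc.is_file():
            raise BadMetadataError(f"no metadata given and no sidecar at {sc}")
        meta = json.loads(sc.read_text())
    if "frame_interval_s" not in meta:
        raise BadMetadataError("metadata must supply frame_interval_s")
    interval = float(meta["frame_interval_s"])
    if not interval > 0:
        raise BadMetadataError(f"frame_interval_s must be > 0, got {interval}")
    pixel_size = meta.get("pixel_size_um")
    pixel_size = float(pixel_size) if pixel_size is not None else None
    return FrameStack(frames, interval, pixel_size)


def write_stack(stack: FrameStack, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write a stack as multi-page TIFF with a JSON metadata sidecar.

    Integer stacks are stored at their native bit depth; floating-point
    derived maps (ΔF/F0 and friends) are stored as 32-bit float TIFF, never
    clipped or rescaled.  ``extra_meta`` entries (e.g. a generator seed) are
    merged into the sidecar for provenance.
    """
    path = Path(path)
    frames = stack.frames
    if np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float32)
    try:
        tifffile.imwrite(path, frames, photometric="minisblack")
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise StackIOError(f"cannot write stack to {path}: {exc}") from exc
    meta = {
        "frame_interval_s": stack.frame_interval_s,
        "pixel_size_um": stack.pixel_size_um,
        "n_frames": stack.n_frames,
        "height_px": stack.height_px,
        "width_px": stack.width_px,
        "tool_version": TOOL_VERSION,
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def build_stimulus_train(
    period_s: float,
    pulse_duration_s: float,
    n_pulses: int,
    t0_s: float = 0.0,
    amplitude_V: float | None = None,
) -> StimulusTrain:
    """Regular pulse train: onsets at ``t0_s + k * period_s``, k = 0..n-1."""
    if n_pulses < 1:
        raise BadMetadataError(f"n_pulses must be >= 1, got {n_pulses}")
    if not (period_s > pulse_duration_s > 0):
        raise BadMetadataError(
            f"need period_s > pulse_duration_s > 0, got {period_s}, {pulse_duration_s}"
        )
    onsets = t0_s + period_s * np.arange(n_pulses, dtype=float)
    return StimulusTrain(onsets, pulse_duration_s, period_s, amplitude_V)
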