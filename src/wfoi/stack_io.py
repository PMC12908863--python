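"""Reading, demultiplexing and normalising interleaved image stacks.

A wide-field session is recorded as one interleaved monochrome stack in
which successive frames cycle through the LED sequence (for example
470 -> 530 -> 470 -> 656 nm).  The operations here split that stack into
per-channel series, subtract the camera dark signal, convert counts to
relative intensity I/I0 against a baseline, and apply block binning.

Axis convention: all stacks are ``(t, row, col)`` row-major arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError, InvalidArgumentError

__all__ = [
    "Channel",
    "ChannelSequence",
    "FrameStack",
    "RelativeStack",
    "read_stack",
    "write_stack",
    "demultiplex",
    "subtract_dark",
    "relative_series",
    "bin_stack",
    "DroppedFrameWarning",
    "SuspiciousDarkWarning",
]


class DroppedFrameWarning(UserWarning):
    """Timestamp gaps suggest frames were dropped during acquisition."""


class SuspiciousDarkWarning(UserWarning):
    """Dark level exceeds the stack median; check channel assignment."""


@dataclass(frozen=True)
class Channel:
    """One slot of the LED cycle."""

    label: str
    wavelength_nm: float
    role: str = "reflectance"  # or "fluorescence-excitation"

    def __post_init__(self):
        if self.role not in ("reflectance", "fluorescence-excitation"):
            raise InvalidArgumentError(f"unknown channel role {self.role!r}")


@dataclass(frozen=True)
class ChannelSequence:
    """Ordered LED cycle; a label may repeat (e.g. 470 twice per cycle)."""

    channels: tuple

    def __post_init__(self):
        chans = tuple(self.channels)
        if len(chans) == 0:
            raise InvalidArgumentError("channel sequence must be non-empty")
        object.__setattr__(self, "channels", chans)

    def __len__(self):
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    @classmethod
    def from_config(cls, entries) -> "ChannelSequence":
        """Build from a list of ``{label, wavelength_nm, role}`` mappings."""
        return cls(tuple(
            Channel(e["label"], float(e["wavelength_nm"]),
                    e.get("role", "reflectance"))
            for e in entries
        ))


@dataclass
class FrameStack:
    """Time series of frames for one channel.

    ``data`` is ``(t, h, w)`` detector counts (or corrected counts);
    ``timestamps`` are seconds, strictly increasing.
    """

    data: np.ndarray
    timestamps: np.ndarray
    channel: Channel | None = None
    frame_indices: np.ndarray | None = None  # positions in the raw stack

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"stack must be (t, h, w), got shape {self.data.shape}")
        if len(self.timestamps) != len(self.data):
            raise FormatError("one timestamp per frame required")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class RelativeStack:
    """Dimensionless I/I0 stack with its baseline image and definition."""

    ratios: np.ndarray
    timestamps: np.ndarray
    baseline_image: np.ndarray
    baseline_descriptor: str
    channel: Channel | None = None
    invalid_mask: np.ndarray | None = None  # pixels with non-positive baseline


def read_stack(paths, frame_rate_hz: float | None = None):
    """Read one or more multi-page TIFFs into a single ``(t, h, w)`` array.

    Files are concatenated in the order given.  Timestamps are synthesised
    from ``frame_rate_hz`` (frame i at ``i / rate``); if omitted, unit
    spacing is used.

    Returns ``(frames, timestamps)``.
    """
    arrays = []
    shape = None
    for p in paths if isinstance(paths, (list, tuple)) else [paths]:
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"{p}: expected 2-D or 3-D TIFF, got ndim={arr.ndim}")
        if shape is None:
            shape = arr.shape[1:]
        elif arr.shape[1:] != shape:
            raise FormatError(
                f"{p}: frame shape {arr.shape[1:]} differs from {shape}")
        arrays.append(arr)
    frames = np.concatenate(arrays, axis=0)
    dt = 1.0 / frame_rate_hz if frame_rate_hz else 1.0
    timestamps = np.arange(frames.shape[0]) * dt
    return frames, timestamps


def write_stack(path, frames) -> None:
    """Write a ``(t, h, w)`` array as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(frames), photometric="minisblack")


def demultiplex(frames, timestamps, sequence: ChannelSequence,
                start_offset: int = 0,
                gap_factor: float = 1.5) -> list[FrameStack]:
    """Split an interleaved stack into one :class:`FrameStack` per cycle slot.

    Frame ``i`` of the raw stack is assigned to cycle position
    ``(i + start_offset) % len(sequence)``.  Returns stacks in cycle order;
    each keeps its raw frame indices so bookkeeping can be audited.  A
    timestamp gap exceeding ``gap_factor`` times the median frame interval
    raises a :class:`DroppedFrameWarning` naming the offending indices.
    """
    frames = np.asarray(frames)
    timestamps = np.asarray(timestamps, dtype=float)
    L = len(sequence)
    if frames.ndim != 3:
        raise FormatError(f"frames must be (t, h, w), got {frames.shape}")
    if len(timestamps) != len(frames):
        raise FormatError("one timestamp per frame required")

    if len(timestamps) > 2:
        dts = np.diff(timestamps)
        med = np.median(dts)
        bad = np.where(dts > gap_factor * med)[0]
        if bad.size:
            warnings.warn(
                f"timestamp gaps at frame indices {bad.tolist()} exceed "
                f"{gap_factor} x median interval; frames may have been dropped",
                DroppedFrameWarning,
            )

    out = []
    for pos, chan in enumerate(sequence):
        idx = np.arange(len(frames))[(np.arange(len(frames)) + start_offset) % L == pos]
        out.append(FrameStack(frames[idx], timestamps[idx], channel=chan,
                              frame_indices=idx))
    assert sum(s.n_frames for s in out) == len(frames)
    return out


def subtract_dark(stack: FrameStack, dark, floor: float = 1.0) -> FrameStack:
    """Subtract the camera dark signal, clipping at a small positive floor.

    ``dark`` is a per-channel scalar or an image matching the frame shape.
    The floor (default 1 count) keeps downstream ratios and logarithms
    defined.
    """
    dark_arr = np.asarray(dark, dtype=float)
    if dark_arr.ndim not in (0, 2):
        raise FormatError("dark must be a scalar or a single image")
    if dark_arr.ndim == 2 and dark_arr.shape != stack.data.shape[1:]:
        raise FormatError(
            f"dark image shape {dark_arr.shape} != frame shape {stack.data.shape[1:]}")
    med = float(np.median(stack.data))
    if np.any(dark_arr > med):
        warnings.warn(
            f"dark level exceeds the stack median ({med:g}); "
            "check channel assignment or dark calibration",
            SuspiciousDarkWarning,
        )
    corrected = np.maximum(stack.data.astype(float) - dark_arr, floor)
    return FrameStack(corrected, stack.timestamps, channel=stack.channel,
                      frame_indices=stack.frame_indices)


def relative_series(stack: FrameStack, baseline="full-mean") -> RelativeStack:
    """Convert counts to relative intensity I/I0.

    ``baseline`` is ``"full-mean"`` (I0 = temporal mean over the whole
    record, per pixel) or a ``(t0, t1)`` window in seconds (I0 = mean over
    frames with t0 <= t < t1).  Pixels with non-positive baseline are
    reported in ``invalid_mask`` and set to NaN rather than silently
    propagated.
    """
    data = stack.data.astype(float)
    if baseline == "full-mean":
        i0 = data.mean(axis=0)
        desc = "full-mean"
    else:
        t0, t1 = float(baseline[0]), float(baseline[1])
        sel = (stack.timestamps >= t0) & (stack.timestamps < t1)
        if not np.any(sel):
            raise InvalidArgumentError(
                f"baseline window [{t0}, {t1}) s selects no frames")
        i0 = data[sel].mean(axis=0)
        desc = f"window[{t0},{t1})"
    invalid = ~(i0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = data / i0
    if np.any(invalid):
        ratios[:, invalid] = np.nan
    return RelativeStack(ratios, stack.timestamps, i0, desc,
                         channel=stack.channel,
                         invalid_mask=invalid if np.any(invalid) else None)


def bin_stack(stack: FrameStack, spatial_factor: int = 1,
              temporal_factor: int = 1) -> FrameStack:
    """Non-overlapping block-mean binning in space and/or time.

    Trailing partial blocks are dropped; timestamps are averaged per
    temporal block.
    """
    sf, tf = int(spatial_factor), int(temporal_factor)
    t, h, w = stack.data.shape
    if sf < 1 or tf < 1:
        raise InvalidArgumentError("binning factors must be >= 1")
    if sf > min(h, w) or tf > t:
        raise InvalidArgumentError(
            f"binning factors ({sf}, {tf}) exceed stack dimensions {stack.data.shape}")
    nt, nh, nw = t // tf, h // sf, w // sf
    d = stack.data[: nt * tf, : nh * sf, : nw * sf].astype(float)
    d = d.reshape(nt, tf, nh, sf, nw, sf).mean(axis=(1, 3, 5))
    ts = stack.timestamps[: nt * tf].reshape(nt, tf).mean(axis=1)
    return FrameStack(d, ts, channel=stack.channel)
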