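"""Preprocessing: band-pass filtering, channel rejection, windowing, resampling.

The pipeline mirrors common practice for continuous intracranial recordings:
a zero-phase Butterworth band-pass (0.5-45 Hz, order 3 by default), removal
of channels whose peak absolute amplitude exceeds a threshold, segmentation
into fixed-length sliding windows (3 s length, 1 s stride by default) that
never span two source files, and anti-aliased polyphase resampling used to
bring the signal to the rate at which symbolic connectivity is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "PreprocessConfig",
    "WindowedSeries",
    "bandpass",
    "reject_channels",
    "window",
    "window_count",
    "downsample",
]

logger = logging.getLogger(__name__)


class InvalidConfigError(ValueError):
    """Raised when a configuration is inconsistent with the recording."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering / rejection / segmentation parameters.

    Defaults: 0.5-45 Hz third-order Butterworth band-pass, 200 (header-unit)
    amplitude rejection threshold, 3-s windows with 1-s stride, and 200 Hz
    as the working rate for symbolic (ordinal-pattern) connectivity.
    """

    f_low: float = 0.5
    f_high: float = 45.0
    filter_order: int = 3
    amp_threshold: float = 200.0
    window_s: float = 3.0
    stride_s: float = 1.0
    wsmi_fs: float = 200.0

    def validate(self, fs: float) -> None:
        if not (0 < self.f_low < self.f_high):
            raise InvalidConfigError(
                f"need 0 < f_low < f_high, got ({self.f_low}, {self.f_high})"
            )
        if self.f_high >= fs / 2:
            raise InvalidConfigError(
                f"f_high={self.f_high} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        if not (self.window_s >= self.stride_s > 0):
            raise InvalidConfigError(
                f"need window_s >= stride_s > 0, got ({self.window_s}, {self.stride_s})"
            )


@dataclass
class WindowedSeries:
    """Ordered fixed-length windows cut from one source file.

    ``starts`` are absolute wall-clock timestamps; ``blocks[i]`` is the
    channels x window_samples array starting at ``starts[i]``.
    """

    starts: list[datetime]
    blocks: list[np.ndarray]
    fs: float
    source_file: str | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(zip(self.starts, self.blocks))


def bandpass(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    Applied forward-backward (``sosfiltfilt``) so no phase distortion is
    introduced; the effective amplitude response is the squared magnitude
    of the one-pass filter.
    """
    cfg.validate(rec.fs)
    sos = signal.butter(
        cfg.filter_order, [cfg.f_low, cfg.f_high], btype="bandpass", fs=rec.fs, output="sos"
    )
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=-1))


def reject_channels(
    rec: Recording, cfg: PreprocessConfig
) -> tuple[Recording, list[str]]:
    """Drop channels whose peak |amplitude| exceeds ``cfg.amp_threshold``.

    Returns the surviving recording (channel order preserved) and the list
    of rejected labels.  Rejecting everything is a hard error: it means the
    threshold is inconsistent with the data units.
    """
    if cfg.amp_threshold <= 0:
        raise InvalidConfigError(
            f"amplitude threshold must be positive, got {cfg.amp_threshold}"
        )
    peak = np.max(np.abs(rec.data), axis=1)
    keep = peak <= cfg.amp_threshold
    rejected = [l for l, k in zip(rec.channel_labels, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"all {rec.n_channels} channels exceed {cfg.amp_threshold} {rec.unit}; "
            f"peak amplitudes span [{peak.min():.3g}, {peak.max():.3g}]"
        )
    if rejected:
        logger.info("rejected %d channel(s): %s", len(rejected), ", ".join(rejected))
    kept = rec.with_data(
        rec.data[keep], channel_labels=[l for l, k in zip(rec.channel_labels, keep) if k]
    )
    return kept, rejected


def window_count(duration_s: float, window_s: float, stride_s: float) -> int:
    """Number of full windows: floor((duration - window)/stride) + 1, or 0."""
    if duration_s < window_s:
        return 0
    return int(math.floor((duration_s - window_s) / stride_s + 1e-9)) + 1


def window(rec: Recording, cfg: PreprocessConfig) -> WindowedSeries:
    """Cut the recording into sliding windows of ``window_s`` every ``stride_s``.

    Windows are views into the recording's buffer (no copy) and never extend
    past the end of the file, so windows from consecutive files never overlap
    a file boundary.
    """
    wlen = int(round(cfg.window_s * rec.fs))
    step = int(round(cfg.stride_s * rec.fs))
    n = window_count(rec.duration_s, cfg.window_s, cfg.stride_s)
    if n == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one "
            f"{cfg.window_s} s window"
        )
    starts, blocks = [], []
    for i in range(n):
        s0 = i * step
        starts.append(rec.start_time + timedelta(seconds=s0 / rec.fs))
        blocks.append(rec.data[:, s0 : s0 + wlen])
    return WindowedSeries(
        starts=starts,
        blocks=blocks,
        fs=rec.fs,
        source_file=rec.source_file,
        channel_labels=list(rec.channel_labels),
    )


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs``.

    Handles non-integer decimation (e.g. 500 -> 200 Hz is a 2/5 rational
    rate change) via ``scipy.signal.resample_poly``, which applies the
    anti-aliasing low-pass internally.
    """
    if target_fs >= rec.fs:
        raise InvalidConfigError(
            f"target rate {target_fs} Hz must be below the current rate {rec.fs} Hz"
        )
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(
        rec.data, frac.numerator, frac.denominator, axis=-1, padtype="line"
    )
    return rec.with_data(out, fs=rec.fs * frac.numerator / frac.denominator)


def downsample_block(block: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Resample a bare channels x samples block (window-level helper)."""
    if target_fs >= fs:
        raise InvalidConfigError(
            f"target rate {target_fs} Hz must be below the current rate {fs} Hz"
        )
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return signal.resample_poly(
        block, frac.numerator, frac.denominator, axis=-1, padtype="line"
    )
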