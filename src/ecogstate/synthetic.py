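"""Synthetic multichannel ECoG-like recordings with a planted state schedule.

Real long-term recordings of the kind this package targets are not publicly
distributable, so every pipeline stage is exercised on generated data that
plants the contrasts the features are designed to detect:

* a 1/f-type pink background on every channel, always present;
* "conscious" epochs add (i) a theta-range oscillatory source shared across
  channels with a per-channel propagation lag — lagged sharing drives up the
  imaginary coherency, which is blind to zero-lag coupling, and the symbolic
  mutual information; (ii) a beta-band oscillation; (iii) independent
  broadband noise that raises Lempel-Ziv complexity, the Poincaré SD1/SD2
  ratio and the spectral edge;
* "unconscious" epochs add high-amplitude slow waves that are identical
  (zero-lag) across channels — coherent but invisible to the imaginary
  coherency and down-weighted by the wSMI weight rule — plus an in-phase
  sleep-spindle-like mid-frequency oscillation, giving the low-complexity,
  low-edge-frequency spectral profile of a deactivated cortex;
* optionally, a configurable number of "noisy" channels rescaled above the
  amplitude-rejection threshold.

Everything is driven by one seeded generator, so identical configurations
reproduce identical sample values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "StateSchedule",
    "ConsciousProfile",
    "UnconsciousProfile",
    "SynthConfig",
    "generate",
    "ground_truth_labels",
    "alternating_schedule",
]

CONSCIOUS = "conscious"
UNCONSCIOUS = "unconscious"


@dataclass(frozen=True)
class StateSchedule:
    """Contiguous, non-overlapping state intervals covering [0, duration].

    ``intervals`` is an ordered list of ``(start_s, end_s, state)`` with
    state one of ``"conscious"`` / ``"unconscious"``.
    """

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        t = 0.0
        for s, e, state in self.intervals:
            if state not in (CONSCIOUS, UNCONSCIOUS):
                raise ValueError(f"unknown state {state!r}")
            if abs(s - t) > 1e-9 or e <= s:
                raise ValueError("intervals must be contiguous and increasing")
            t = e

    @property
    def duration_s(self) -> float:
        return self.intervals[-1][1]

    def state_at(self, t: float) -> str:
        for s, e, state in self.intervals:
            if s <= t < e:
                return state
        return self.intervals[-1][2]

    def mask(self, fs: float, n_samples: int, state: str) -> np.ndarray:
        """Sample-level 0/1 envelope of ``state``."""
        t = np.arange(n_samples) / fs
        out = np.zeros(n_samples)
        for s, e, st in self.intervals:
            if st == state:
                out[(t >= s) & (t < e)] = 1.0
        return out


def alternating_schedule(
    n_files: int, file_length_s: float, block_s: float, first: str = UNCONSCIOUS
) -> StateSchedule:
    """Blocks of ``block_s`` seconds alternating between the two states."""
    total = n_files * file_length_s
    other = CONSCIOUS if first == UNCONSCIOUS else UNCONSCIOUS
    ivs, t, state = [], 0.0, first
    while t < total - 1e-9:
        e = min(t + block_s, total)
        ivs.append((t, e, state))
        t, state = e, (other if state == first else first)
    return StateSchedule(tuple(ivs))


@dataclass(frozen=True)
class ConsciousProfile:
    """Amplitudes (in background-RMS units) of the conscious-regime sources."""

    theta_gain: float = 2.2  # 2-4 Hz oscillatory noise, independent per channel
    beta_gain: float = 1.1  # beta-band (18-22 Hz) oscillation
    broadband_gain: float = 1.2  # independent white noise per channel
    coupling_strength: float = 0.8  # shared lagged theta-band source
    coupling_lag_s: float = 0.02  # per-channel-index propagation lag


@dataclass(frozen=True)
class UnconsciousProfile:
    """Amplitudes of the unconscious-regime sources (all zero-lag shared).

    The mid-band hump (4.5-11.5 Hz, broadband rather than a narrow spindle)
    supplies the sedation-like mass between the slow waves and the beta
    band; keeping it broadband leaves its autocorrelation negligible at the
    Poincaré lag, so the unconscious cloud stays elongated.
    """

    slow_wave_gain: float = 0.6  # 0.5-1.5 Hz shared slow waves
    spindle_gain: float = 0.7  # 4.5-11.5 Hz shared mid-band activity
    coupling_strength: float = 0.0  # extra lagged coupling (off by default)


@dataclass(frozen=True)
class SynthConfig:
    """Recording geometry, regime profiles and the noisy-channel plant.

    Defaults emulate a 64-channel, 500 Hz acquisition; the desk-scale
    fixture used throughout the test-suite shrinks ``n_files`` /
    ``file_length_s`` / ``n_channels`` but never the contrast profiles.
    """

    n_channels: int = 64
    fs: float = 500.0
    file_length_s: float = 3600.0
    n_files: int = 24
    seed: int = 0
    background_rms: float = 0.5
    conscious: ConsciousProfile = field(default_factory=ConsciousProfile)
    unconscious: UnconsciousProfile = field(default_factory=UnconsciousProfile)
    noisy_channels: int = 0
    noisy_amplitude: float = 250.0  # peak amplitude given to planted bad channels
    start_time: datetime = datetime(2024, 1, 1, 0, 34, 0)
    unit: str = "mV"


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    nz = f > 0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    x = np.fft.irfft(spec * shape, n)
    return x / max(x.std(), 1e-12)


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, f1: float, f2: float
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    sos = signal.butter(4, [f1, f2], btype="bandpass", fs=fs, output="sos")
    # pad to let the filter settle, then trim
    pad = int(4 * fs / f1)
    x = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    return x / max(x.std(), 1e-12)


def generate(cfg: SynthConfig, schedule: StateSchedule) -> list[Recording]:
    """Generate one :class:`Recording` per "file" according to the schedule.

    The schedule must span exactly ``n_files * file_length_s`` seconds.
    """
    if abs(schedule.duration_s - cfg.n_files * cfg.file_length_s) > 1e-6:
        raise ValueError(
            f"schedule covers {schedule.duration_s} s but the configuration "
            f"asks for {cfg.n_files} x {cfg.file_length_s} s"
        )
    rng = np.random.default_rng(cfg.seed)
    nominal = int(round(cfg.file_length_s * cfg.fs))
    lag_step = int(round(cfg.conscious.coupling_lag_s * cfg.fs))
    max_lag = lag_step * max(cfg.n_channels - 1, 1)
    recordings = []
    noisy_idx = set(
        rng.choice(cfg.n_channels, size=cfg.noisy_channels, replace=False).tolist()
        if cfg.noisy_channels
        else []
    )
    for ifile in range(cfg.n_files):
        n = nominal
        t0 = ifile * cfg.file_length_s
        tt = t0 + np.arange(n) / cfg.fs
        # state envelopes in absolute time
        mask_c = np.zeros(n)
        mask_u = np.zeros(n)
        for s, e, state in schedule.intervals:
            sel = (tt >= s) & (tt < e)
            (mask_c if state == CONSCIOUS else mask_u)[sel] = 1.0
        # shared sources for this file
        theta_src = _band_noise(rng, n + max_lag, cfg.fs, 2.0, 3.5)
        beta_src = _band_noise(rng, n + max_lag, cfg.fs, 18.0, 22.0)
        slow_src = _band_noise(rng, n, cfg.fs, 0.5, 1.5)
        spindle_src = _band_noise(rng, n, cfg.fs, 4.5, 11.5)
        data = np.empty((cfg.n_channels, n))
        c, u = cfg.conscious, cfg.unconscious
        for ch in range(cfg.n_channels):
            lag = ch * lag_step
            x = cfg.background_rms * _pink_noise(rng, n, cfg.fs)
            x += mask_c * (
                c.coupling_strength * theta_src[lag : lag + n]
                + c.theta_gain * _band_noise(rng, n, cfg.fs, 2.0, 3.5)
                + c.beta_gain * beta_src[lag : lag + n]
                + c.broadband_gain * rng.standard_normal(n)
            )
            x += mask_u * (
                u.slow_wave_gain * slow_src
                + u.spindle_gain * spindle_src
                + u.coupling_strength * theta_src[lag : lag + n]
            )
            if ch in noisy_idx:
                x *= cfg.noisy_amplitude / max(np.abs(x).max(), 1e-12)
            data[ch] = x
        recordings.append(
            Recording(
                data=data,
                fs=cfg.fs,
                channel_labels=[f"G{i + 1:03d}" for i in range(cfg.n_channels)],
                start_time=cfg.start_time + timedelta(seconds=t0),
                unit=cfg.unit,
                source_file=f"synthetic_{ifile:02d}",
            )
        )
    return recordings


def ground_truth_labels(
    schedule: StateSchedule, windows, t0: datetime, window_s: float
) -> list[str]:
    """State label per window: the schedule state at the window midpoint."""
    labels = []
    for start in windows.starts:
        mid = (start - t0).total_seconds() + window_s / 2.0
        labels.append(schedule.state_at(mid))
    return labels
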