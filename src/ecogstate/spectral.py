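"""Spectral features: Welch PSD, relative band power, spectral edge frequency.

Relative power of a band [f1, f2] is the ratio of the PSD summed over that
band to the PSD summed over a total band (0-45 Hz here, the filter pass
band):

    RP = sum_{f1<=f<=f2} Sx(f) / sum_{fl<=f<=fh} Sx(f)

The spectral edge frequency SEFr is the smallest frequency below which a
fraction r (default 0.95) of the total power lies; it is reported normalized
by the 45 Hz filter ceiling so that, like the other features, it lives on a
unitless 0-1 scale.  Both are computed on the discrete Welch grid without
interpolation, with band edges inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "SpectralParams",
    "PsdEstimate",
    "welch_psd",
    "relative_power",
    "spectral_edge",
    "THETA",
    "BETA",
    "TOTAL",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f1, f2] in Hz (edges inclusive)."""

    name: str
    f1: float
    f2: float

    def __post_init__(self):
        if not (0 <= self.f1 < self.f2):
            raise ValueError(f"need 0 <= f1 < f2, got [{self.f1}, {self.f2}]")


# Band conventions of the consciousness-feature literature this package
# follows: theta spanning the slow end (0-4 Hz) rather than the classical
# 4-8 Hz EEG theta; beta 12-30 Hz; "total" capped by the 45 Hz filter edge.
THETA = BandDefinition("theta", 0.0, 4.0)
BETA = BandDefinition("beta", 12.0, 30.0)
TOTAL = BandDefinition("total", 0.0, 45.0)


@dataclass(frozen=True)
class SpectralParams:
    """Welch estimator settings and spectral-edge parameters.

    ``window_fraction``: Welch sub-window length as a fraction of the data
    segment (1/8 by default), Hamming-tapered, 50% overlap.
    ``sef_fraction``: the power fraction r defining SEFr (0.95 -> SEF95).
    ``sef_norm``: normalization ceiling in Hz for the reported edge.
    """

    window_fraction: float = 1.0 / 8.0
    overlap: float = 0.5
    taper: str = "hamming"
    sef_fraction: float = 0.95
    sef_norm: float = 45.0

    def __post_init__(self):
        if not (0 < self.overlap < 1):
            raise ValueError(f"overlap must be in (0,1), got {self.overlap}")
        if not (0 < self.sef_fraction <= 1):
            raise ValueError(f"sef_fraction must be in (0,1], got {self.sef_fraction}")


@dataclass
class PsdEstimate:
    """Welch PSD on a frequency grid spanning [0, fs/2].

    ``power`` has shape (n_channels, n_freqs); single-channel input yields
    shape (1, n_freqs).
    """

    freqs: np.ndarray
    power: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(block: np.ndarray, fs: float, p: SpectralParams = SpectralParams()) -> PsdEstimate:
    """Welch PSD of a channels x samples block.

    Sub-windows of ``floor(samples * window_fraction)`` samples, Hamming
    taper, 50% overlap, density scaling (band ratios are scale-invariant,
    so density vs. power normalization is immaterial downstream).
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    nseg = int(block.shape[-1] * p.window_fraction)
    if nseg < 2:
        raise ValueError(
            f"segment of {block.shape[-1]} samples too short for "
            f"window_fraction={p.window_fraction}"
        )
    freqs, power = signal.welch(
        block,
        fs=fs,
        window=p.taper,
        nperseg=nseg,
        noverlap=int(nseg * p.overlap),
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return PsdEstimate(freqs=freqs, power=power)


def _band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    return (freqs >= band.f1) & (freqs <= band.f2)


def relative_power(
    psd: PsdEstimate, band: BandDefinition, total: BandDefinition = TOTAL
) -> np.ndarray:
    """Fraction of ``total``-band power lying in ``band``, per channel.

    Band sums are inclusive of both edge bins.  Raises if the total band
    carries no power (an all-zero signal has no defined band fraction).
    """
    num = psd.power[..., _band_mask(psd.freqs, band)].sum(axis=-1)
    den = psd.power[..., _band_mask(psd.freqs, total)].sum(axis=-1)
    if np.any(den <= 0):
        raise ValueError("total band power is zero; relative power undefined")
    return num / den


def spectral_edge(psd: PsdEstimate, p: SpectralParams = SpectralParams()) -> np.ndarray:
    """Normalized spectral edge frequency per channel.

    The smallest grid frequency F with cumulative power >= r * total power,
    returned as F / sef_norm.  Ties resolve to the lower frequency because
    the cumulative sum is evaluated on the grid in increasing order.
    """
    total = psd.power.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total power; spectral edge undefined")
    cum = np.cumsum(psd.power, axis=-1)
    # first index where cumulative power crosses the threshold
    crossed = cum >= p.sef_fraction * total - 1e-15 * total
    idx = crossed.argmax(axis=-1)
    return psd.freqs[idx] / p.sef_norm
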