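"""Complexity features: Poincaré-plot SD1/SD2 ratio and Lempel-Ziv complexity.

The Poincaré plot scatters x_k against its lag-tau copy x_{k+tau}.  SD1 is
the dispersion perpendicular to the identity line, SD2 along it:

    SD1^2 = Var(x_k - x_{k+tau}) / 2,     SD2^2 = 2 Var(x_k) - SD1^2

and the ellipsoid radius ratio ERR = SD1/SD2 is ~1 for uncorrelated noise
(round cloud) and ->0 for signals with strong linear lag structure
(elongated cloud).  The lag is taken as a fraction (default 1/4) of the
dominant oscillation period.

Lempel-Ziv complexity counts the phrases of the LZ76 exhaustive-history
parsing of a median-binarized window; the normalized form c(n) log2(n) / n
removes the trivial length dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import SpectralParams, welch_psd

__all__ = [
    "PoincareParams",
    "LzcParams",
    "dominant_period",
    "poincare_err",
    "binarize",
    "lzc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PoincareParams:
    """Lag selection for the Poincaré plot.

    ``tau`` is the lag in samples; when built from a signal it is
    ``tau_rule`` x the dominant cycle period (rule range 1/5..1/4),
    rounded to at least one sample.
    """

    tau: int = 1
    tau_rule: float = 0.25
    default_period_s: float = 0.1

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1 sample, got {self.tau}")


@dataclass(frozen=True)
class LzcParams:
    binarization: str = "median"
    normalization: str = "normalized"  # "raw" returns the bare phrase count


def dominant_period(
    x: np.ndarray,
    fs: float,
    f_low: float = 0.5,
    f_high: float = 45.0,
    default_period_s: float = 0.1,
) -> float:
    """Period (s) of the strongest PSD peak within [f_low, f_high].

    Flat or degenerate spectra (no in-band peak rising above the in-band
    median by 3x) fall back to ``default_period_s`` with a logged warning,
    so a lag can always be derived.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x != x.flat[0] if x.size else False):
        logger.warning("constant signal: falling back to default period %.3fs", default_period_s)
        return default_period_s
    # cap sub-window length at 4 s: a coarse, heavily averaged grid gives a
    # far more stable argmax than a finely resolved noisy periodogram
    frac = min(1.0 / 8.0, 4.0 * fs / x.size) if x.size > 32 * fs else 1.0 / 8.0
    psd = welch_psd(x, fs, SpectralParams(window_fraction=frac))
    mask = (psd.freqs >= f_low) & (psd.freqs <= f_high)
    p = psd.power[0, mask]
    f = psd.freqs[mask]
    if p.size == 0 or p.max() <= 0 or p.max() < 3.0 * np.median(p):
        logger.warning(
            "no dominant spectral peak in [%g, %g] Hz: falling back to %.3fs",
            f_low, f_high, default_period_s,
        )
        return default_period_s
    f0 = f[p.argmax()]
    if f0 <= 0:
        logger.warning("dominant power at DC: falling back to %.3fs", default_period_s)
        return default_period_s
    # refine by the power centroid of the octave around the peak: the raw
    # argmax of a periodogram wanders within the dominant hump, the
    # centroid of that hump does not
    near = (f >= f0 / 2) & (f <= f0 * 2) & (f > 0)
    f0 = float(np.sum(f[near] * p[near]) / np.sum(p[near]))
    return 1.0 / f0


def tau_from_signal(x: np.ndarray, fs: float, p: PoincareParams) -> int:
    """Lag in samples: tau_rule x dominant period, at least 1 sample."""
    period = dominant_period(x, fs, default_period_s=p.default_period_s)
    return max(1, int(round(p.tau_rule * period * fs)))


def poincare_err(x: np.ndarray, p: PoincareParams) -> float:
    """Ellipsoid radius ratio SD1/SD2 of the lag-``p.tau`` Poincaré plot.

    Invariant to amplitude scaling and offset.  A constant signal has no
    defined ellipse (SD2 = 0) and raises; a (finite-sample) negative SD2
    radicand is clamped to zero with a warning, yielding ERR = +inf cases
    only when the clamp makes SD2 exactly 0 while SD1 > 0 — treated as an
    error since the ratio is then meaningless.
    """
    x = np.asarray(x, dtype=float)
    tau = p.tau
    if x.size <= tau + 1:
        raise ValueError(f"window of {x.size} samples too short for tau={tau}")
    d = x[:-tau] - x[tau:]
    sd1_sq = 0.5 * np.var(d)
    sd2_sq = 2.0 * np.var(x) - sd1_sq
    if sd2_sq < 0:
        logger.warning("negative SD2 radicand (%.3g) clamped to 0", sd2_sq)
        sd2_sq = 0.0
    sd1 = np.sqrt(sd1_sq)
    sd2 = np.sqrt(sd2_sq)
    if sd2 == 0:
        raise ValueError("SD2 = 0 (constant or degenerate signal): ERR undefined")
    return float(sd1 / sd2)


def binarize(x: np.ndarray, p: LzcParams = LzcParams()) -> np.ndarray:
    """Two-symbol quantization of a window: 1 where x exceeds its median."""
    if p.binarization != "median":
        raise ValueError(f"unknown binarization rule {p.binarization!r}")
    x = np.asarray(x, dtype=float)
    return (x > np.median(x)).astype(np.uint8)


def lz76_phrase_count(s: np.ndarray) -> int:
    """Number of phrases in the LZ76 exhaustive-history parsing.

    Each phrase is the shortest continuation that has not yet occurred as a
    substring of everything before its final symbol; a trailing reproducible
    segment counts as one final phrase.
    """
    seq = "".join("1" if b else "0" for b in np.asarray(s).ravel())
    n = len(seq)
    if n < 2:
        raise ValueError(f"need a sequence of length >= 2, got {n}")
    c = 0
    i = 0
    while i < n:
        k = 1
        # extend the phrase while seq[i:i+k] occurs before its last symbol
        while i + k <= n and seq[i : i + k] in seq[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def lzc(s: np.ndarray, p: LzcParams = LzcParams()) -> float:
    """Lempel-Ziv complexity of a binary sequence.

    ``normalized`` (default) returns c(n) log2(n) / n, which is ~1 for
    maximally irregular sequences and near 0 for trivially repetitive ones;
    ``raw`` returns the integer phrase count.
    """
    c = lz76_phrase_count(s)
    if p.normalization == "raw":
        return float(c)
    if p.normalization == "normalized":
        n = len(s)
        return c * np.log2(n) / n
    raise ValueError(f"unknown normalization {p.normalization!r}")
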