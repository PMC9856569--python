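"""Connectivity features: imaginary coherency and weighted symbolic MI.

Both measures fill a symmetric channels x channels matrix per data window
and are reduced to one scalar by averaging the strictly-lower triangle.

Imaginary coherency.  The complex coherency Cxy(f) = Sxy / sqrt(Sxx Syy)
has unit modulus bound; its imaginary part vanishes for zero-lag (common
source / volume conducted) coupling, so |Im Cxy| averaged over the band of
interest indexes genuinely lagged interaction.

Weighted symbolic mutual information (wSMI).  Each signal is converted to a
sequence of ordinal patterns: the rank ordering of k points spaced tau
samples apart (k = 3 -> 3! = 6 symbols).  The mutual information between
the two aligned symbol sequences is computed from the empirical joint
distribution, but symbol pairs that are identical or exactly sign-opposite
are given weight zero, discarding coupling explainable by a common source:

    wSMI(x, y) = 1/log(k!) * sum_{a,b} w(a,b) p(a,b) log[ p(a,b) / (p(a) p(b)) ]
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial, log

import numpy as np
from scipy import signal

from .spectral import BandDefinition, SpectralParams, THETA

__all__ = [
    "WsmiParams",
    "ConnectivityMatrix",
    "icoh_pair",
    "symbolize",
    "wsmi_pair",
    "connectivity_matrix",
    "reduce_matrix",
]


@dataclass(frozen=True)
class WsmiParams:
    """Ordinal-pattern symbolization parameters.

    ``tau`` is in samples at the (downsampled) working rate: the default of
    8 samples at 200 Hz spans (k-1)*tau = 80 ms per pattern, placing the
    pattern scale in the slow/theta range.
    """

    k: int = 3
    tau: int = 8

    def __post_init__(self):
        if self.k < 2:
            raise ValueError(f"symbol length k must be >= 2, got {self.k}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1 sample, got {self.tau}")

    @property
    def n_symbols(self) -> int:
        return factorial(self.k)


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise coupling matrix; diagonal is NaN (excluded)."""

    values: np.ndarray
    measure: str
    channel_labels: list[str] | None = None


# ---------------------------------------------------------------------------
# spectral leg: imaginary coherency


def _welch_segments(block: np.ndarray, p: SpectralParams) -> np.ndarray:
    """Hamming-tapered overlapping FFT segments, shape (ch, n_seg, n_freq)."""
    block = np.atleast_2d(np.asarray(block, dtype=float))
    n = block.shape[-1]
    nseg = int(n * p.window_fraction)
    if nseg < 2:
        raise ValueError(f"block of {n} samples too short for Welch segmentation")
    step = nseg - int(nseg * p.overlap)
    starts = range(0, n - nseg + 1, step)
    taper = signal.get_window(p.taper, nseg)  # periodic, as in Welch averaging
    segs = np.stack([block[:, s : s + nseg] * taper for s in starts], axis=1)
    return np.fft.rfft(segs, axis=-1)


def cross_spectra(block: np.ndarray, fs: float, p: SpectralParams = SpectralParams()):
    """All-pairs Welch cross-spectral matrix Sxy(f) for one window.

    Returns (freqs, S) with S of shape (ch, ch, n_freq); S[i, i] is the
    auto-spectrum.  Scaling constants are omitted — coherency is a ratio in
    which they cancel.
    """
    X = _welch_segments(block, p)
    n = np.atleast_2d(block).shape[-1]
    nseg = int(n * p.window_fraction)
    freqs = np.fft.rfftfreq(nseg, d=1.0 / fs)
    S = np.einsum("isf,jsf->ijf", X, np.conj(X)) / X.shape[1]
    return freqs, S


def icoh_pair(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: BandDefinition = THETA,
    p: SpectralParams = SpectralParams(),
) -> float:
    """Mean |imaginary coherency| between two channels over ``band``.

    Zero for identical (or merely rescaled) signals, whose coherency is
    purely real; bounded in [0, 1].
    """
    block = np.vstack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    freqs, S = cross_spectra(block, fs, p)
    return _icoh_from_spectra(freqs, S, band)[0, 1]


def _icoh_from_spectra(freqs: np.ndarray, S: np.ndarray, band: BandDefinition) -> np.ndarray:
    auto = np.real(np.einsum("iif->if", S))
    if np.any(auto <= 0):
        raise ValueError("zero auto-spectrum: coherency undefined")
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    coh = S / denom
    mask = (freqs >= band.f1) & (freqs <= band.f2)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band [{band.f1}, {band.f2}] Hz")
    out = np.abs(np.imag(coh[..., mask])).mean(axis=-1)
    np.fill_diagonal(out, np.nan)
    return out


# ---------------------------------------------------------------------------
# symbolic leg: ordinal patterns and wSMI


def _pattern_tables(k: int) -> tuple[dict[tuple, int], np.ndarray]:
    """Rank-tuple -> symbol id, and the id of each symbol's sign-opposite."""
    perms = list(permutations(range(k)))
    index = {perm: i for i, perm in enumerate(perms)}
    opposite = np.array(
        [index[tuple(k - 1 - r for r in perm)] for perm in perms], dtype=int
    )
    return index, opposite


def symbolize(x: np.ndarray, p: WsmiParams = WsmiParams()) -> np.ndarray:
    """Ordinal-pattern symbol sequence of a single-channel window.

    Position t maps to the rank pattern of (x_t, x_{t+tau}, ...,
    x_{t+(k-1)tau}); ties rank by order of appearance (stable sort).
    Symbols are integers in [0, k!).
    """
    x = np.asarray(x, dtype=float).ravel()
    span = (p.k - 1) * p.tau
    if x.size <= span:
        raise ValueError(
            f"window of {x.size} samples too short for k={p.k}, tau={p.tau}"
        )
    m = x.size - span
    emb = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:, :: p.tau]
    assert emb.shape == (m, p.k)
    ranks = np.argsort(np.argsort(emb, axis=1, kind="stable"), axis=1, kind="stable")
    index, _ = _pattern_tables(p.k)
    # encode rank tuples as base-k integers, then map to permutation ids
    codes = ranks @ (p.k ** np.arange(p.k))
    code_to_id = np.full(p.k ** p.k, -1, dtype=int)
    for perm, i in index.items():
        code_to_id[np.dot(perm, p.k ** np.arange(p.k))] = i
    return code_to_id[codes]


def wsmi_pair(
    x: np.ndarray, y: np.ndarray, p: WsmiParams = WsmiParams()
) -> float:
    """Weighted symbolic mutual information between two aligned windows.

    Natural log throughout with the 1/log(k!) prefactor in the same base.
    Joint probabilities come from raw co-occurrence counts; empty cells
    contribute 0.  Degenerate single-symbol sequences return 0.
    """
    sx = symbolize(x, p)
    sy = symbolize(y, p)
    return wsmi_from_symbols(sx, sy, p)


def wsmi_from_symbols(sx: np.ndarray, sy: np.ndarray, p: WsmiParams) -> float:
    if sx.shape != sy.shape:
        raise ValueError("symbol sequences must be aligned (equal length)")
    ns = p.n_symbols
    joint = np.zeros((ns, ns))
    np.add.at(joint, (sx, sy), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    if np.count_nonzero(px) < 2 or np.count_nonzero(py) < 2:
        return 0.0
    _, opposite = _pattern_tables(p.k)
    w = np.ones((ns, ns))
    ids = np.arange(ns)
    w[ids, ids] = 0.0
    w[ids, opposite] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (px[:, None] * py[None, :])
        terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
    return float((w * terms).sum() / log(ns))


# ---------------------------------------------------------------------------
# matrices and reduction


def connectivity_matrix(
    block: np.ndarray,
    measure: str,
    fs: float | None = None,
    band: BandDefinition = THETA,
    wsmi_params: WsmiParams = WsmiParams(),
    spectral_params: SpectralParams = SpectralParams(),
    channel_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Pairwise coupling matrix for one channels x samples window.

    ``measure`` is ``"icoh"`` (requires ``fs``) or ``"wsmi"`` (the block is
    expected already at the symbolic working rate).  The diagonal is NaN
    and excluded from every reduction.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    nch = block.shape[0]
    if nch < 2:
        raise ValueError("need at least 2 channels for connectivity")
    if measure == "icoh":
        if fs is None:
            raise ValueError("icoh requires the sampling rate fs")
        freqs, S = cross_spectra(block, fs, spectral_params)
        values = _icoh_from_spectra(freqs, S, band)
    elif measure == "wsmi":
        symbols = [symbolize(block[i], wsmi_params) for i in range(nch)]
        values = np.full((nch, nch), np.nan)
        for i in range(nch):
            for j in range(i):
                v = wsmi_from_symbols(symbols[i], symbols[j], wsmi_params)
                values[i, j] = values[j, i] = v
    else:
        raise ValueError(f"unknown connectivity measure {measure!r}")
    return ConnectivityMatrix(values=values, measure=measure, channel_labels=channel_labels)


def reduce_matrix(m: ConnectivityMatrix) -> float:
    """Mean of the strictly-lower-triangle entries (diagonal excluded)."""
    nch = m.values.shape[0]
    if nch < 2:
        raise ValueError("need at least 2 channels to reduce a connectivity matrix")
    il = np.tril_indices(nch, k=-1)
    return float(np.mean(m.values[il]))
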