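"""Per-window feature extraction: seven scalars per 3-s window.

Spectral and complexity measures are computed per channel and averaged
across the retained channels; the two connectivity measures fill a pairwise
matrix whose strictly-lower-triangle mean is the window scalar.  wSMI is
computed on the recording resampled to the symbolic working rate (200 Hz
by default) — the same windows cut at the lower rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import FEATURE_NAMES, FeatureMatrix
from .complexity import LzcParams, PoincareParams, binarize, lzc, poincare_err, tau_from_signal
from .connectivity import WsmiParams, connectivity_matrix, reduce_matrix
from .preprocess import PreprocessConfig, WindowedSeries
from .spectral import BETA, THETA, TOTAL, SpectralParams, relative_power, spectral_edge, welch_psd

__all__ = ["FeatureParams", "compute_window_features", "compute_feature_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureParams:
    """Bundle of all feature-stage parameters."""

    spectral: SpectralParams = field(default_factory=SpectralParams)
    poincare: PoincareParams = field(default_factory=PoincareParams)
    lzc: LzcParams = field(default_factory=LzcParams)
    wsmi: WsmiParams = field(default_factory=WsmiParams)
    theta = THETA
    beta = BETA
    total = TOTAL


def compute_window_features(
    block: np.ndarray,
    fs: float,
    wsmi_block: np.ndarray,
    wsmi_fs: float,
    params: FeatureParams,
) -> np.ndarray:
    """The seven feature scalars for one window.

    ``block`` is channels x samples at the acquisition rate; ``wsmi_block``
    is the same window at the symbolic working rate.  Failures in a single
    measure yield NaN for that cell (imputed downstream) rather than
    aborting a long run.
    """
    out = np.full(len(FEATURE_NAMES), np.nan)
    nch = block.shape[0]
    try:
        psd = welch_psd(block, fs, params.spectral)
        out[0] = relative_power(psd, params.theta, params.total).mean()
        out[1] = relative_power(psd, params.beta, params.total).mean()
        out[2] = spectral_edge(psd, params.spectral).mean()
    except ValueError as exc:
        logger.warning("spectral features failed: %s", exc)
    try:
        out[3] = float(
            np.mean([poincare_err(block[i], params.poincare) for i in range(nch)])
        )
    except ValueError as exc:
        logger.warning("ERR failed: %s", exc)
    try:
        out[4] = float(
            np.mean([lzc(binarize(block[i], params.lzc), params.lzc) for i in range(nch)])
        )
    except ValueError as exc:
        logger.warning("LZC failed: %s", exc)
    if nch >= 2:
        try:
            out[5] = reduce_matrix(
                connectivity_matrix(
                    block, "icoh", fs=fs, band=params.theta,
                    spectral_params=params.spectral,
                )
            )
        except ValueError as exc:
            logger.warning("iCOH failed: %s", exc)
        try:
            out[6] = reduce_matrix(
                connectivity_matrix(wsmi_block, "wsmi", wsmi_params=params.wsmi)
            )
        except ValueError as exc:
            logger.warning("wSMI failed: %s", exc)
    return out


def compute_feature_matrix(
    windows: list[WindowedSeries],
    wsmi_windows: list[WindowedSeries],
    params: FeatureParams | None = None,
    calibrate_tau: bool = True,
    calibration_signal: np.ndarray | None = None,
) -> FeatureMatrix:
    """Assemble the T x 7 feature matrix from aligned window series.

    ``windows`` and ``wsmi_windows`` are per-file series at the acquisition
    and symbolic rates respectively (equal counts file-by-file).  The
    Poincaré lag is calibrated once — a fraction of the dominant cycle
    period of ``calibration_signal`` (a stretch of the first file; falls
    back to the first window) — unless ``calibrate_tau`` is False, in which
    case the configured ``params.poincare.tau`` is used.  A single global
    lag keeps the ERR comparable across windows.
    """
    params = params or FeatureParams()
    if len(windows) != len(wsmi_windows):
        raise ValueError("window series lists differ in file count")
    if calibrate_tau:
        first = (
            calibration_signal
            if calibration_signal is not None
            else windows[0].blocks[0][0]
        )
        tau = tau_from_signal(first, windows[0].fs, params.poincare)
        params.poincare = PoincareParams(
            tau=tau,
            tau_rule=params.poincare.tau_rule,
            default_period_s=params.poincare.default_period_s,
        )
        logger.info("Poincaré lag calibrated to %d samples", tau)
    times, rows = [], []
    for ws, wws in zip(windows, wsmi_windows):
        if len(ws) != len(wws):
            raise ValueError(
                f"window counts disagree between rates for {ws.source_file}: "
                f"{len(ws)} vs {len(wws)}"
            )
        for (t, block), (_, wblock) in zip(ws, wws):
            times.append(t)
            rows.append(
                compute_window_features(block, ws.fs, wblock, wws.fs, params)
            )
    return FeatureMatrix(times=times, raw=np.array(rows))


def default_preprocess() -> PreprocessConfig:
    return PreprocessConfig()
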