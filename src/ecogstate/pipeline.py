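"""End-to-end orchestration: preprocess -> features -> clustering -> report.

:func:`run` takes a list of recordings (one per source file), applies the
band-pass, rejects high-amplitude channels using the peak over the whole
multi-file recording, windows each file (windows never span files),
resamples for the symbolic connectivity leg, extracts the seven features
per window, soft-clusters, and writes the consciousness trace and interval
summaries.  Identical inputs, configuration and seed reproduce identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import (
    ClusterConfig,
    ConsciousnessTrace,
    FeatureMatrix,
    ensemble,
    fcm_fit,
    gmm_fit,
    membership_trace,
    predefined_partition,
)
from .features import FeatureParams, compute_feature_matrix
from .preprocess import PreprocessConfig, bandpass, downsample, reject_channels, window
from .recording import Recording
from .reporting import feature_correlations, resolve_intervals, summarize

__all__ = ["RunConfig", "RunResult", "run", "extract_features"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters for one end-to-end run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureParams = field(default_factory=FeatureParams)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    intervals: dict[str, tuple[str, str]] = field(default_factory=dict)
    predefined_centroids: np.ndarray | None = None
    predefined_gmm: dict | None = None
    out_dir: Path | None = None


@dataclass
class RunResult:
    features: FeatureMatrix
    traces: dict[str, ConsciousnessTrace]
    summary: dict
    correlations: pd.DataFrame
    rejected_channels: list[str]


def _global_rejection(
    recs: list[Recording], cfg: PreprocessConfig
) -> tuple[list[Recording], list[str]]:
    """Reject channels whose peak amplitude over *any* file exceeds the
    threshold, so the channel set is consistent across the whole recording."""
    peak = np.max([np.abs(r.data).max(axis=1) for r in recs], axis=0)
    keep = peak <= cfg.amp_threshold
    labels = recs[0].channel_labels
    rejected = [l for l, k in zip(labels, keep) if not k]
    if not keep.any():
        raise ValueError("all channels exceed the amplitude threshold")
    if rejected:
        logger.info("rejected %d channel(s): %s", len(rejected), ", ".join(rejected))
    survivors = [l for l, k in zip(labels, keep) if k]
    return [r.pick(survivors) for r in recs], rejected


def extract_features(
    recs: list[Recording], cfg: RunConfig
) -> tuple[FeatureMatrix, list[str]]:
    """Preprocess all files and assemble the feature matrix."""
    if not recs:
        raise ValueError("no input recordings")
    pp = cfg.preprocess
    pp.validate(recs[0].fs)
    recs, rejected = _global_rejection(recs, pp)
    main_windows, wsmi_windows = [], []
    calibration = None
    for rec in recs:
        filtered = bandpass(rec, pp)
        if calibration is None:
            # tau calibration stretch: the whole first file (capped at 10 min)
            calibration = filtered.data[0, : int(600 * rec.fs)]
        main_windows.append(window(filtered, pp))
        wsmi_windows.append(window(downsample(filtered, pp.wsmi_fs), pp))
    F = compute_feature_matrix(
        main_windows, wsmi_windows, cfg.features, calibration_signal=calibration
    )
    return F, rejected


def run(recs: list[Recording], cfg: RunConfig | None = None) -> RunResult:
    """Full pipeline on a list of per-file recordings.

    Returns the feature matrix, the FCM / GMM / ensemble traces (plus the
    predefined-centroid trace when centres are configured), the interval
    summary and the feature-trace Spearman correlation table; artifacts are
    written to ``cfg.out_dir`` when set (trace CSV, summary + manifest JSON).
    """
    cfg = cfg or RunConfig()
    F, rejected = extract_features(recs, cfg)
    fcm = fcm_fit(F, cfg.cluster)
    gmm = gmm_fit(F, cfg.cluster)
    traces = {
        "fcm": membership_trace(fcm, F.times),
        "gmm": membership_trace(gmm, F.times),
    }
    traces["ensemble"] = ensemble(traces["fcm"], traces["gmm"])
    if cfg.predefined_centroids is not None:
        traces["predefined"] = predefined_partition(
            F, cfg.cluster, cfg.predefined_centroids, cfg.predefined_gmm
        )
    intervals = resolve_intervals(cfg.intervals, recs[0].start_time)
    summary = summarize(traces["ensemble"], intervals)
    corr = feature_correlations(F, traces)
    result = RunResult(
        features=F,
        traces=traces,
        summary=summary,
        correlations=corr,
        rejected_channels=rejected,
    )
    if cfg.out_dir is not None:
        _write_artifacts(result, cfg)
    return result


def _write_artifacts(result: RunResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"timestamp": [t.isoformat() for t in result.features.times]}
        | {name: tr.values for name, tr in result.traces.items()}
    )
    df.to_csv(out / "trace.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
    result.correlations.to_csv(out / "correlations.csv")
    manifest = {
        "seed": cfg.cluster.seed,
        "n_windows": result.features.n_windows,
        "rejected_channels": result.rejected_channels,
        "preprocess": vars(cfg.preprocess),
        "cluster": {
            k: v for k, v in vars(cfg.cluster).items() if not k.startswith("_")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
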