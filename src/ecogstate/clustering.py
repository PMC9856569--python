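"""Soft clustering of the windowed feature matrix into a consciousness trace.

The T x 7 feature matrix (relative theta and beta power, normalized SEF95,
Poincaré ERR, Lempel-Ziv complexity, theta-band imaginary coherency and
wSMI, each averaged across channels or channel pairs per window) is min-max
normalized per column, partitioned into two soft clusters by fuzzy c-means
and by a Gaussian mixture model, and the per-window membership degree to
the "conscious" cluster — the one whose centroid sits higher in normalized
feature space, since higher feature values are hypothesized to accompany
higher consciousness — is averaged across the two methods:

    P_avg(c | m1, m2) = ( P(c | m1) + P(c | m2) ) / 2

A pre-defined-centroid mode evaluates the same membership formulas against
fixed cluster centres / mixture parameters without any fitting, for use
when a recording does not itself span both states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "SoftPartition",
    "ConsciousnessTrace",
    "ClusterConfig",
    "fcm_fit",
    "fcm_memberships",
    "gmm_fit",
    "identify_conscious",
    "membership_trace",
    "ensemble",
    "predefined_partition",
    "fit_reference_model",
    "save_reference_model",
    "load_reference_model",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ["Ptheta", "Pbeta", "SEF95", "ERR", "LZC", "iCOHtheta", "wSMI"]


@dataclass
class FeatureMatrix:
    """Windowed features, raw and 0-1 normalized.

    ``normalized`` is the column-wise min-max rescaling of ``raw`` over the
    whole recording; every normalized column attains both 0 and 1.
    """

    times: list[datetime]
    raw: np.ndarray
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    normalized: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != len(self.names):
            raise ValueError(
                f"raw matrix {self.raw.shape} does not match {len(self.names)} features"
            )
        if len(self.times) != self.raw.shape[0]:
            raise ValueError("times and rows disagree")
        if np.isnan(self.raw).any():
            self.raw = _impute_forward(self.raw, self.names)
        if self.normalized is None:
            lo = self.raw.min(axis=0)
            hi = self.raw.max(axis=0)
            flat = hi - lo == 0
            if flat.any():
                bad = [n for n, f in zip(self.names, flat) if f]
                raise ValueError(f"constant feature column(s): {', '.join(bad)}")
            self.normalized = (self.raw - lo) / (hi - lo)

    @property
    def n_windows(self) -> int:
        return self.raw.shape[0]


def _impute_forward(raw: np.ndarray, names: list[str]) -> np.ndarray:
    """Carry the previous window's value into NaN cells (backfill the head)."""
    out = raw.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nan = np.isnan(col)
        if nan.all():
            raise ValueError(f"feature {names[j]} is NaN in every window")
        if nan.any():
            logger.warning("imputing %d missing value(s) in %s", nan.sum(), names[j])
            idx = np.where(~nan, np.arange(col.size), 0)
            np.maximum.accumulate(idx, out=idx)
            col[:] = col[idx]
            # leading NaNs (before the first valid value): backfill
            first = np.argmax(~np.isnan(col)) if np.isnan(col[0]) else 0
            col[:first] = col[first]
    return out


@dataclass(frozen=True)
class ClusterConfig:
    """Soft-clustering parameters: 2 clusters, fuzzifier m=2, EM/FCM stop
    at 1000 iterations or objective improvement below 1e-5."""

    n_clusters: int = 2
    m: float = 2.0
    max_iter: int = 1000
    tol: float = 1e-5
    seed: int = 0
    gmm_covariance: str = "full"
    reg_covar: float = 1e-6

    def __post_init__(self):
        if self.m <= 1:
            raise ValueError(f"fuzzifier m must exceed 1, got {self.m}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")


@dataclass
class SoftPartition:
    """A fitted 2-cluster soft partition of the feature matrix."""

    method: str  # "fcm" | "gmm"
    memberships: np.ndarray  # T x 2, rows sum to 1
    centroids: np.ndarray  # 2 x n_features (FCM centres or GMM means)
    model_params: dict = field(default_factory=dict)
    conscious_index: int | None = None
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))


@dataclass
class ConsciousnessTrace:
    """Per-window membership degree to the conscious cluster, in [0, 1]."""

    times: list[datetime]
    values: np.ndarray
    method: str  # "fcm" | "gmm" | "ensemble" | "predefined"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != self.values.size:
            raise ValueError("times and values disagree")


# ---------------------------------------------------------------------------
# fuzzy c-means


def fcm_memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix for fixed centres: u_ic = 1 / sum_j (d_ic/d_ij)^(2/(m-1)).

    Points coincident with a centre get membership 1 there.
    """
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)  # T x c
    zero = d < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = 0.0
        u[hit, zero[hit].argmax(axis=1)] = 1.0
    return u


def fcm_fit(F: FeatureMatrix, cfg: ClusterConfig = ClusterConfig()) -> SoftPartition:
    """Fuzzy c-means on the normalized features (Bezdek alternating updates).

    Starts from a seeded random membership matrix; stops when the weighted
    within-cluster objective improves by less than ``cfg.tol`` or at
    ``cfg.max_iter`` (with a warning).
    """
    X = F.normalized
    T, _ = X.shape
    if T < cfg.n_clusters:
        raise ValueError(f"{T} windows cannot support {cfg.n_clusters} clusters")
    rng = np.random.default_rng(cfg.seed)
    u = rng.random((T, cfg.n_clusters))
    u /= u.sum(axis=1, keepdims=True)
    prev_obj = np.inf
    for it in range(cfg.max_iter):
        um = u ** cfg.m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
        obj = float((um * d**2).sum())
        u = fcm_memberships(X, centers, cfg.m)
        if abs(prev_obj - obj) < cfg.tol:
            break
        prev_obj = obj
    else:
        logger.warning("FCM did not converge in %d iterations", cfg.max_iter)
    part = SoftPartition(
        method="fcm",
        memberships=u,
        centroids=centers,
        model_params={"m": cfg.m, "iterations": it + 1, "objective": obj},
        feature_names=list(F.names),
    )
    return identify_conscious(part)


# ---------------------------------------------------------------------------
# Gaussian mixture


def gmm_fit(F: FeatureMatrix, cfg: ClusterConfig = ClusterConfig()) -> SoftPartition:
    """Two-component Gaussian mixture by EM; memberships are the posterior
    responsibilities.  Covariances are full per-component with additive
    diagonal regularization against singularity."""
    X = F.normalized
    if X.shape[0] < cfg.n_clusters:
        raise ValueError(
            f"{X.shape[0]} windows cannot support {cfg.n_clusters} components"
        )
    gm = GaussianMixture(
        n_components=cfg.n_clusters,
        covariance_type=cfg.gmm_covariance,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        reg_covar=cfg.reg_covar,
        init_params="k-means++",
        random_state=cfg.seed,
    )
    gm.fit(X)
    if not gm.converged_:
        logger.warning("GMM EM did not converge in %d iterations", cfg.max_iter)
    part = SoftPartition(
        method="gmm",
        memberships=gm.predict_proba(X),
        centroids=gm.means_,
        model_params={
            "weights": gm.weights_,
            "covariances": gm.covariances_,
            "covariance_type": cfg.gmm_covariance,
            "converged": bool(gm.converged_),
        },
        feature_names=list(F.names),
    )
    return identify_conscious(part)


# ---------------------------------------------------------------------------
# conscious-cluster identification, traces, ensemble


def identify_conscious(part: SoftPartition) -> SoftPartition:
    """Mark the cluster whose centroid has the larger mean over the
    normalized coordinates as "conscious"; ties break on the Pbeta
    coordinate, and an exact tie on both is a degenerate clustering."""
    means = part.centroids.mean(axis=1)
    if means[0] != means[1]:
        part.conscious_index = int(means.argmax())
        return part
    try:
        j = part.feature_names.index("Pbeta")
    except ValueError:
        j = 1
    beta = part.centroids[:, j]
    if beta[0] == beta[1]:
        raise ValueError(
            "degenerate clustering: centroids tie on mean and on Pbeta"
        )
    part.conscious_index = int(beta.argmax())
    return part


def membership_trace(part: SoftPartition, times: list[datetime]) -> ConsciousnessTrace:
    """The conscious-cluster membership column as a time-stamped trace."""
    if part.conscious_index is None:
        part = identify_conscious(part)
    return ConsciousnessTrace(
        times=times, values=part.memberships[:, part.conscious_index], method=part.method
    )


def ensemble(p1: ConsciousnessTrace, p2: ConsciousnessTrace) -> ConsciousnessTrace:
    """Average ensemble: element-wise mean of two membership traces."""
    if p1.times != p2.times:
        raise ValueError("traces are not aligned in time")
    return ConsciousnessTrace(
        times=p1.times, values=0.5 * (p1.values + p2.values), method="ensemble"
    )


# ---------------------------------------------------------------------------
# pre-defined-centroid mode


def predefined_partition(
    F: FeatureMatrix,
    cfg: ClusterConfig = ClusterConfig(),
    centroids: np.ndarray | None = None,
    gmm_params: dict | None = None,
) -> ConsciousnessTrace:
    """Score windows against fixed cluster centres without any fitting.

    The FCM membership formula is evaluated at ``centroids`` and, when
    ``gmm_params`` (means / covariances / weights) is supplied, GMM
    posteriors at those parameters; the legs are ensemble-averaged.  This
    is the fallback when a recording does not span both states and fitted
    clusters would both represent the same state.
    """
    if centroids is None:
        raise ValueError("predefined mode requires cluster centroids")
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (cfg.n_clusters, len(F.names)):
        raise ValueError(
            f"centroids shape {centroids.shape} != ({cfg.n_clusters}, {len(F.names)})"
        )
    u = fcm_memberships(F.normalized, centroids, cfg.m)
    fcm_part = SoftPartition(
        method="fcm", memberships=u, centroids=centroids, feature_names=list(F.names)
    )
    legs = [membership_trace(fcm_part, F.times)]
    if gmm_params is not None:
        means = np.asarray(gmm_params["means"], dtype=float)
        covs = np.asarray(gmm_params["covariances"], dtype=float)
        weights = np.asarray(gmm_params["weights"], dtype=float)
        logp = np.stack(
            [
                np.log(weights[c])
                + multivariate_normal(means[c], covs[c], allow_singular=True).logpdf(
                    F.normalized
                )
                for c in range(means.shape[0])
            ],
            axis=1,
        )
        logp -= logp.max(axis=1, keepdims=True)
        post = np.exp(logp)
        post /= post.sum(axis=1, keepdims=True)
        gmm_part = SoftPartition(
            method="gmm", memberships=post, centroids=means, feature_names=list(F.names)
        )
        legs.append(membership_trace(gmm_part, F.times))
    if len(legs) == 1:
        out = ConsciousnessTrace(F.times, legs[0].values, "predefined")
    else:
        out = ensemble(legs[0], legs[1])
        out.method = "predefined"
    return out


def fit_reference_model(F: FeatureMatrix, cfg: ClusterConfig = ClusterConfig()) -> dict:
    """Fit FCM centres + GMM parameters on a reference dataset for later use
    in :func:`predefined_partition` on recordings that lack state contrast."""
    fcm = fcm_fit(F, cfg)
    gmm = gmm_fit(F, cfg)
    return {
        "feature_names": list(F.names),
        "fcm_centroids": fcm.centroids,
        "gmm_params": {
            "means": gmm.centroids,
            "covariances": np.asarray(gmm.model_params["covariances"]),
            "weights": np.asarray(gmm.model_params["weights"]),
        },
    }


def save_reference_model(model: dict, path: str | Path) -> Path:
    path = Path(path)
    out = {
        "feature_names": model["feature_names"],
        "fcm_centroids": np.asarray(model["fcm_centroids"]).tolist(),
        "gmm_params": {k: np.asarray(v).tolist() for k, v in model["gmm_params"].items()},
    }
    path.write_text(json.dumps(out, indent=2))
    return path


def load_reference_model(path: str | Path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {
        "feature_names": raw["feature_names"],
        "fcm_centroids": np.asarray(raw["fcm_centroids"], dtype=float),
        "gmm_params": {
            k: np.asarray(v, dtype=float) for k, v in raw["gmm_params"].items()
        },
    }
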