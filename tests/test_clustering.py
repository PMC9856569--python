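from datetime import datetime, timedelta

import numpy as np
import pytest

from ecogstate import (
    FEATURE_NAMES,
    ClusterConfig,
    ConsciousnessTrace,
    FeatureMatrix,
    SoftPartition,
    ensemble,
    fcm_fit,
    gmm_fit,
    identify_conscious,
    membership_trace,
    predefined_partition,
)
from ecogstate.clustering import fcm_memberships


def _times(n):
    t0 = datetime(2024, 1, 1, 0, 0, 0)
    return [t0 + timedelta(seconds=i) for i in range(n)]


def _blobs(rng, n_per=200, sep=6.0, spread=0.3):
    """Two well-separated 7-D Gaussian blobs in feature space."""
    lo = rng.normal(0.0, spread, size=(n_per, 7))
    hi = rng.normal(sep, spread, size=(n_per, 7))
    raw = np.vstack([lo, hi])
    labels = np.array([0] * n_per + [1] * n_per)
    return FeatureMatrix(times=_times(2 * n_per), raw=raw), labels


class TestFeatureMatrix:
    def test_normalized_columns_attain_bounds(self, rng):
        F = FeatureMatrix(times=_times(50), raw=rng.random((50, 7)) * 10 - 3)
        assert np.allclose(F.normalized.min(axis=0), 0.0)
        assert np.allclose(F.normalized.max(axis=0), 1.0)

    def test_constant_column_rejected_by_name(self, rng):
        raw = rng.random((20, 7))
        raw[:, 3] = 0.5
        with pytest.raises(ValueError, match="ERR"):
            FeatureMatrix(times=_times(20), raw=raw)

    def test_missing_values_carried_forward(self, rng):
        raw = rng.random((10, 7))
        raw[4, 2] = np.nan
        raw[0, 5] = np.nan
        F = FeatureMatrix(times=_times(10), raw=raw)
        assert F.raw[4, 2] == F.raw[3, 2]
        assert F.raw[0, 5] == F.raw[1, 5]  # leading gap backfilled
        assert not np.isnan(F.raw).any()


class TestFcm:
    def test_memberships_rows_sum_to_one(self, rng):
        F, _ = _blobs(rng)
        part = fcm_fit(F, ClusterConfig(seed=0))
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((part.memberships >= 0) & (part.memberships <= 1))

    def test_point_at_centroid_full_membership(self):
        centers = np.array([[0.0] * 7, [1.0] * 7])
        u = fcm_memberships(centers[:1], centers, m=2.0)
        assert u[0, 0] == pytest.approx(1.0)

    def test_equidistant_point_half_half(self):
        centers = np.array([[0.0] * 7, [1.0] * 7])
        mid = np.full((1, 7), 0.5)
        u = fcm_memberships(mid, centers, m=2.0)
        np.testing.assert_allclose(u[0], [0.5, 0.5])

    def test_separated_blobs_recovered(self, rng):
        F, labels = _blobs(rng)
        part = fcm_fit(F, ClusterConfig(seed=0))
        hard = part.memberships.argmax(axis=1)
        # match clusters to blobs by centroid mean (low blob -> low centroid)
        order = np.argsort(part.centroids.mean(axis=1))
        mapped = np.where(hard == order[1], 1, 0)
        assert np.mean(mapped == labels) >= 0.99


class TestGmm:
    def test_posteriors_rows_sum_to_one(self, rng):
        F, _ = _blobs(rng)
        part = gmm_fit(F, ClusterConfig(seed=0))
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_point_at_component_mean_confident(self, rng):
        F, labels = _blobs(rng, sep=8.0, spread=0.2)
        part = gmm_fit(F, ClusterConfig(seed=0))
        # the data point closest to each recovered mean is assigned >0.99
        for c in range(2):
            i = np.linalg.norm(F.normalized - part.centroids[c], axis=1).argmin()
            assert part.memberships[i, c] > 0.99

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        n = 400
        mu = np.array([[0.2] * 7, [0.8] * 7])
        sigma = 0.05
        raw = np.vstack(
            [rng.normal(mu[0], sigma, (n, 7)), rng.normal(mu[1], sigma, (n, 7))]
        )
        F = FeatureMatrix(times=_times(2 * n), raw=raw)
        part = gmm_fit(F, ClusterConfig(seed=0))
        order = np.argsort(part.centroids.mean(axis=1))
        # normalized scale: compare against the min-max image of the true means
        lo, hi = raw.min(axis=0), raw.max(axis=0)
        mu_norm = (mu - lo) / (hi - lo)
        sigma_norm = sigma / (hi - lo)
        se = sigma_norm / np.sqrt(n)
        for c, o in enumerate(order):
            np.testing.assert_array_less(
                np.abs(part.centroids[o] - mu_norm[c]), 3 * se
            )


class TestConsciousIdentification:
    def _part(self, centroids):
        return SoftPartition(
            method="fcm",
            memberships=np.full((4, 2), 0.5),
            centroids=np.asarray(centroids, dtype=float),
        )

    def test_higher_centroid_selected(self):
        part = identify_conscious(self._part([[0.2] * 7, [0.8] * 7]))
        assert part.conscious_index == 1

    def test_label_swap_invariance(self):
        a = identify_conscious(self._part([[0.2] * 7, [0.8] * 7]))
        b = identify_conscious(self._part([[0.8] * 7, [0.2] * 7]))
        assert a.conscious_index == 1 and b.conscious_index == 0

    def test_mixed_centroid_majority_mean_wins(self):
        mixed = [0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.1]
        low = [0.3] * 7
        part = identify_conscious(self._part([low, mixed]))
        assert part.conscious_index == 1

    def test_exact_tie_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            identify_conscious(self._part([[0.5] * 7, [0.5] * 7]))


class TestEnsemble:
    def test_elementwise_mean(self):
        t = _times(2)
        p1 = ConsciousnessTrace(t, [0.4, 1.0], "fcm")
        p2 = ConsciousnessTrace(t, [0.6, 0.0], "gmm")
        out = ensemble(p1, p2)
        np.testing.assert_allclose(out.values, [0.5, 0.5])

    def test_identical_traces_identity_and_order_invariance(self, rng):
        t = _times(10)
        v1, v2 = rng.random(10), rng.random(10)
        p1 = ConsciousnessTrace(t, v1, "fcm")
        p2 = ConsciousnessTrace(t, v2, "gmm")
        np.testing.assert_allclose(ensemble(p1, p1).values, v1)
        np.testing.assert_allclose(ensemble(p1, p2).values, ensemble(p2, p1).values)
        out = ensemble(p1, p2).values
        assert np.all(out >= np.minimum(v1, v2)) and np.all(out <= np.maximum(v1, v2))

    def test_misaligned_times_rejected(self):
        p1 = ConsciousnessTrace(_times(3), [0.1, 0.2, 0.3], "fcm")
        p2 = ConsciousnessTrace(_times(3)[::-1], [0.1, 0.2, 0.3], "gmm")
        with pytest.raises(ValueError):
            ensemble(p1, p2)


class TestPredefined:
    def test_point_at_centre_full_membership(self, rng):
        raw = rng.random((30, 7))
        centres = np.array([[0.0] * 7, [1.0] * 7])
        raw[0] = 0.0
        raw[1] = 1.0
        F = FeatureMatrix(times=_times(30), raw=raw)
        trace = predefined_partition(F, ClusterConfig(), centroids=centres)
        assert trace.values[1] == pytest.approx(1.0)  # at the conscious centre
        assert trace.values[0] == pytest.approx(0.0)

    def test_midpoint_half_membership(self):
        raw = np.vstack([np.zeros(7), np.ones(7), np.full(7, 0.5)])
        F = FeatureMatrix(times=_times(3), raw=raw)
        trace = predefined_partition(
            F, ClusterConfig(), centroids=np.array([[0.0] * 7, [1.0] * 7])
        )
        assert trace.values[2] == pytest.approx(0.5)

    def test_matches_fcm_membership_formula(self, rng):
        raw = rng.random((40, 7))
        F = FeatureMatrix(times=_times(40), raw=raw)
        centres = rng.random((2, 7))
        trace = predefined_partition(F, ClusterConfig(), centroids=centres)
        u = fcm_memberships(F.normalized, centres, m=2.0)
        part = SoftPartition(method="fcm", memberships=u, centroids=centres)
        expected = membership_trace(part, F.times).values
        np.testing.assert_allclose(trace.values, expected)

    def test_wrong_dimension_rejected(self, rng):
        F = FeatureMatrix(times=_times(10), raw=rng.random((10, 7)))
        with pytest.raises(ValueError):
            predefined_partition(F, ClusterConfig(), centroids=np.zeros((2, 5)))


def test_feature_names_order():
    assert FEATURE_NAMES == ["Ptheta", "Pbeta", "SEF95", "ERR", "LZC", "iCOHtheta", "wSMI"]
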