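import itertools
from collections import Counter
from math import factorial, log

import numpy as np
import pytest
from scipy import signal as sp_signal

from ecogstate import (
    THETA,
    WsmiParams,
    connectivity_matrix,
    icoh_pair,
    reduce_matrix,
    symbolize,
    wsmi_pair,
)
from ecogstate.synthetic import _band_noise


def wsmi_oracle(x, y, p: WsmiParams) -> float:
    """Exhaustive joint-count wSMI on explicit symbol tables.

    Symbols are the rank tuples themselves; the weight zeroes identical and
    rank-reversed (sign-opposite) pairs.  Entirely independent of the
    package's vectorized encoding.
    """

    def patterns(v):
        out = []
        for t in range(len(v) - (p.k - 1) * p.tau):
            vals = [v[t + j * p.tau] for j in range(p.k)]
            order = sorted(range(p.k), key=lambda i: (vals[i], i))
            ranks = tuple(order.index(i) for i in range(p.k))
            out.append(ranks)
        return out

    sx, sy = patterns(x), patterns(y)
    joint = Counter(zip(sx, sy))
    total = sum(joint.values())
    px = Counter(sx)
    py = Counter(sy)
    acc = 0.0
    for (a, b), c in joint.items():
        opposite = tuple(p.k - 1 - r for r in a)
        w = 0.0 if (a == b or b == opposite) else 1.0
        pab = c / total
        pa = px[a] / total
        pb = py[b] / total
        acc += w * pab * log(pab / (pa * pb))
    return acc / log(factorial(p.k))


class TestIcoh:
    def test_identical_signals_zero(self, rng):
        x = rng.standard_normal(1500)
        assert icoh_pair(x, x, 500.0) == pytest.approx(0.0, abs=1e-12)

    def test_scaled_copy_zero(self, rng):
        x = rng.standard_normal(1500)
        assert icoh_pair(x, 2.0 * x, 500.0) == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_coupling_detected(self, rng):
        # 90-degree-shifted narrowband pair: coherency nearly purely imaginary.
        # A 12-s block gives several theta-band Welch bins beyond DC (where
        # the imaginary part is identically zero).
        n = 6000
        src = _band_noise(rng, 2 * n, 500.0, 2.0, 4.0)
        x = src[:n]
        q = np.imag(sp_signal.hilbert(src))[:n]
        y = q + 0.05 * rng.standard_normal(n)
        assert icoh_pair(x, y, 500.0) > 0.5

    def test_bounded_and_scale_invariant(self, rng):
        x = rng.standard_normal(1500)
        y = rng.standard_normal(1500)
        v = icoh_pair(x, y, 500.0)
        assert 0.0 <= v <= 1.0
        assert icoh_pair(5.0 * x, 0.1 * y, 500.0) == pytest.approx(v, rel=1e-9)

    def test_matches_scipy_csd_route(self, rng):
        """Same theta-band |Im coherency| from scipy's Welch cross-spectra."""
        x = rng.standard_normal(1500)
        y = rng.standard_normal(1500) + 0.5 * x
        nseg = 1500 // 8
        kw = dict(
            fs=500.0, window="hamming", nperseg=nseg, noverlap=nseg // 2,
            detrend=False,
        )
        f, sxy = sp_signal.csd(x, y, **kw)
        _, sxx = sp_signal.welch(x, **kw)
        _, syy = sp_signal.welch(y, **kw)
        coh = sxy / np.sqrt(sxx * syy)
        mask = (f >= THETA.f1) & (f <= THETA.f2)
        expected = np.abs(np.imag(coh[mask])).mean()
        assert icoh_pair(x, y, 500.0) == pytest.approx(expected, rel=1e-8)


class TestSymbolize:
    def test_monotone_series_single_symbol(self):
        s = symbolize(np.arange(100.0), WsmiParams(k=3, tau=2))
        assert len(set(s.tolist())) == 1

    def test_alphabet_size_is_k_factorial(self, rng):
        s = symbolize(rng.standard_normal(20000), WsmiParams(k=3, tau=1))
        assert set(s.tolist()) == set(range(6))

    def test_simple_pattern(self):
        # [1, 3, 2]: low, high, mid -> ranks (0, 2, 1)
        s = symbolize(np.array([1.0, 3.0, 2.0]), WsmiParams(k=3, tau=1))
        assert len(s) == 1
        down = symbolize(np.array([3.0, 2.0, 1.0]), WsmiParams(k=3, tau=1))
        up = symbolize(np.array([1.0, 2.0, 3.0]), WsmiParams(k=3, tau=1))
        assert s[0] not in (down[0], up[0])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            symbolize(np.zeros(16), WsmiParams(k=3, tau=8))


class TestWsmi:
    def test_identical_signals_zero(self, rng):
        x = rng.standard_normal(600)
        assert wsmi_pair(x, x, WsmiParams()) == 0.0

    def test_independent_signals_near_zero(self, rng):
        x = rng.standard_normal(5000)
        y = rng.standard_normal(5000)
        assert abs(wsmi_pair(x, y, WsmiParams(k=3, tau=1))) < 0.02

    def test_symmetry(self, rng):
        x = rng.standard_normal(600)
        y = rng.standard_normal(600)
        p = WsmiParams()
        assert wsmi_pair(x, y, p) == pytest.approx(wsmi_pair(y, x, p), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(600)
        y = rng.standard_normal(600)
        p = WsmiParams(k=3, tau=2)
        base = wsmi_pair(x, y, p)
        assert wsmi_pair(np.exp(x), y**3, p) == pytest.approx(base, abs=1e-12)

    def test_matches_joint_count_oracle_short_sequences(self, rng):
        p = WsmiParams(k=3, tau=1)
        for _ in range(50):
            n = int(rng.integers(10, 31))
            x = rng.standard_normal(n)
            y = np.roll(x, 2) + 0.5 * rng.standard_normal(n)
            assert wsmi_pair(x, y, p) == pytest.approx(
                wsmi_oracle(x, y, p), abs=1e-12
            )

    def test_degenerate_sequence_returns_zero(self):
        x = np.arange(100.0)  # single ascending symbol everywhere
        y = np.arange(100.0)[::-1].copy()
        assert wsmi_pair(x, y, WsmiParams(k=3, tau=2)) == 0.0


class TestMatrix:
    def test_identical_channels_icoh_zero(self, rng):
        x = rng.standard_normal(1500)
        m = connectivity_matrix(np.vstack([x, x]), "icoh", fs=500.0)
        assert m.values[1, 0] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(m.values[0, 0])

    def test_permutation_equivariance(self, rng):
        block = rng.standard_normal((4, 1500))
        perm = [3, 1, 0, 2]
        m = connectivity_matrix(block, "icoh", fs=500.0).values
        mp = connectivity_matrix(block[perm], "icoh", fs=500.0).values
        np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], rtol=1e-10)

    def test_coupled_pair_stands_out(self, rng):
        """The single lag-coupled pair exceeds the 95th percentile of a
        Monte Carlo null of uncoupled channel triples."""
        src = _band_noise(rng, 2000, 500.0, 2.0, 4.0)
        block = np.vstack([
            src[:1500] + 0.2 * rng.standard_normal(1500),
            src[25:1525] + 0.2 * rng.standard_normal(1500),
            rng.standard_normal(1500),
        ])
        m = connectivity_matrix(block, "icoh", fs=500.0).values
        null = [
            connectivity_matrix(rng.standard_normal((2, 1500)), "icoh", fs=500.0).values[1, 0]
            for _ in range(60)
        ]
        thresh = np.quantile(null, 0.95)
        assert m[1, 0] > thresh
        assert m[2, 0] < m[1, 0] and m[2, 1] < m[1, 0]

    def test_reduce_is_lower_triangle_mean(self):
        from ecogstate.connectivity import ConnectivityMatrix

        v = np.full((3, 3), np.nan)
        v[1, 0] = v[0, 1] = 0.1
        v[2, 0] = v[0, 2] = 0.2
        v[2, 1] = v[1, 2] = 0.3
        m = ConnectivityMatrix(values=v, measure="icoh")
        assert reduce_matrix(m) == pytest.approx(0.2)
        # symmetry: upper-triangle mean agrees
        iu = np.triu_indices(3, k=1)
        assert np.mean(v[iu]) == pytest.approx(reduce_matrix(m))

    def test_constant_matrix_reduces_to_constant(self):
        from ecogstate.connectivity import ConnectivityMatrix

        v = np.full((4, 4), 0.4)
        np.fill_diagonal(v, np.nan)
        assert reduce_matrix(ConnectivityMatrix(values=v, measure="wsmi")) == pytest.approx(0.4)

    def test_wsmi_matrix_symmetric(self, rng):
        block = rng.standard_normal((3, 600))
        m = connectivity_matrix(block, "wsmi").values
        np.testing.assert_allclose(m, m.T, equal_nan=True)
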