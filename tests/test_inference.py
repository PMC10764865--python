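"""Cluster permutation, BH correction, mutual information, lagged MI."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ripplemem.inference import (bh_correct, cluster_permutation,
                                 lagged_mi_directionality, mutual_information,
                                 quantile_bins, wilcoxon_paired)


def _enumeration_oracle(d, alpha=0.05, tail="two"):
    """Independent exhaustive sign-flip cluster test for tiny problems."""
    n, m = d.shape
    thr = stats.t.ppf(1 - alpha / 2, n - 1) if tail == "two" else \
        stats.t.ppf(1 - alpha, n - 1)

    def tstat(x):
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mu / (sd / np.sqrt(n))
        return np.where(np.isfinite(t), t, 0.0)

    def clusters(t):
        out, i = [], 0
        while i < m:
            if abs(t[i]) > thr:
                j = i
                while j + 1 < m and abs(t[j + 1]) > thr and \
                        np.sign(t[j + 1]) == np.sign(t[i]):
                    j += 1
                out.append((i, j, t[i : j + 1].sum()))
                i = j + 1
            else:
                i += 1
        return out

    real = clusters(tstat(d))
    null = []
    for signs in itertools.product([1, -1], repeat=n):
        td = tstat(np.array(signs)[:, None] * d)
        cl = clusters(td)
        null.append(max((abs(c[2]) for c in cl), default=0.0))
    null = np.array(null)
    return [(s, e, c, np.mean(null >= abs(c) - 1e-12)) for s, e, c in real]


class TestClusterPermutation:
    def test_identical_conditions_nothing_significant(self, rng):
        a = rng.standard_normal((8, 30))
        res = cluster_permutation(a, a.copy(), n_perm=500, seed=0)
        assert res.clusters == []

    def test_matches_exhaustive_enumeration(self, rng):
        d = rng.standard_normal((6, 4))
        d[:, 1:3] += 2.0  # planted 2-bin difference
        res = cluster_permutation(d, None, n_perm=64, exhaustive=True)
        oracle = _enumeration_oracle(d)
        assert len(res.clusters) == len(oracle)
        for c, (s, e, stat, p) in zip(res.clusters, oracle):
            assert (c.start, c.stop) == (s, e)
            assert c.sum_t == pytest.approx(stat)
            assert c.p == pytest.approx(p)

    def test_planted_effect_detected(self, rng):
        a = rng.standard_normal((10, 40))
        b = rng.standard_normal((10, 40))
        a[:, 10:18] += 1.5
        res = cluster_permutation(a, b, n_perm=500, seed=1)
        sig = res.significant
        assert sig and any(c.start <= 14 <= c.stop for c in sig)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((1, 5)))


class TestBH:
    def test_all_ones_nothing_rejected(self):
        assert not bh_correct([1.0, 1.0, 1.0]).any()

    def test_step_up_oracle(self):
        p = np.array([0.001, 0.02, 0.04, 0.9])
        # hand step-up at q=0.05: sorted p_i <= q*i/m -> largest such i
        # 0.001<=0.0125 T; 0.02<=0.025 T; 0.04<=0.0375 F; 0.9<=0.05 F
        assert bh_correct(p, q=0.05).tolist() == [True, True, False, False]

    def test_q_one_rejects_everything(self):
        assert bh_correct([0.2, 0.9, 1.0], q=1.0).all()

    def test_empty_and_invalid(self):
        assert bh_correct([]).size == 0
        with pytest.raises(ValueError):
            bh_correct([1.5])

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=20)
        r1 = bh_correct(p, q=0.05)
        r2 = bh_correct(p, q=0.2)
        assert np.all(r2 | ~r1)


class TestMutualInformation:
    def test_identity_channel(self, rng):
        x = np.repeat(np.arange(10), 50)
        rng.shuffle(x)
        assert mutual_information(x, x) == pytest.approx(np.log2(10))

    def test_independent_large_sample_near_zero(self, rng):
        x = rng.integers(0, 4, 20000)
        y = rng.integers(0, 4, 20000)
        mi = mutual_information(x, y)
        assert 0 <= mi < 0.01

    def test_two_by_two_entropy_oracle(self):
        x = np.array([0] * 50 + [1] * 50)
        y = np.array([0] * 45 + [1] * 5 + [0] * 5 + [1] * 45)

        def h(ps):
            ps = np.array(ps, dtype=float)
            ps = ps[ps > 0]
            return -(ps * np.log2(ps)).sum()

        expected = h([0.5, 0.5]) + h([0.5, 0.5]) - h([0.45, 0.05, 0.05, 0.45])
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_symmetric(self, rng):
        x = rng.integers(0, 5, 500)
        y = (x + rng.integers(0, 2, 500)) % 5
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mutual_information([], [])
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=60))
    def test_nonnegative(self, xs):
        x = np.array(xs)
        y = np.roll(x, 1)
        assert mutual_information(x, y) >= -1e-12


class TestQuantileBins:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=10, max_size=200),
           st.integers(2, 10))
    def test_uniform_counts(self, xs, k):
        sym = quantile_bins(np.array(xs), k)
        counts = np.bincount(sym[sym >= 0], minlength=k)
        assert counts.max() - counts.min() <= 1

    def test_nan_maps_to_missing(self):
        sym = quantile_bins(np.array([1.0, np.nan, 3.0]), 2)
        assert sym[1] == -1

    def test_deterministic_tie_breaking(self):
        v = np.array([1.0, 1.0, 1.0, 1.0])
        a = quantile_bins(v, 2)
        assert a.tolist() == quantile_bins(v, 2).tolist()
        assert np.bincount(a).tolist() == [2, 2]


class TestLaggedMI:
    def test_identical_traces_symmetric(self, rng):
        sym = [rng.integers(0, 4, (30, 12)) for _ in range(6)]
        diffs, pvals, res = lagged_mi_directionality(sym, sym, n_perm=100, seed=0)
        assert np.allclose(diffs[:, :-1], 0.0, atol=1e-12)

    def test_planted_delay_positive_before_lag(self, rng):
        n_p, n_r, T = 8, 60, 15
        amy, hpc = [], []
        for p in range(n_p):
            latent = rng.integers(0, 4, (n_r, T + 5))
            amy.append(latent[:, 5:])          # AMY carries the future
            hpc.append(latent[:, :T])          # HPC lags by 5 bins
            hpc[-1] = np.where(rng.uniform(size=(n_r, T)) < 0.2,
                               rng.integers(0, 4, (n_r, T)), hpc[-1])
        diffs, pvals, res = lagged_mi_directionality(amy, hpc, n_perm=300, seed=1)
        early = np.nanmean(diffs[:, :5])
        assert early > 0
        assert any(c.sum_t > 0 and c.p < 0.05 for c in res.clusters)

    def test_too_few_bins_rejected(self, rng):
        s = [rng.integers(0, 3, (10, 1))]
        with pytest.raises(ValueError):
            lagged_mi_directionality(s, s)


class TestWilcoxon:
    def test_exact_matches_scipy(self, rng):
        x = rng.standard_normal(12)
        stat, p = wilcoxon_paired(x)
        ref = stats.wilcoxon(x, method="exact")
        assert (stat, p) == (ref.statistic, ref.pvalue)
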