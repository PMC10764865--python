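"""PSV construction, Spearman similarity, ripple-locked traces, nulls."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from ripplemem.hfa import Spectrogram
from ripplemem.rsa import (FISHER_CLIP, PSVSeries, build_psvs, jitter_null,
                           joint_similarity, response_trace, ripple_locked,
                           similarity_matrix, stimulus_specificity)


def _spec(power, rate=100.0, t0=0.0):
    n, m = power.shape
    return Spectrogram(power=power, freqs=np.arange(m, dtype=float),
                       times=t0 + np.arange(n) / rate, rate=rate)


def _psv(vectors):
    vectors = np.asarray(vectors, dtype=float)
    return PSVSeries(vectors=vectors,
                     centers=0.005 + 0.01 * np.arange(len(vectors)),
                     freqs=np.arange(vectors.shape[1], dtype=float))


class TestBuildPSVs:
    def test_two_second_epoch_gives_200_bins(self, rng):
        spec = _spec(rng.standard_normal((400, 5)), rate=100.0)
        psv = build_psvs(spec, (0.0, 2.0))
        assert psv.vectors.shape[0] == 200

    def test_tenth_second_epoch_gives_10_bins(self, rng):
        spec = _spec(rng.standard_normal((100, 5)), rate=100.0)
        psv = build_psvs(spec, (0.0, 0.1))
        assert psv.vectors.shape[0] == 10

    def test_constant_spectrogram_identical_psvs(self):
        spec = _spec(np.tile([1.0, 2.0, 3.0], (300, 1)), rate=100.0)
        psv = build_psvs(spec, (0.0, 2.0))
        assert np.allclose(psv.vectors, psv.vectors[0])

    def test_too_short_epoch_rejected(self, rng):
        spec = _spec(rng.standard_normal((100, 5)), rate=100.0)
        with pytest.raises(ValueError, match="short"):
            build_psvs(spec, (0.0, 0.005))


class TestSimilarity:
    def test_identical_psvs_hit_clip_bound(self, rng):
        v = rng.standard_normal((3, 20))
        sim = similarity_matrix(_psv(v), _psv(v))
        assert np.allclose(np.diag(sim.values), np.arctanh(FISHER_CLIP))

    def test_rank_reversal_hits_negative_bound(self, rng):
        v = rng.standard_normal((1, 20))
        sim = similarity_matrix(_psv(v), _psv(-v))
        assert sim.values[0, 0] == pytest.approx(np.arctanh(-FISHER_CLIP))

    def test_matches_brute_force_spearman(self, rng):
        a = rng.standard_normal((7, 31))
        b = rng.standard_normal((9, 31))
        sim = similarity_matrix(_psv(a), _psv(b))
        for i in range(7):
            for j in range(9):
                rho = spearmanr(a[i], b[j]).statistic
                assert abs(np.tanh(sim.values[i, j]) - rho) < 1e-10

    def test_known_pair_example(self):
        rho = spearmanr([1, 2, 3, 5], [2, 1, 4, 6]).statistic
        sim = similarity_matrix(_psv([[1, 2, 3, 5]]), _psv([[2, 1, 4, 6]]))
        assert np.tanh(sim.values[0, 0]) == pytest.approx(rho, abs=1e-12)

    def test_constant_psv_flagged_zero(self, rng):
        a = np.vstack([np.ones(10), rng.standard_normal(10)])
        sim = similarity_matrix(_psv(a), _psv(rng.standard_normal((2, 10))))
        assert np.all(sim.values[0] == 0.0)
        assert sim.constant_flags[0][0]

    def test_mismatched_frequency_axes_rejected(self, rng):
        with pytest.raises(ValueError, match="frequency"):
            similarity_matrix(_psv(rng.standard_normal((2, 10))),
                              _psv(rng.standard_normal((2, 11))))

    def test_response_trace_is_column_mean(self, rng):
        a = rng.standard_normal((5, 12))
        b = rng.standard_normal((4, 12))
        sim = similarity_matrix(_psv(a), _psv(b))
        assert np.allclose(response_trace(sim), sim.values.mean(axis=0))


class TestRippleLocked:
    def _setup(self, trace):
        times = 10.0 + 0.01 * np.arange(len(trace))
        return [np.asarray(trace)], [times], [10.0]

    def test_constant_trace_locked_constant(self):
        traces, times, starts = self._setup(np.full(200, 3.3))
        lags, rows = ripple_locked(traces, times, [np.array([10.8])], starts)
        assert np.allclose(rows[0][np.isfinite(rows[0])], 3.3)

    def test_delta_peaks_at_zero_lag(self):
        tr = np.zeros(200)
        tr[80] = 1.0
        traces, times, starts = self._setup(tr)
        peak = times[0][80]
        lags, rows = ripple_locked(traces, times, [np.array([peak])], starts)
        assert lags[np.nanargmax(rows[0])] == pytest.approx(0.0)

    def test_pre_window_samples_are_missing(self):
        traces, times, starts = self._setup(np.ones(200))
        lags, rows = ripple_locked(traces, times, [np.array([10.1])], starts)
        assert np.isnan(rows[0][lags < -0.1]).all()
        assert np.isfinite(rows[0][lags >= -0.1]).all()


class TestJitterNull:
    def _args(self, trace, peaks, seed=0, n=200):
        times = 10.0 + 0.01 * np.arange(len(trace))
        return dict(traces=[np.asarray(trace)], trace_times=[times],
                    peaks_by_trial=[np.asarray(peaks)], valid_starts=[10.0],
                    jitter_windows=[(10.0, 10.0 + 0.01 * len(trace))],
                    n_jitter=n, seed=seed)

    def test_constant_trace_z_zero(self):
        res = jitter_null(**self._args(np.full(300, 1.7), [11.0]))
        assert np.allclose(res.zscored[np.isfinite(res.zscored)], 0.0)

    def test_planted_bump_exceeds_null(self, rng):
        tr = rng.standard_normal(300) * 0.1
        tr[95:105] += 3.0
        res = jitter_null(**self._args(tr, [10.0 + 0.01 * 100], n=500))
        k = np.argmin(np.abs(res.lags))
        assert res.similarity[k] > res.null_p95[k]
        assert res.zscored[k] > 2.0

    def test_fixed_seed_reproducible(self, rng):
        tr = rng.standard_normal(300)
        a = jitter_null(**self._args(tr, [11.0], seed=3))
        b = jitter_null(**self._args(tr, [11.0], seed=3))
        assert np.array_equal(a.null_mean, b.null_mean, equal_nan=True)

    def test_few_jitters_warn(self, rng):
        with pytest.warns(UserWarning, match="jitter"):
            jitter_null(**self._args(rng.standard_normal(300), [11.0], n=50))


class TestStimulusSpecificity:
    def _psvs(self, rng, n_trials=6, shared=False, boost=3.0):
        n_f = 40
        templates = [rng.standard_normal(n_f) for _ in range(n_trials)]
        if shared:
            templates = [templates[0]] * n_trials
        enc, rip, post = [], [], []
        for i in range(n_trials):
            enc.append(templates[i] + 0.3 * rng.standard_normal((8, n_f)))
            rip.append(boost * templates[i] + 0.3 * rng.standard_normal((4, n_f)))
            post.append(0.2 * rng.standard_normal((12, n_f)))
        return enc, rip, post

    def test_shared_template_no_specificity(self, rng):
        enc, rip, post = self._psvs(rng, shared=True)
        res = stimulus_specificity(enc, rip, post, n_shuffle=200, seed=0)
        assert abs(res.s_spec.mean()) < 0.1

    def test_distinct_templates_specific_beyond_null(self, rng):
        enc, rip, post = self._psvs(rng, shared=False)
        res = stimulus_specificity(enc, rip, post, n_shuffle=300, seed=0)
        assert res.s_spec.mean() > np.percentile(res.shuffle_means, 95)

    def test_shuffle_null_centered_at_zero(self, rng):
        enc, rip, post = self._psvs(rng, shared=False)
        res = stimulus_specificity(enc, rip, post, n_shuffle=500, seed=1)
        assert abs(np.mean(res.shuffle_means)) < 0.05

    def test_identity_matches_definition(self, rng):
        enc, rip, post = self._psvs(rng)
        res = stimulus_specificity(enc, rip, post, n_shuffle=10, seed=0)
        assert np.allclose(res.s_spec,
                           (res.s_same - res.s_diff)
                           - (res.s_same_avg - res.s_diff_avg))

    def test_single_trial_rejected(self, rng):
        enc, rip, post = self._psvs(rng, n_trials=1)
        with pytest.raises(ValueError):
            stimulus_specificity(enc[:1], rip[:1], post[:1])


class TestJointSimilarity:
    def test_all_ones_gives_ones(self):
        rows = np.ones((5, 11))
        assert np.allclose(joint_similarity(rows, rows), 1.0)

    def test_outer_product_peak_location(self):
        lags = np.round(np.arange(-0.25, 0.2501, 0.01), 10)
        amy = np.exp(-0.5 * ((lags + 0.1) / 0.02) ** 2)[None, :]
        hpc = np.exp(-0.5 * (lags / 0.02) ** 2)[None, :]
        J = joint_similarity(amy, hpc)
        i, j = np.unravel_index(np.nanargmax(J), J.shape)
        assert lags[i] == pytest.approx(-0.1)
        assert lags[j] == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_similarity(np.ones((2, 5)), np.ones((2, 6)))

    def test_empty_gives_nan_matrix(self):
        J = joint_similarity(np.empty((0, 5)), np.empty((0, 5)))
        assert J.shape == (5, 5) and np.isnan(J).all()
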