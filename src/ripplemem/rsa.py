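"""Encoding-response representational similarity and ripple-locked analyses.

Stimulus similarity is the Fisher-transformed Spearman correlation between
z-scored power-spectral vectors (PSVs) of 100-ms bins, computed for every
combination of encoding and response time bins of the same trial. The
response-bin trace (mean over encoding bins) is then sampled in +/-250 ms
windows around hippocampal ripple peaks; chance level comes from circularly
jittering the ripple times within the post-encoding-plus-fixation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .hfa import Spectrogram

__all__ = [
    "PSVSeries",
    "SimilarityMatrix",
    "RippleLockedTrace",
    "StimulusSpecificityResult",
    "build_psvs",
    "similarity_matrix",
    "response_trace",
    "ripple_locked",
    "jitter_null",
    "stimulus_specificity",
    "joint_similarity",
]

FISHER_CLIP = 1.0 - 1e-10
DEFAULT_LAGS = np.round(np.arange(-0.250, 0.2501, 0.010), 10)


@dataclass
class PSVSeries:
    """Per-time-bin power spectral vectors (n_bins, n_freqs)."""

    vectors: np.ndarray
    centers: np.ndarray  # seconds, absolute
    freqs: np.ndarray
    bin_width: float = 0.100
    step: float = 0.010


@dataclass
class SimilarityMatrix:
    """Fisher-z Spearman similarity, encoding bins x response bins."""

    values: np.ndarray
    enc_centers: np.ndarray
    resp_centers: np.ndarray
    constant_flags: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class RippleLockedTrace:
    """Ripple-locked similarity with its jitter null distribution."""

    lags: np.ndarray
    similarity: np.ndarray  # real trace (mean over ripples)
    null_mean: np.ndarray
    null_sd: np.ndarray
    null_p95: np.ndarray
    zscored: np.ndarray  # real trace z-scored against the null
    n_jitter: int


@dataclass
class StimulusSpecificityResult:
    s_same: np.ndarray
    s_diff: np.ndarray
    s_same_avg: np.ndarray
    s_diff_avg: np.ndarray
    s_spec: np.ndarray  # per trial
    shuffle_means: np.ndarray  # null distribution of the mean S_spec


def build_psvs(
    spec: Spectrogram,
    epoch: tuple[float, float],
    bin_width: float = 0.100,
    step: float = 0.010,
) -> PSVSeries:
    """Average normalized power in sliding bins over ``epoch``.

    Bin centers sit at step/2 + k*step from the epoch start and windows are
    truncated at the epoch edges, so a 2-s epoch at 100 ms / 10 ms yields
    exactly 200 bins.
    """
    t0, t1 = epoch
    dur = t1 - t0
    if dur < step:
        raise ValueError("epoch shorter than one PSV step")
    n_bins = int(round(dur / step))
    centers = t0 + step / 2 + step * np.arange(n_bins)
    vectors = np.empty((n_bins, spec.freqs.size))
    times = spec.times
    for k, c in enumerate(centers):
        lo = max(c - bin_width / 2, t0)
        hi = min(c + bin_width / 2, t1)
        m = (times >= lo) & (times < hi)
        if not m.any():
            raise ValueError("epoch not covered by the spectrogram")
        vectors[k] = spec.power[m].mean(axis=0)
    return PSVSeries(vectors=vectors, centers=centers, freqs=spec.freqs,
                     bin_width=bin_width, step=step)


def _rank_z(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-rank each row and z-score; flags rows with zero rank variance."""
    r = rankdata(vectors, axis=1)
    mu = r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd = np.where(sd == 0, 1.0, sd)
    return (r - mu) / sd, flat


def similarity_matrix(enc: PSVSeries, resp: PSVSeries) -> SimilarityMatrix:
    """Spearman correlation (average ranks) of every encoding/response PSV
    pair, Fisher-transformed with clipping at |rho| = 1 - 1e-10.

    Constant PSVs (zero rank variance) yield 0 and are flagged.
    """
    if enc.vectors.shape[1] != resp.vectors.shape[1]:
        raise ValueError("encoding and response PSVs must share the frequency axis")
    n_f = enc.vectors.shape[1]
    a, flat_a = _rank_z(enc.vectors)
    b, flat_b = _rank_z(resp.vectors)
    rho = (a @ b.T) / n_f
    rho[flat_a, :] = 0.0
    rho[:, flat_b] = 0.0
    z = np.arctanh(np.clip(rho, -FISHER_CLIP, FISHER_CLIP))
    return SimilarityMatrix(values=z, enc_centers=enc.centers,
                            resp_centers=resp.centers,
                            constant_flags=(flat_a, flat_b))


def response_trace(sim: SimilarityMatrix) -> np.ndarray:
    """Similarity time series: unweighted mean over encoding bins."""
    return sim.values.mean(axis=0)


def _sample_trace(
    trace: np.ndarray,
    trace_times: np.ndarray,
    peak: float,
    lags: np.ndarray,
    valid_start: float,
) -> np.ndarray:
    """Nearest-bin samples of the similarity trace at peak+lags.

    Samples before ``valid_start`` (encoding overlap) or outside the trace
    are NaN (absent, not zero)."""
    step = trace_times[1] - trace_times[0] if trace_times.size > 1 else 0.010
    t = peak + lags
    idx = np.round((t - trace_times[0]) / step).astype(int)
    out = np.full(lags.size, np.nan)
    ok = (idx >= 0) & (idx < trace.size) & (t >= valid_start)
    out[ok] = trace[idx[ok]]
    return out


def ripple_locked(
    traces: list[np.ndarray],
    trace_times: list[np.ndarray],
    peaks_by_trial: list[np.ndarray],
    valid_starts: list[float],
    lags: np.ndarray = DEFAULT_LAGS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ripple similarity snippets aligned on ripple peaks.

    Returns (lags, matrix of shape (n_ripples, n_lags)); rows keep NaN where
    the window leaves the response period or overlaps the encoding epoch.
    """
    rows = []
    for tr, tt, peaks, v0 in zip(traces, trace_times, peaks_by_trial, valid_starts):
        for p in np.atleast_1d(peaks):
            rows.append(_sample_trace(np.asarray(tr), np.asarray(tt), float(p),
                                      lags, v0))
    if not rows:
        return lags, np.empty((0, lags.size))
    return lags, np.array(rows)


def jitter_null(
    traces: list[np.ndarray],
    trace_times: list[np.ndarray],
    peaks_by_trial: list[np.ndarray],
    valid_starts: list[float],
    jitter_windows: list[tuple[float, float]],
    jitter: float = 0.500,
    n_jitter: int = 1000,
    seed: int = 0,
    lags: np.ndarray = DEFAULT_LAGS,
) -> RippleLockedTrace:
    """Circular-jitter null for the ripple-locked similarity trace.

    Each ripple peak is shifted by U(-jitter, +jitter) and wrapped within its
    trial's window (post-encoding onset to offset of the subsequent cross
    fixation); the per-iteration ripple-average builds the null.
    """
    if n_jitter < 100:
        warnings.warn("fewer than 100 jitters: unstable percentile estimates")
    rng = np.random.default_rng(seed)
    _, real = ripple_locked(traces, trace_times, peaks_by_trial, valid_starts, lags)
    real_avg = np.nanmean(real, axis=0) if real.size else np.full(lags.size, np.nan)

    flat_peaks = []
    for ti, peaks in enumerate(peaks_by_trial):
        for p in np.atleast_1d(peaks):
            flat_peaks.append((ti, float(p)))
    null = np.full((n_jitter, lags.size), np.nan)
    for it in range(n_jitter):
        rows = []
        for ti, p in flat_peaks:
            lo, hi = jitter_windows[ti]
            span = hi - lo
            delta = rng.uniform(-jitter, jitter)
            p2 = lo + (p - lo + delta) % span
            rows.append(_sample_trace(np.asarray(traces[ti]),
                                      np.asarray(trace_times[ti]), p2, lags,
                                      valid_starts[ti]))
        if rows:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                null[it] = np.nanmean(np.array(rows), axis=0)
    mean = np.nanmean(null, axis=0)
    sd = np.nanstd(null, axis=0, ddof=0)
    p95 = np.nanpercentile(null, 95, axis=0)
    # a null with no variability (constant similarity) leaves the real trace
    # exactly at chance; guard against floating-point dust in the null SD
    eps = np.maximum(np.abs(mean), 1.0) * 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (real_avg - mean) / np.where(sd <= eps, np.nan, sd)
    z = np.where((sd <= eps) & (np.abs(real_avg - mean) <= eps), 0.0, z)
    return RippleLockedTrace(lags=lags, similarity=real_avg, null_mean=mean,
                             null_sd=sd, null_p95=p95, zscored=z,
                             n_jitter=n_jitter)


def _mean_fisher_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Mean Fisher-z Spearman similarity between two PSV sets (all bin pairs)."""
    n_f = a.shape[1]
    az, fa = _rank_z(a)
    bz, fb = _rank_z(b)
    rho = (az @ bz.T) / n_f
    rho[fa, :] = 0.0
    rho[:, fb] = 0.0
    return float(np.arctanh(np.clip(rho, -FISHER_CLIP, FISHER_CLIP)).mean())


def stimulus_specificity(
    enc_psvs: list[np.ndarray],
    ripple_psvs: list[np.ndarray],
    post_psvs: list[np.ndarray],
    n_shuffle: int = 1000,
    seed: int = 0,
) -> StimulusSpecificityResult:
    """Stimulus-specific similarity S_spec per trial with an identity-shuffle null.

    For trial i: S_same = sim(Enc_i, Ripple_i), S_diff = mean over j != i of
    sim(Enc_j, Ripple_i); the same contrast on the whole post-encoding window
    (S_same_avg, S_diff_avg) corrects for temporal-proximity inflation:
    S_spec = (S_same - S_diff) - (S_same_avg - S_diff_avg).
    """
    n = len(enc_psvs)
    if n < 2:
        raise ValueError("stimulus specificity requires at least two trials")
    M = np.empty((n, n))       # ripple window i vs encoding j
    Mavg = np.empty((n, n))    # post-encoding window i vs encoding j
    for i in range(n):
        for j in range(n):
            M[i, j] = _mean_fisher_similarity(enc_psvs[j], ripple_psvs[i])
            Mavg[i, j] = _mean_fisher_similarity(enc_psvs[j], post_psvs[i])

    def _spec(perm: np.ndarray) -> tuple[np.ndarray, ...]:
        same = M[np.arange(n), perm]
        same_avg = Mavg[np.arange(n), perm]
        diff = (M.sum(axis=1) - same) / (n - 1)
        diff_avg = (Mavg.sum(axis=1) - same_avg) / (n - 1)
        return same, diff, same_avg, diff_avg

    ident = np.arange(n)
    s_same, s_diff, s_same_avg, s_diff_avg = _spec(ident)
    s_spec = (s_same - s_diff) - (s_same_avg - s_diff_avg)

    rng = np.random.default_rng(seed)
    shuffle_means = np.empty(n_shuffle)
    for k in range(n_shuffle):
        perm = rng.permutation(n)
        a, b, c, d = _spec(perm)
        shuffle_means[k] = ((a - b) - (c - d)).mean()
    return StimulusSpecificityResult(s_same=s_same, s_diff=s_diff,
                                     s_same_avg=s_same_avg,
                                     s_diff_avg=s_diff_avg, s_spec=s_spec,
                                     shuffle_means=shuffle_means)


def joint_similarity(
    amy_rows: np.ndarray,
    hpc_rows: np.ndarray,
) -> np.ndarray:
    """Ripple-averaged outer product of the two regions' locked traces.

    ``amy_rows`` and ``hpc_rows`` are (n_ripples, n_lags) matrices aligned on
    the same ripple peaks; NaN samples are excluded pairwise from the mean.
    """
    if amy_rows.shape != hpc_rows.shape:
        raise ValueError("per-ripple traces must be time-aligned and equal-shaped")
    if amy_rows.shape[0] == 0:
        return np.full((amy_rows.shape[1], amy_rows.shape[1]), np.nan)
    prod = amy_rows[:, :, None] * hpc_rows[:, None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(prod, axis=0)
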