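"""Shared statistics: cluster-based permutation tests, Benjamini-Hochberg
correction, Wilcoxon comparisons, and lagged mutual-information directionality.

The cluster test is the standard paired sign-flip maximum-cluster-sum
procedure: per-bin paired t statistics, clusters of contiguous suprathreshold
bins, and a null built from label exchanges (exhaustive when feasible).
Mutual information is the plug-in estimate H(X) + H(Y) - H(X,Y) in bits on
uniform-count (quantile) bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ClusterResult",
    "cluster_permutation",
    "bh_correct",
    "mutual_information",
    "quantile_bins",
    "wilcoxon_paired",
    "lagged_mi_directionality",
]


@dataclass(frozen=True)
class Cluster:
    start: int  # first bin (inclusive)
    stop: int   # last bin (inclusive)
    sum_t: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    threshold: float
    n_perm: int
    tail: str
    null_max: np.ndarray

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < 0.05]


def _paired_t(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mu = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mu / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _find_clusters(t: np.ndarray, thr: float, tail: str) -> list[tuple[int, int, float]]:
    if tail == "greater":
        supra = t > thr
    elif tail == "less":
        supra = t < -thr
    else:
        supra = np.abs(t) > thr
    out = []
    i = 0
    m = t.size
    while i < m:
        if supra[i]:
            j = i
            sign = np.sign(t[i])
            while j + 1 < m and supra[j + 1] and np.sign(t[j + 1]) == sign:
                j += 1
            out.append((i, j, float(t[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def _max_cluster_stats(t_mat: np.ndarray, thr: float, tail: str) -> np.ndarray:
    out = np.zeros(t_mat.shape[0])
    for k, t in enumerate(t_mat):
        cl = _find_clusters(t, thr, tail)
        if cl:
            out[k] = max(abs(c[2]) for c in cl)
    return out


def cluster_permutation(
    a: np.ndarray,
    b: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    tail: str = "two",
    seed: int = 0,
    exhaustive: bool | None = None,
) -> ClusterResult:
    """Paired cluster-based permutation test on per-participant traces.

    ``a`` and ``b`` are (n_participants, n_bins); ``b=None`` tests ``a``
    against zero. Clusters of contiguous bins with per-bin paired-t p < alpha
    are scored by their summed t; the null is the maximum |cluster sum| over
    sign-flipped differences. All 2^n flips are enumerated when 2^n <= n_perm
    or ``exhaustive`` is set.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    n, m = d.shape
    if n < 2:
        raise ValueError("need at least two participants")
    if tail == "two":
        thr = stats.t.ppf(1 - alpha / 2, n - 1)
    else:
        thr = stats.t.ppf(1 - alpha, n - 1)
    t_real = _paired_t(d)
    clusters = _find_clusters(t_real, thr, tail)

    if exhaustive is None:
        exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n)] for k in range(2**n)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    # paired t under sign flips: sum(d_i^2) is flip-invariant
    ss = (d**2).sum(axis=0)
    mu_p = signs @ d / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var_p = (ss / n - mu_p**2) * n / (n - 1)
        t_mat = mu_p / np.sqrt(var_p / n)
    t_mat = np.where(np.isfinite(t_mat), t_mat, 0.0)
    null_max = _max_cluster_stats(t_mat, thr, tail)

    out = []
    for s, e, st in clusters:
        if exhaustive:
            p = float(np.mean(null_max >= abs(st) - 1e-12))
        else:
            p = float((1 + np.sum(null_max >= abs(st) - 1e-12)) / (1 + len(null_max)))
        out.append(Cluster(start=s, stop=e, sum_t=st, p=p))
    return ClusterResult(clusters=out, t_values=t_real, threshold=thr,
                         n_perm=len(signs), tail=tail, null_max=null_max)


def bh_correct(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def mutual_information(x, y, base: float = 2.0) -> float:
    """Plug-in mutual information between two symbol sequences (bits).

    MI = H(X) + H(Y) - H(X, Y) from the empirical joint distribution.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or x.size != y.size:
        raise ValueError("x and y must be equal-length and non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).astype(float)
    joint /= joint.sum()

    def _h(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p)) / np.log(base)

    jm = joint.reshape(nx, ny)
    return float(_h(jm.sum(axis=1)) + _h(jm.sum(axis=0)) - _h(joint))


def quantile_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Uniform-count (quantile) binning with deterministic tie-breaking.

    Values are ranked by (value, index) via a stable sort; bin counts differ
    by at most one. NaNs map to -1.
    """
    values = np.asarray(values, dtype=float).ravel()
    out = np.full(values.size, -1, dtype=int)
    ok = np.flatnonzero(np.isfinite(values))
    if ok.size == 0:
        return out
    pos = np.empty(ok.size, dtype=int)
    pos[np.argsort(values[ok], kind="stable")] = np.arange(ok.size)
    out[ok] = (pos * n_bins) // ok.size
    return out


def wilcoxon_paired(x, y=None, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test (exact for n <= 25, normal approx. above)."""
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    method = "exact" if (d.size <= 25 and not np.any(d == 0)) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def lagged_mi_directionality(
    amy_symbols: list[np.ndarray],
    hpc_symbols: list[np.ndarray],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, ClusterResult]:
    """Directional lagged-MI contrast across participants.

    Inputs are per-participant (n_ripples, n_time_bins) symbol matrices
    (already quantile-binned with global edges; -1 marks missing). For each
    time bin t, MI_AMY->HPC(t) is the mean MI between the amygdala symbols at
    t and the hippocampal symbols at every strictly later bin (and symmetric
    for HPC->AMY). Returns (per-participant difference traces, per-bin
    Wilcoxon p-values, cluster-permutation result on the difference).
    """
    n_p = len(amy_symbols)
    if n_p != len(hpc_symbols) or n_p == 0:
        raise ValueError("need matched per-participant symbol matrices")
    T = amy_symbols[0].shape[1]
    if T < 2:
        raise ValueError("need at least two lag bins")
    diffs = np.full((n_p, T), np.nan)
    for p in range(n_p):
        A, H = amy_symbols[p], hpc_symbols[p]
        mi = np.full((T, T), np.nan)
        for t1 in range(T):
            for t2 in range(T):
                ok = (A[:, t1] >= 0) & (H[:, t2] >= 0)
                if ok.sum() >= 2:
                    mi[t1, t2] = mutual_information(A[ok, t1], H[ok, t2])
        for t in range(T - 1):
            fwd = mi[t, t + 1 :]
            bwd = mi[t + 1 :, t]
            diffs[p, t] = np.nanmean(fwd) - np.nanmean(bwd)
    valid = ~np.isnan(diffs).any(axis=0)
    pvals = np.full(T, np.nan)
    for t in np.flatnonzero(valid):
        col = diffs[:, t]
        if np.allclose(col, 0):
            pvals[t] = 1.0
        else:
            _, pvals[t] = wilcoxon_paired(col)
    dd = diffs[:, valid]
    cluster = cluster_permutation(dd, None, n_perm=n_perm, alpha=alpha,
                                  tail="two", seed=seed)
    return diffs, pvals, cluster
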