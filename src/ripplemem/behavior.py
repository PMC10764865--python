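"""Behavioral scoring and the trial-level logistic mixed-effects model.

Discrimination is scored as Repeat->Old, Lure->New, Novel->New. The Lure
Discrimination Index LDI = P(New|Lure) - P(New|Repeat) corrects for a
general New-response bias. The effect of encoded-stimulus valence, arousal
and lure-pair similarity on correct Lure discrimination is estimated with a
random-intercept logistic model fitted by maximum likelihood (Gauss-Hermite
quadrature over the participant intercepts), with predictors normalized to
[0, 1] relative to their rating scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

__all__ = [
    "BehavioralFit",
    "score_discrimination",
    "accuracy_by_type",
    "ldi",
    "normalize_ratings",
    "fit_logistic_lme",
]

NOVEL_INCLUSION_ACC = 85.0  # percent; participant screening threshold

RATING_SCALES = {"valence": (1.0, 9.0), "arousal": (1.0, 9.0),
                 "lure_similarity": (1.0, 8.0)}


@dataclass
class BehavioralFit:
    """Fixed effects of the random-intercept logistic model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma_u: float
    loglike: float
    converged: bool
    separation_flag: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se,
                             "t": self.tvalues, "p": self.pvalues},
                            index=self.names)


def score_discrimination(table: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh the ``correct`` column for retrieval trials.

    Trials without a response are flagged excluded. Participants with Novel
    accuracy below 85% are marked excluded on all their rows.
    """
    t = table.copy()
    ret = t["phase"] == "retrieval"
    missing = ret & t["response"].isna()
    t.loc[missing, "excluded"] = True
    expected = t["type"].map({"Repeat": "Old", "Lure": "New", "Novel": "New"})
    t.loc[ret, "correct"] = t.loc[ret, "response"] == expected[ret]
    for pid, grp in t[ret & ~t["excluded"]].groupby("participant"):
        nov = grp[grp["type"] == "Novel"]
        if len(nov) and 100.0 * nov["correct"].mean() < NOVEL_INCLUSION_ACC:
            t.loc[t["participant"] == pid, "excluded"] = True
    return t


def accuracy_by_type(table: pd.DataFrame) -> pd.Series:
    """Percent correct per retrieval trial type (excluded trials dropped)."""
    ret = table[(table["phase"] == "retrieval") & (~table["excluded"])]
    return 100.0 * ret.groupby("type")["correct"].mean()


def ldi(table: pd.DataFrame) -> float:
    """Lure Discrimination Index: P(New|Lure) - P(New|Repeat)."""
    ret = table[(table["phase"] == "retrieval") & (~table["excluded"])]
    lure = ret[ret["type"] == "Lure"]
    rep = ret[ret["type"] == "Repeat"]
    if len(lure) == 0 or len(rep) == 0:
        raise ValueError("LDI undefined without both Lure and Repeat trials")
    return float((lure["response"] == "New").mean()
                 - (rep["response"] == "New").mean())


def normalize_ratings(values: np.ndarray, scale: tuple[float, float]) -> np.ndarray:
    lo, hi = scale
    return (np.asarray(values, dtype=float) - lo) / (hi - lo)


def _glmm_negloglike(params, X, y, groups, nodes, weights, grad=False):
    k = X.shape[1]
    beta = params[:k]
    sigma = np.exp(params[k])
    eta = X @ beta
    ll = 0.0
    g_beta = np.zeros(k)
    g_logsig = 0.0
    for g in np.unique(groups):
        m = groups == g
        # GH quadrature over u ~ N(0, sigma^2): u = sigma * node
        lp = eta[m][:, None] + sigma * nodes[None, :]
        yv = y[m][:, None]
        loglik_nodes = np.sum(yv * lp - np.logaddexp(0.0, lp), axis=0)
        mx = loglik_nodes.max()
        wexp = weights * np.exp(loglik_nodes - mx)
        Z = wexp.sum()
        ll += mx + np.log(Z)
        if grad:
            resid = yv - 1.0 / (1.0 + np.exp(-lp))  # (n_g, Q)
            post = wexp / Z
            g_beta += X[m].T @ (resid @ post)
            g_logsig += float(post @ (resid.sum(axis=0) * sigma * nodes))
    if grad:
        return -ll, -np.concatenate([g_beta, [g_logsig]])
    return -ll


def fit_logistic_lme(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = ("valence", "arousal", "lure_similarity"),
    n_quad: int = 25,
    ridge: float = 0.0,
) -> BehavioralFit:
    """Random-intercept logistic regression of Lure responses (1 = New).

    Predictors are normalized to [0, 1] relative to their rating scales.
    Maximum likelihood via Gauss-Hermite quadrature; standard errors from
    the numerical Hessian at the optimum. Apparent separation (any |beta|
    above 15) triggers a flagged ridge-penalized refit.
    """
    lure = table[(table["phase"] == "retrieval") & (table["type"] == "Lure")
                 & (~table["excluded"]) & table["response"].notna()]
    if lure["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    y = (lure["response"] == "New").to_numpy(dtype=float)
    cols = [np.ones(len(lure))]
    names = ["intercept"]
    for p in predictors:
        cols.append(normalize_ratings(lure[p].to_numpy(), RATING_SCALES[p]))
        names.append(p)
    X = np.column_stack(cols)
    groups = lure["participant"].to_numpy()
    nodes, weights = hermegauss(n_quad)
    weights = weights / np.sqrt(2 * np.pi)

    def obj(params):
        nll, g = _glmm_negloglike(params, X, y, groups, nodes, weights,
                                  grad=True)
        if ridge > 0:
            nll += ridge * np.sum(params[: X.shape[1]] ** 2)
            g[: X.shape[1]] += 2 * ridge * params[: X.shape[1]]
        return nll, g

    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.log(0.5)
    res = optimize.minimize(obj, x0, method="BFGS", jac=True,
                            options={"gtol": 1e-8, "maxiter": 1000})
    k = X.shape[1]
    separation = bool(np.any(np.abs(res.x[:k]) > 15))
    if separation and ridge == 0.0:
        fit = fit_logistic_lme(table, predictors, n_quad, ridge=1e-3)
        fit.separation_flag = True
        return fit

    # SEs from the observed information (numerical Hessian)
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(res.x, lambda p: obj(p)[0])
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(res.x.size, np.nan)
    beta = res.x[:k]
    se = se_all[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.norm.sf(np.abs(t))
    return BehavioralFit(names=names, beta=beta, se=se, tvalues=t, pvalues=p,
                         sigma_u=float(np.exp(res.x[k])), loglike=-res.fun,
                         converged=bool(res.success),
                         separation_flag=separation)
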