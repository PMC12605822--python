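"""Outcome-discrimination statistics.

Rank-based AUC (with its Mann-Whitney identity), one-sided two-group rank
test, binomial logistic regression with likelihood-ratio model
comparison, Yates-corrected chi-square for contingency tables, and a
stratified bootstrap for AUC confidence intervals.

Conventions: outcome labels are binary with 1 = good (seizure-free
analogue).  The one-sided alternative throughout is "good outcomes have
larger scores" (a larger proportion of their abnormalities resected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "OutcomeEvaluation", "LogisticModelFit", "ContingencyResult",
    "auc_two_group", "rank_test_one_sided", "fit_logistic",
    "likelihood_ratio_compare", "chi2_contingency", "bootstrap_auc",
    "evaluate_category",
]


@dataclass
class OutcomeEvaluation:
    category: str
    n_good: int
    n_poor: int
    auc: float
    statistic: float
    p_one_sided: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_resamples: int | None = None


@dataclass
class LogisticModelFit:
    predictors: list[str]
    coef: np.ndarray
    loglik: float
    n: int
    converged: bool
    separation_warning: bool = False

    @property
    def n_params(self) -> int:
        return len(self.coef)


@dataclass
class ContingencyResult:
    observed: np.ndarray
    statistic: float
    df: int
    p: float
    continuity_correction: bool


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    good = scores[labels == 1]
    poor = scores[labels == 0]
    if len(good) == 0 or len(poor) == 0:
        raise ValueError("both outcome groups must be non-empty")
    return good, poor


def auc_two_group(scores, labels) -> float:
    """AUC = P(score_good > score_poor) + 0.5 P(tie), via the Mann-Whitney
    statistic; AUC > 0.5 means good outcomes have larger scores."""
    good, poor = _split(scores, labels)
    u = stats.mannwhitneyu(good, poor, alternative="greater").statistic
    return float(u) / (len(good) * len(poor))


def rank_test_one_sided(scores, labels) -> tuple[float, float]:
    """One-sided two-group rank-sum test (alternative: good > poor).

    Exact null distribution for small tie-free samples, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    good, poor = _split(scores, labels)
    pooled = np.concatenate([good, poor])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and len(good) * len(poor) <= 400) \
        else "asymptotic"
    res = stats.mannwhitneyu(good, poor, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def fit_logistic(predictors, outcome, names=None) -> LogisticModelFit:
    """Maximum-likelihood binomial logistic fit (Newton/IRLS, intercept
    always included).  Perfect separation is flagged, not silently hidden.
    """
    y = np.asarray(outcome, dtype=float)
    if predictors is None:
        X = np.empty((len(y), 0))
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if X.shape[0] != len(y):
        raise ValueError("predictor rows must match outcome length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few observations for the number of predictors")
    if X.shape[1] and (X.std(axis=0) == 0).any():
        raise ValueError("constant predictor column (collinear with intercept)")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    design = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, design).fit(method="newton", maxiter=50,
                                          tol=1e-8, disp=False)
            coef = np.asarray(fit.params)
            llf = float(fit.llf)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:  # perfect separation can abort the solver
            separation = True
            fit = sm.Logit(y, design).fit_regularized(alpha=1e-6, disp=False)
            coef = np.asarray(fit.params)
            llf = float(fit.llf)
            converged = False
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
            if "convergence" in str(w.message).lower():
                converged = False
    if separation:
        warnings.warn("possible perfect separation; coefficients unstable")
    return LogisticModelFit(["const"] + list(names), coef, llf, len(y),
                            converged, separation)


def likelihood_ratio_compare(fit_a: LogisticModelFit, fit_b: LogisticModelFit
                             ) -> tuple[float, float, bool]:
    """LR statistic 2*(ll_big - ll_small) with chi-square reference.

    Returns (statistic, p, non_nested).  Models whose predictor sets are
    not nested get non_nested=True; with zero parameter difference the
    chi-square reference is undefined and p is NaN.
    """
    if fit_a.n != fit_b.n:
        raise ValueError("models were fitted on different sample sizes")
    small, big = sorted((fit_a, fit_b), key=lambda f: f.n_params)
    non_nested = not set(small.predictors) <= set(big.predictors)
    statistic = 2.0 * (big.loglik - small.loglik)
    df = big.n_params - small.n_params
    if df > 0:
        p = float(stats.chi2.sf(statistic, df))
    else:
        statistic = abs(statistic)
        # zero added parameters: no evidence either way when the
        # log-likelihoods agree; otherwise the chi-square reference is
        # undefined (non-nested comparison of equal-size models)
        if statistic < 1e-12:
            p = 1.0
        else:
            p = float("nan")
            non_nested = True
    if non_nested:
        warnings.warn("likelihood-ratio comparison of non-nested models; "
                      "the chi-square reference distribution is heuristic")
    return float(statistic), p, non_nested


def chi2_contingency(table, continuity_correction: bool = True) -> ContingencyResult:
    """Pearson chi-square on a contingency table (Yates correction for 2x2)."""
    obs = np.asarray(table)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs < 0).any() or not np.array_equal(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    obs = obs.astype(np.int64)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the contingency table")
    res = stats.chi2_contingency(obs, correction=continuity_correction)
    return ContingencyResult(obs, float(res.statistic), int(res.dof),
                             float(res.pvalue), continuity_correction)


def bootstrap_auc(scores, labels, n_resamples: int = 1000, seed: int = 0,
                  level: float = 0.95) -> tuple[float, float]:
    """Percentile CI for the AUC under stratified resampling (resampling
    with replacement within each outcome group, preserving group sizes)."""
    good, poor = _split(scores, labels)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_resamples)
    ng, np_ = len(good), len(poor)
    for i in range(n_resamples):
        g = good[rng.integers(0, ng, ng)]
        p = poor[rng.integers(0, np_, np_)]
        u = stats.mannwhitneyu(g, p, alternative="greater").statistic
        aucs[i] = u / (ng * np_)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate_category(scores, labels, category: str = "",
                      n_resamples: int | None = None, seed: int = 0
                      ) -> OutcomeEvaluation:
    """AUC + one-sided rank test (+ optional bootstrap CI) for one category.

    NaN scores (patients with an empty abnormal set in this category) are
    excluded before any statistic is computed.
    """
    good, poor = _split(scores, labels)
    auc = auc_two_group(scores, labels)
    statistic, p = rank_test_one_sided(scores, labels)
    ev = OutcomeEvaluation(category, len(good), len(poor), auc, statistic, p)
    if n_resamples:
        ev.ci_low, ev.ci_high = bootstrap_auc(scores, labels, n_resamples, seed)
        ev.n_resamples = n_resamples
    return ev
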