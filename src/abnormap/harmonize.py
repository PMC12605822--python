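"""Empirical-Bayes location/scale harmonization of regional features (ComBat).

Removes additive and multiplicative scanner/protocol (batch) effects from
subjects x regions feature matrices while preserving age/sex covariate
structure, using the classic parametric empirical-Bayes formulation:
per-region standardization against a covariate model, method-of-moments
hyperpriors across regions within batch (normal prior on batch locations,
inverse-gamma on batch scales), and iterative conditional estimation of
the shrunken batch parameters.

The estimator can be fitted on one table (e.g. controls only) and applied
to another (patients), so that patient-specific pathology is not absorbed
into the batch model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CombatModel", "ComBatHarmonizer", "fit_combat", "apply_combat"]


@dataclass
class CombatModel:
    """Fitted harmonization parameters.

    alpha: per-region intercept (grand batch-weighted mean).
    beta: covariates x regions coefficient matrix.
    sigma: pooled per-region residual SD.
    gamma_star / delta_star: EB-shrunk per-batch location and scale,
        shape (n_batches, n_regions).
    """

    regions: list[str]
    batches: list
    covariates: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    flagged: list[str]

    def to_json(self) -> str:
        return json.dumps({
            "regions": self.regions,
            "batches": [str(b) for b in self.batches],
            "covariates": self.covariates,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "flagged": self.flagged,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CombatModel":
        d = json.loads(text)
        return cls(d["regions"], d["batches"], d["covariates"],
                   np.array(d["alpha"]), np.array(d["beta"]),
                   np.array(d["sigma"]), np.array(d["gamma_star"]),
                   np.array(d["delta_star"]), d["flagged"])


def _postmean(ghat, gbar, n, dstar, t2):
    return (t2 * n * ghat + dstar * gbar) / (t2 * n + dstar)


def _postvar(ssq, n, lam, theta):
    return (0.5 * ssq + theta) / (0.5 * n + lam - 1.0)


class ComBatHarmonizer(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes batch harmonization, sklearn-style.

    Parameters
    ----------
    tol, max_iter : convergence of the iterative conditional estimation of
        the shrunken batch parameters.
    keep_covariates : when True (standard behaviour) the covariate
        contributions are restored in the output; when False the output is
        additionally covariate-adjusted (intercept + residual only), which
        is the form used to build normative maps.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 100,
                 keep_covariates: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.keep_covariates = keep_covariates

    def fit(self, X: pd.DataFrame, y=None, *, batch, covariates=None
            ) -> "ComBatHarmonizer":
        """Estimate the batch model.

        X : subjects x regions frame. batch : length-n labels.
        covariates : n x p frame/array (e.g. age, sex); may be None.
        """
        X = pd.DataFrame(X)
        Y = X.to_numpy(dtype=float)
        n, nr = Y.shape
        batch = np.asarray(batch)
        if covariates is None:
            C = np.empty((n, 0))
            cov_names: list[str] = []
        else:
            cov = pd.DataFrame(covariates)
            cov_names = [str(c) for c in cov.columns]
            C = cov.to_numpy(dtype=float)
        if not np.isfinite(C).all():
            raise ValueError("covariates must be complete (no NaN)")

        levels = list(pd.unique(batch))
        counts = np.array([(batch == b).sum() for b in levels])
        if (counts < 2).any():
            bad = levels[int(np.argmin(counts))]
            raise ValueError(f"batch {bad!r} has fewer than 2 subjects")

        # design: batch indicators + covariates (no global intercept;
        # the batch block spans it)
        B = np.stack([(batch == b).astype(float) for b in levels], axis=1)
        D = np.hstack([B, C])
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            raise ValueError("singular design: covariates are collinear "
                             "with the batch indicators or each other")
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        gamma_hat_ls = coef[:len(levels)]          # per-batch intercepts
        beta = coef[len(levels):]                  # covariate effects

        w = counts / counts.sum()
        alpha = w @ gamma_hat_ls                   # batch-weighted grand mean
        fitted = D @ coef
        resid = Y - fitted
        sigma2 = (resid ** 2).sum(axis=0) / n
        sigma = np.sqrt(sigma2)

        scale = np.abs(Y).mean(axis=0) + 1e-30
        tiny = sigma <= 1e-10 * scale
        flagged = [str(r) for r, t, s in zip(X.columns, tiny, sigma)
                   if t or not np.isfinite(s)]
        sigma = np.where(tiny, 0.0, sigma)
        if flagged:
            warnings.warn(f"zero-variance regions passed through unadjusted: {flagged}")
        ok = sigma > 0
        safe_sigma = np.where(ok, sigma, 1.0)

        stand_mean = alpha[None, :] + C @ beta
        Z = (Y - stand_mean) / safe_sigma[None, :]

        n_lev = len(levels)
        gamma_star = np.zeros((n_lev, nr))
        delta_star = np.ones((n_lev, nr))
        for bi, b in enumerate(levels):
            mask = batch == b
            nb = int(mask.sum())
            Zb = Z[mask]
            ghat = Zb.mean(axis=0)
            dhat = Zb.var(axis=0, ddof=0)
            # method-of-moments hyperpriors across regions
            gbar = ghat.mean()
            t2 = ghat.var(ddof=1) if nr > 1 else 0.0
            m = dhat.mean()
            s2 = dhat.var(ddof=1) if nr > 1 else 0.0
            if s2 <= 1e-12 * max(m * m, 1e-30):
                # no spread across regions: EB shrinkage is undefined,
                # keep the per-region estimates (also the single-batch
                # identity case, where ghat = 0 and dhat = 1 exactly)
                gamma_star[bi] = ghat
                delta_star[bi] = np.sqrt(np.maximum(dhat, 1e-30))
                continue
            lam = (m * m + 2.0 * s2) / s2
            theta = (m ** 3 + m * s2) / s2
            g_old, d_old = ghat.copy(), dhat.copy()
            for _ in range(self.max_iter):
                g_new = _postmean(ghat, gbar, nb, d_old, t2)
                ssq = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = _postvar(ssq, nb, lam, theta)
                change = max(np.abs(g_new - g_old).max(),
                             np.abs(d_new - d_old).max())
                g_old, d_old = g_new, d_new
                if change < self.tol:
                    break
            gamma_star[bi] = g_old
            delta_star[bi] = np.sqrt(d_old)

        self.model_ = CombatModel(
            regions=[str(c) for c in X.columns], batches=levels,
            covariates=cov_names, alpha=alpha, beta=beta, sigma=sigma,
            gamma_star=gamma_star, delta_star=delta_star, flagged=flagged,
        )
        self.n_features_in_ = nr
        return self

    def transform(self, X: pd.DataFrame, *, batch, covariates=None) -> pd.DataFrame:
        """Harmonize a table with a fitted model (regions must match)."""
        m = self.model_
        X = pd.DataFrame(X)
        if [str(c) for c in X.columns] != m.regions:
            raise ValueError("region columns do not match the fitted model")
        Y = X.to_numpy(dtype=float)
        n = Y.shape[0]
        batch = np.asarray(batch)
        unseen = set(pd.unique(batch)) - set(m.batches)
        if unseen:
            raise ValueError(f"unseen batch level(s): {sorted(map(str, unseen))}")
        if covariates is None:
            if m.covariates:
                raise ValueError("model was fitted with covariates; none given")
            C = np.empty((n, 0))
        else:
            C = pd.DataFrame(covariates).to_numpy(dtype=float)
            if C.shape[1] != len(m.covariates):
                raise ValueError("covariate count does not match the fitted model")

        ok = m.sigma > 0
        safe_sigma = np.where(ok, m.sigma, 1.0)
        stand_mean = m.alpha[None, :] + C @ m.beta
        Z = (Y - stand_mean) / safe_sigma[None, :]
        out = Y.copy()
        for bi, b in enumerate(m.batches):
            mask = batch == b
            if not mask.any():
                continue
            adj = (Z[mask] - m.gamma_star[bi][None, :]) / m.delta_star[bi][None, :]
            restore = m.alpha[None, :] + (C[mask] @ m.beta if self.keep_covariates
                                          else 0.0)
            out[mask] = adj * safe_sigma[None, :] + restore
        # zero-variance regions pass through unchanged
        out[:, ~ok] = Y[:, ~ok]
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def fit_combat(X: pd.DataFrame, batch, covariates=None, **kwargs) -> ComBatHarmonizer:
    """Convenience wrapper returning a fitted :class:`ComBatHarmonizer`."""
    return ComBatHarmonizer(**kwargs).fit(X, batch=batch, covariates=covariates)


def apply_combat(harmonizer: ComBatHarmonizer, X: pd.DataFrame, batch,
                 covariates=None) -> pd.DataFrame:
    return harmonizer.transform(X, batch=batch, covariates=covariates)
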