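"""Normative maps and patient z-scoring.

A normative map is the per-region mean and SD of a feature in healthy
controls (after harmonization and covariate adjustment); patients are
z-scored against it, so each regional z measures deviation from the
healthy mean in control-SD units.  Region labels can be re-oriented from
anatomical left/right to ipsilateral/contralateral using each patient's
seizure-focus side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import RegionTable

__all__ = ["NormativeMap", "NormativeScorer", "fit_normative",
           "zscore_patients", "orient_ipsi_contra"]


@dataclass
class NormativeMap:
    """Per-region control mean/SD; regions with zero SD are flagged invalid."""

    regions: list[str]
    mu: np.ndarray
    sd: np.ndarray
    modality: str
    n_controls: int

    @property
    def valid(self) -> np.ndarray:
        return self.sd > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu, "sd": self.sd,
                             "valid": self.valid}, index=self.regions)


class NormativeScorer(BaseEstimator, TransformerMixin):
    """fit() on a control matrix, transform() any matrix into z-scores.

    The SD uses the unbiased (n-1) estimator.  Zero-SD regions are
    flagged; their z-scores come out as NaN and are excluded downstream.
    """

    def __init__(self, modality: str = "gm_volume"):
        self.modality = modality

    def fit(self, X: pd.DataFrame, y=None) -> "NormativeScorer":
        X = pd.DataFrame(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 controls for a normative map")
        vals = X.to_numpy(dtype=float)
        self.mean_ = vals.mean(axis=0)
        self.sd_ = vals.std(axis=0, ddof=1)
        self.regions_ = [str(c) for c in X.columns]
        self.n_features_in_ = X.shape[1]
        self.n_controls_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if [str(c) for c in X.columns] != self.regions_:
            raise ValueError("region columns do not match the normative map")
        sd = np.where(self.sd_ > 0, self.sd_, np.nan)
        z = (X.to_numpy(dtype=float) - self.mean_[None, :]) / sd[None, :]
        return pd.DataFrame(z, index=X.index, columns=X.columns)

    @property
    def map_(self) -> NormativeMap:
        return NormativeMap(self.regions_, self.mean_, self.sd_,
                            self.modality, self.n_controls_)


def fit_normative(controls: RegionTable | pd.DataFrame,
                  modality: str | None = None) -> NormativeMap:
    """Per-region control mean and unbiased SD."""
    if isinstance(controls, RegionTable):
        X, modality = controls.values, controls.modality
    else:
        X = controls
        modality = modality or "gm_volume"
    return NormativeScorer(modality).fit(X).map_


def zscore_patients(patients: RegionTable | pd.DataFrame,
                    nmap: NormativeMap) -> pd.DataFrame:
    """z = (value - mu_r) / s_r; flagged regions yield NaN."""
    if isinstance(patients, RegionTable):
        if patients.modality != nmap.modality:
            raise ValueError(
                f"modality mismatch: table is {patients.modality!r}, "
                f"map is {nmap.modality!r}")
        X = patients.values
    else:
        X = pd.DataFrame(patients)
    if [str(c) for c in X.columns] != nmap.regions:
        raise ValueError("region columns do not match the normative map")
    sd = np.where(nmap.valid, nmap.sd, np.nan)
    z = (X.to_numpy(dtype=float) - nmap.mu[None, :]) / sd[None, :]
    return pd.DataFrame(z, index=X.index, columns=X.columns)


def _swap_label(region: str) -> str:
    if region.startswith("L_"):
        return "R_" + region[2:]
    if region.startswith("R_"):
        return "L_" + region[2:]
    if region.startswith("M_"):
        return region
    raise ValueError(f"region {region!r} carries no hemisphere label "
                     "(expected L_/R_/M_ prefix)")


def orient_ipsi_contra(z: pd.DataFrame, tle_side: pd.Series | dict) -> pd.DataFrame:
    """Relabel regions so left/right becomes ipsi/contra to the seizure focus.

    For left-sided subjects the mapping is the identity; for right-sided
    subjects the L_/R_ labels are swapped.  Values are untouched - only
    column assignment changes per subject.  Applying the transform twice
    restores the original table.
    """
    sides = pd.Series(tle_side)
    out = z.copy()
    swapped = {c: _swap_label(str(c)) for c in z.columns}
    for sid, side in sides.items():
        if side == "left":
            continue
        if side != "right":
            raise ValueError(f"subject {sid!r}: tle_side must be left or right")
        row = z.loc[sid]
        out.loc[sid] = row.rename(swapped).reindex(z.columns).to_numpy()
    return out
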