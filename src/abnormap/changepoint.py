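"""Patient-specific abnormality thresholds from ranked regional z-scores.

A patient's regional z-scores are ranked with the expected-abnormal tail
first (most negative first for gray-matter volume, most positive first
for superficial-white-matter diffusivity).  A Bayesian change-point scan
then separates an extreme "abnormal" prefix from the remaining regions by
comparing, for every admissible split, the marginal likelihood of a
two-segment model against a no-change model; the abnormal set is the
prefix before the selected split.

Two evidence models are provided:

``mean_shift``
    The classic two-segment Gaussian mean-shift with a shared unknown
    variance and conjugate normal-inverse-gamma priors, against a
    single-mean no-change model.  Exact conjugate integrals, no sampling.
    Appropriate for sequences whose null is "no shift anywhere".

``ranked_null`` (default for z-score pipelines)
    Takes into account that the input is a *sorted* sample: under the
    null hypothesis of no abnormality the sequence should follow the
    order-statistic profile of a standard-normal sample, which is itself
    strongly non-constant.  The suffix is therefore pinned to the
    expected order-statistic profile of a null sample of the remaining
    size (independent-normal approximation to the order-statistic law),
    while the prefix is modelled as a free Gaussian segment with the same
    conjugate marginal likelihood as above.  The no-change model is the
    full-length null profile.

In both modes the no-change model receives prior mass 1/2 and the
remaining mass is spread uniformly over split locations, and a selected
split is only accepted when the prefix mean is more extreme than the
suffix mean in the modality's abnormal direction and lies on the
abnormal side of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "RankedSequence",
    "ChangepointResult",
    "AbnormalitySet",
    "rank_zscores",
    "detect_changepoint",
    "extract_abnormal_set",
    "RankedAbnormalityDetector",
]

GM = "gm_volume"
SWM = "swm_md"

# abnormal direction per modality: -1 = most negative z abnormal (atrophy),
# +1 = most positive z abnormal (diffusivity increase)
_SIGN = {GM: -1.0, SWM: +1.0}


@dataclass
class RankedSequence:
    """Region IDs and z-values ordered with the candidate-abnormal tail first."""

    region_ids: list[str]
    z: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.modality not in _SIGN:
            raise ValueError(f"unknown modality {self.modality!r}")
        if len(self.region_ids) != len(self.z):
            raise ValueError("region_ids and z must have equal length")

    @property
    def oriented(self) -> np.ndarray:
        """z-values flipped so the abnormal tail is always the negative end."""
        return -self.z if _SIGN[self.modality] > 0 else self.z

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class ChangepointResult:
    k: int
    candidate_ks: np.ndarray
    log_evidence: np.ndarray
    log_evidence_null: float
    mode: str
    too_short: bool = False

    @property
    def threshold_index(self) -> int:
        return self.k


@dataclass
class AbnormalitySet:
    patient_id: str
    modality: str
    regions: set[str] = field(default_factory=set)
    threshold_z: float | None = None

    def __len__(self) -> int:
        return len(self.regions)


def rank_zscores(z_row: Mapping[str, float] | pd.Series, modality: str) -> RankedSequence:
    """Sort one subject's regional z-scores into the modality's ranking order.

    GM: ascending (most negative first); SWM: descending (most positive
    first).  Missing values are dropped; ties are broken by region ID so
    the ordering is deterministic.
    """
    if modality not in _SIGN:
        raise ValueError(f"unknown modality {modality!r}")
    series = pd.Series(dict(z_row)) if not isinstance(z_row, pd.Series) else z_row
    series = series.dropna()
    if len(series) < 2:
        raise ValueError("need at least 2 valid regions to rank")
    # stable sort on (value, id): sort by id first, then by value
    series = series.sort_index(kind="mergesort")
    order = np.argsort(_SIGN[modality] * -series.to_numpy(), kind="mergesort")
    ids = [series.index[i] for i in order]
    return RankedSequence(ids, series.to_numpy()[order], modality)


def _nig_log_evidence(s: float, ss: float, n: int,
                      tau: float, a0: float, b0: float) -> float:
    """Marginal likelihood of n iid Gaussian points, unknown mean and
    variance, mean ~ N(0, sigma^2/tau), sigma^2 ~ InvGamma(a0, b0)."""
    ln = n + tau
    an = a0 + 0.5 * n
    bn = b0 + 0.5 * (ss - s * s / ln)
    return (-0.5 * n * np.log(2 * np.pi) + 0.5 * (np.log(tau) - np.log(ln))
            + a0 * np.log(b0) - an * np.log(bn) + gammaln(an) - gammaln(a0))


@lru_cache(maxsize=512)
def _null_profile(m: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Blom expected order statistics of m standard normals, their marginal
    SDs, and the constant part of the profile log-likelihood."""
    i = np.arange(1, m + 1)
    p = (i - 0.375) / (m + 0.25)
    xi = norm.ppf(p)
    phi = norm.pdf(xi)
    sd = np.sqrt(p * (1.0 - p) / ((m + 2) * phi ** 2))
    const = float(-0.5 * m * np.log(2 * np.pi) - np.log(sd).sum())
    return xi, sd, const


def _profile_loglik(tail: np.ndarray) -> float:
    m = len(tail)
    if m == 0:
        return 0.0
    xi, sd, const = _null_profile(m)
    r = (tail - xi) / sd
    return const - 0.5 * float(r @ r)


def detect_changepoint(seq: RankedSequence, min_segment: int = 3,
                       mode: str = "ranked_null", tau: float = 0.01,
                       a0: float = 0.01, b0: float = 0.01,
                       null_mass: float = 0.5) -> ChangepointResult:
    """Scan all admissible splits of a ranked sequence and select the split
    (or the no-change model) with the highest posterior evidence.

    Returns k* = 0 when the no-change model wins, when the sequence is
    shorter than 2 * min_segment, or when no split passes the
    prefix-extremity guard.
    """
    if min_segment < 1:
        raise ValueError("min_segment must be >= 1")
    y = seq.oriented  # abnormal tail = negative end, ascending
    n = len(y)
    if n < 2 * min_segment:
        return ChangepointResult(0, np.array([], dtype=int), np.array([]),
                                 np.nan, mode, too_short=True)

    ks = np.arange(min_segment, n - min_segment + 1)
    cums = np.cumsum(y)
    cumss = np.cumsum(y * y)
    s_tot, ss_tot = cums[-1], cumss[-1]
    s1, ss1 = cums[ks - 1], cumss[ks - 1]

    lp_null = np.log(null_mass)
    lp_split = np.log((1.0 - null_mass) / len(ks))

    if mode == "mean_shift":
        lev_null = _nig_log_evidence(s_tot, ss_tot, n, tau, a0, b0) + lp_null
        an = a0 + 0.5 * n
        l1 = ks + tau
        l2 = (n - ks) + tau
        s2 = s_tot - s1
        bn = b0 + 0.5 * (ss_tot - s1 * s1 / l1 - s2 * s2 / l2)
        lev = (-0.5 * n * np.log(2 * np.pi)
               + 0.5 * (2 * np.log(tau) - np.log(l1) - np.log(l2))
               + a0 * np.log(b0) - an * np.log(bn)
               + gammaln(an) - gammaln(a0) + lp_split)
    elif mode == "ranked_null":
        lev_null = _profile_loglik(y) + lp_null
        lev = np.empty(len(ks))
        for j, k in enumerate(ks):
            lev[j] = (_nig_log_evidence(s1[j], ss1[j], int(k), tau, a0, b0)
                      + _profile_loglik(y[k:]) + lp_split)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # prefix-extremity guard: the abnormal prefix must be more extreme than
    # the suffix and lie on the abnormal side of zero
    pre_mean = s1 / ks
    suf_mean = (s_tot - s1) / (n - ks)
    admissible = (pre_mean < suf_mean) & (pre_mean < 0.0)
    lev = np.where(admissible, lev, -np.inf)

    if not np.isfinite(lev).any() or lev_null >= lev.max():
        k_star = 0
    else:
        k_star = int(ks[int(np.argmax(lev))])
    return ChangepointResult(k_star, ks, lev, float(lev_null), mode)


def extract_abnormal_set(seq: RankedSequence, cp: ChangepointResult,
                         patient_id: str = "") -> AbnormalitySet:
    """The abnormal set is exactly the first k* ranked regions."""
    if cp.k < 0 or cp.k > len(seq):
        raise ValueError("changepoint result does not match the sequence")
    if not cp.too_short and len(cp.candidate_ks) and (
            len(seq) != cp.candidate_ks[-1] + cp.candidate_ks[0]):
        raise ValueError("changepoint result does not match the sequence")
    regions = set(seq.region_ids[:cp.k])
    threshold = float(seq.z[cp.k - 1]) if cp.k > 0 else None
    return AbnormalitySet(patient_id, seq.modality, regions, threshold)


class RankedAbnormalityDetector(BaseEstimator):
    """Estimator wrapper: z-score table in, per-patient abnormal sets out.

    Parameters mirror :func:`detect_changepoint`.  ``fit`` only records
    the region universe (detection is per-subject and has no pooled
    parameters); ``predict`` returns a boolean subjects x regions frame,
    ``detect`` returns :class:`AbnormalitySet` objects.
    """

    def __init__(self, modality: str = GM, min_segment: int = 3,
                 mode: str = "ranked_null", tau: float = 0.01,
                 a0: float = 0.01, b0: float = 0.01, null_mass: float = 0.5):
        self.modality = modality
        self.min_segment = min_segment
        self.mode = mode
        self.tau = tau
        self.a0 = a0
        self.b0 = b0
        self.null_mass = null_mass

    def fit(self, X: pd.DataFrame, y=None) -> "RankedAbnormalityDetector":
        X = pd.DataFrame(X)
        self.region_ids_ = list(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def detect(self, X: pd.DataFrame) -> dict[str, AbnormalitySet]:
        X = pd.DataFrame(X)
        out = {}
        for pid, row in X.iterrows():
            seq = rank_zscores(row, self.modality)
            cp = detect_changepoint(seq, self.min_segment, self.mode,
                                    self.tau, self.a0, self.b0, self.null_mass)
            out[str(pid)] = extract_abnormal_set(seq, cp, str(pid))
        return out

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        sets = self.detect(X)
        flags = pd.DataFrame(False, index=X.index, columns=X.columns)
        for pid, ab in sets.items():
            flags.loc[pid, sorted(ab.regions)] = True
        return flags
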