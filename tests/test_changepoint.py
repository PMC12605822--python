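"""Ranking, change-point evidence, and abnormal-set extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_t, norm

from abnormap.changepoint import (RankedAbnormalityDetector, RankedSequence,
                                  detect_changepoint, extract_abnormal_set,
                                  rank_zscores)

# ---------------------------------------------------------------------------
# independent oracle: the two-segment marginal likelihood computed through the
# multivariate Student-t predictive density (normal-inverse-gamma marginal),
# a completely different derivation from the prefix-sum implementation
# ---------------------------------------------------------------------------

TAU, A0, B0 = 0.01, 0.01, 0.01


def _mvt_evidence(y, X):
    n = len(y)
    shape = (B0 / A0) * (np.eye(n) + X @ X.T / TAU)
    return multivariate_t.logpdf(y, loc=np.zeros(n), shape=shape, df=2 * A0)


def brute_force_mean_shift(y, min_segment=3, null_mass=0.5):
    """Enumerate every split of the two-segment shared-variance model."""
    n = len(y)
    ks = range(min_segment, n - min_segment + 1)
    lev0 = _mvt_evidence(y, np.ones((n, 1))) + np.log(null_mass)
    best_k, best = 0, lev0
    lp = np.log((1 - null_mass) / len(list(ks)))
    for k in range(min_segment, n - min_segment + 1):
        pre, suf = y[:k], y[k:]
        if not (pre.mean() < suf.mean() and pre.mean() < 0):
            continue
        X = np.zeros((n, 2))
        X[:k, 0] = 1.0
        X[k:, 1] = 1.0
        lev = _mvt_evidence(y, X) + lp
        if lev > best:
            best, best_k = lev, k
    return best_k


def brute_force_ranked_null(y, min_segment=3, null_mass=0.5):
    """Same enumeration for the null-anchored model: Student-t prefix plus
    independent-normal order-statistic suffix, both written from scratch."""
    n = len(y)

    def profile(tail):
        m = len(tail)
        if m == 0:
            return 0.0
        p = (np.arange(1, m + 1) - 0.375) / (m + 0.25)
        xi = norm.ppf(p)
        sd = np.sqrt(p * (1 - p) / ((m + 2) * norm.pdf(xi) ** 2))
        return float(norm.logpdf(tail, loc=xi, scale=sd).sum())

    ks = list(range(min_segment, n - min_segment + 1))
    best_k, best = 0, profile(y) + np.log(null_mass)
    lp = np.log((1 - null_mass) / len(ks))
    for k in ks:
        pre, suf = y[:k], y[k:]
        if not (pre.mean() < suf.mean() and pre.mean() < 0):
            continue
        lev = _mvt_evidence(pre, np.ones((k, 1))) + profile(suf) + lp
        if lev > best:
            best, best_k = lev, k
    return best_k


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_gm_ranking_is_ascending():
    seq = rank_zscores({"A": -3.0, "B": 0.0, "C": 1.0}, "gm_volume")
    assert seq.region_ids == ["A", "B", "C"]


def test_swm_ranking_is_descending():
    seq = rank_zscores({"A": -3.0, "B": 0.0, "C": 1.0}, "swm_md")
    assert seq.region_ids == ["C", "B", "A"]


def test_ties_break_by_region_id():
    seq = rank_zscores({"B": 1.0, "A": 1.0}, "swm_md")
    assert seq.region_ids == ["A", "B"]


def test_missing_values_dropped_and_all_missing_errors():
    seq = rank_zscores({"A": np.nan, "B": -1.0, "C": 0.0}, "gm_volume")
    assert seq.region_ids == ["B", "C"]
    with pytest.raises(ValueError):
        rank_zscores({"A": np.nan, "B": np.nan}, "gm_volume")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_step_sequence_recovers_boundary():
    z = np.r_[np.full(5, -4.0), np.zeros(55)]
    seq = RankedSequence([f"r{i:02d}" for i in range(60)], z, "gm_volume")
    cp = detect_changepoint(seq, mode="mean_shift")
    assert cp.k == 5
    ab = extract_abnormal_set(seq, cp)
    assert ab.regions == {f"r{i:02d}" for i in range(5)}
    assert ab.threshold_z == -4.0


def test_step_against_sorted_noise_recovers_boundary():
    # the null-anchored model expects the non-abnormal remainder to look
    # like a sorted normal sample, so its step fixture uses a noise suffix
    rng = np.random.default_rng(0)
    z = np.r_[np.full(5, -4.0), np.sort(rng.normal(0, 1, 55))]
    seq = RankedSequence([f"r{i:02d}" for i in range(60)], z, "gm_volume")
    assert detect_changepoint(seq, mode="ranked_null").k == 5


@pytest.mark.parametrize("mode", ["mean_shift", "ranked_null"])
def test_constant_sequence_has_no_changepoint(mode):
    z = np.full(60, 0.1)
    seq = RankedSequence([f"r{i}" for i in range(60)], z, "gm_volume")
    assert detect_changepoint(seq, mode=mode).k == 0


@pytest.mark.parametrize("mode", ["mean_shift", "ranked_null"])
def test_wrong_tail_rejected_by_extremity_guard(mode):
    # the shifted values sit at the non-abnormal end for GM
    z = np.r_[np.zeros(55), np.full(5, 4.0)]
    seq = RankedSequence([f"r{i}" for i in range(60)], z, "gm_volume")
    assert detect_changepoint(seq, mode=mode).k == 0


def test_swm_direction_uses_positive_tail():
    rng = np.random.default_rng(0)
    # ranked descending: the +4 tail first, then noise sorted descending
    z = np.r_[np.full(5, 4.0), -np.sort(rng.normal(0, 1, 55))]
    seq = RankedSequence([f"r{i:02d}" for i in range(60)], z, "swm_md")
    assert detect_changepoint(seq).k == 5


def test_short_sequence_flagged():
    seq = RankedSequence(list("abcd"), np.array([-3.0, -2, 0, 1]), "gm_volume")
    cp = detect_changepoint(seq, min_segment=3)
    assert cp.k == 0 and cp.too_short


def test_empty_set_when_k_zero():
    seq = RankedSequence(list("abcdef"), np.full(6, 0.5), "gm_volume")
    cp = detect_changepoint(seq)
    ab = extract_abnormal_set(seq, cp, "p1")
    assert len(ab) == 0 and ab.threshold_z is None


@pytest.mark.parametrize("mode,oracle", [
    ("mean_shift", brute_force_mean_shift),
    ("ranked_null", brute_force_ranked_null),
])
def test_oracle_equivalence_on_random_sequences(mode, oracle):
    """Selected split matches brute-force enumeration of the marginal
    likelihood computed via an independent (multivariate-t) route."""
    rng = np.random.default_rng(7)
    n_match = 0
    trials = 60
    for _ in range(trials):
        n = int(rng.integers(8, 51))
        if rng.random() < 0.5:
            y = np.sort(rng.normal(0, 1, n))
        else:
            k = int(rng.integers(3, max(4, n // 3)))
            y = np.sort(np.r_[rng.normal(-3, 1, k), rng.normal(0, 1, n - k)])
        seq = RankedSequence([f"r{i:03d}" for i in range(n)], y, "gm_volume")
        cp = detect_changepoint(seq, mode=mode)
        assert cp.k == oracle(y), f"mismatch at n={n}"
        n_match += 1
    assert n_match == trials


def test_scale_invariance_of_mean_shift_mode():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(10, 60))
        k = int(rng.integers(3, max(4, n // 3)))
        y = np.sort(np.r_[rng.normal(-2.5, 1, k), rng.normal(0, 1, n - k)])
        seq = RankedSequence([f"r{i:03d}" for i in range(n)], y, "gm_volume")
        base = detect_changepoint(seq, mode="mean_shift").k
        for c in (0.5, 2.0, 10.0):
            scaled = RankedSequence(seq.region_ids, c * y, "gm_volume")
            assert detect_changepoint(scaled, mode="mean_shift").k == base


def test_detection_sensitivity_monotone_in_effect_size():
    rng = np.random.default_rng(5)
    mean_sens = []
    for effect in (1.5, 2.5, 3.5):
        sens = []
        for _ in range(120):
            z = np.r_[rng.normal(0, 1, 123), rng.normal(-effect, 1, 5)]
            ids = [f"r{i:03d}" for i in range(128)]
            seq = rank_zscores(pd.Series(z, index=ids), "gm_volume")
            cp = detect_changepoint(seq)
            found = set(seq.region_ids[:cp.k])
            sens.append(len(found & {f"r{i:03d}" for i in range(123, 128)}) / 5)
        mean_sens.append(np.mean(sens))
    assert mean_sens[0] <= mean_sens[1] + 0.05
    assert mean_sens[1] <= mean_sens[2] + 0.05
    assert mean_sens[2] > 0.6


def test_detector_estimator_roundtrip(small_cohort):
    gm_c, _, gm_p, _, truth = small_cohort
    # quick z-scores without harmonization: raw normative on controls
    from abnormap.normative import NormativeScorer
    z = NormativeScorer("gm_volume").fit(gm_c.values).transform(gm_p.values)
    det = RankedAbnormalityDetector(modality="gm_volume").fit(z)
    sets = det.detect(z)
    flags = det.predict(z)
    for pid, ab in sets.items():
        assert set(flags.columns[flags.loc[pid]]) == ab.regions
    assert det.get_params()["modality"] == "gm_volume"


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-6, 6, allow_nan=False), min_size=2, max_size=40),
       st.sampled_from(["gm_volume", "swm_md"]))
def test_ranking_is_deterministic_and_order_correct(values, modality):
    row = pd.Series(values, index=[f"r{i:02d}" for i in range(len(values))])
    a = rank_zscores(row, modality)
    b = rank_zscores(row.sample(frac=1, random_state=0), modality)
    assert a.region_ids == b.region_ids          # input order irrelevant
    diffs = np.diff(a.z)
    assert (diffs >= 0).all() if modality == "gm_volume" else (diffs <= 0).all()
    assert sorted(a.region_ids) == sorted(row.index)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_abnormal_set_size_always_equals_k(seed_int):
    rng = np.random.default_rng(seed_int)
    n = int(rng.integers(6, 64))
    z = rng.normal(-rng.uniform(0, 2), 1, n)
    row = pd.Series(z, index=[f"r{i:02d}" for i in range(n)])
    seq = rank_zscores(row, "gm_volume")
    cp = detect_changepoint(seq)
    ab = extract_abnormal_set(seq, cp, "p")
    assert len(ab) == cp.k
    assert 0 <= cp.k <= max(0, len(seq) - 3)
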