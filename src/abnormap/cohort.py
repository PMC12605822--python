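"""Synthetic cohorts with the statistical structure of a two-site TLE imaging study.

Generates control and patient region-by-subject feature tables for two
modalities (gray-matter volume in mm^3, superficial-white-matter mean
diffusivity in mm^2/s), with age/sex covariate effects, additive and
multiplicative site (acquisition protocol) effects, patient abnormalities
injected into a temporal-lobe-like region block, per-patient resection
sets, and surgical outcomes stochastically linked to the proportion of
injected abnormality that was resected.  A :class:`TruthRecord` carries
the ground truth needed for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModalityParams",
    "GeneratorConfig",
    "RegionTable",
    "TruthRecord",
    "generate_cohort",
    "make_region_ids",
]

GM = "gm_volume"
SWM = "swm_md"


@dataclass
class ModalityParams:
    """Per-modality generator parameters.

    mean_range / sd_range give the uniform ranges from which region-level
    means and noise SDs are drawn (feature units).  age_effect is in
    feature units per year, sex_effect in feature units (sex coded 0/1).
    site_shift is the additive offset per site step; site_scale multiplies
    the noise SD per site step (site 0 is the reference).  abnormal_effect
    is the injected shift in units of the region noise SD: volume decrease
    for GM, diffusivity increase for SWM.
    """

    mean_range: tuple[float, float]
    sd_range: tuple[float, float]
    age_effect: float
    sex_effect: float
    site_shift: float
    site_scale: float
    abnormal_effect: float


def _default_gm() -> ModalityParams:
    return ModalityParams(
        mean_range=(5000.0, 9000.0),
        sd_range=(200.0, 500.0),
        age_effect=-8.0,
        sex_effect=250.0,
        site_shift=150.0,
        site_scale=1.1,
        abnormal_effect=3.0,
    )


def _default_swm() -> ModalityParams:
    return ModalityParams(
        mean_range=(7.0e-4, 9.0e-4),
        sd_range=(2.0e-5, 5.0e-5),
        age_effect=1.0e-6,
        sex_effect=5.0e-6,
        site_shift=2.0e-5,
        site_scale=1.1,
        abnormal_effect=3.0,
    )


@dataclass
class GeneratorConfig:
    n_controls: int = 97
    n_patients: int = 143
    n_regions: int = 460
    n_sites: int = 2
    gm: ModalityParams = field(default_factory=_default_gm)
    swm: ModalityParams = field(default_factory=_default_swm)
    age_range: tuple[float, float] = (18.0, 65.0)
    abnormal_region_count: int = 6
    abnormal_overlap_fraction: float = 0.5
    focality: float = 0.7
    resection_region_count: int = 10
    outcome_intercept: float = -1.2
    outcome_slope: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_controls", "n_patients", "n_regions", "n_sites",
                     "abnormal_region_count", "resection_region_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.abnormal_region_count >= self.n_regions:
            raise ValueError("abnormal_region_count must be < n_regions")
        if 2 * self.abnormal_region_count >= self.n_regions:
            raise ValueError("need n_regions > 2 * abnormal_region_count")
        if 2 * self.resection_region_count > self.n_regions:
            raise ValueError("resection block does not fit in one hemisphere")
        for frac in (self.abnormal_overlap_fraction, self.focality):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for mod in (self.gm, self.swm):
            if mod.site_scale <= 0:
                raise ValueError("site_scale must be > 0")
            if mod.sd_range[0] <= 0:
                raise ValueError("sd_range must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")


@dataclass
class RegionTable:
    """Subjects x regions feature matrix plus per-subject metadata.

    values: DataFrame indexed by subject ID with one column per region.
    metadata: DataFrame on the same index with columns
        age, sex (0/1), site, group ('control'|'patient'),
        tle_side ('left'|'right'|'n/a'), outcome ('ILAE1,2'|'ILAE3+'|'n/a').
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("values and metadata must share the subject index")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate subject ID: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("region values must be finite")
        if (arr <= 0).any():
            raise ValueError("feature values must be positive")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, subjects: Sequence[str]) -> "RegionTable":
        return RegionTable(self.values.loc[subjects], self.metadata.loc[subjects],
                           self.modality)


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, keyed by patient ID."""

    injected_gm_regions: dict[str, set[str]]
    injected_swm_regions: dict[str, set[str]]
    resected_regions: dict[str, set[str]]
    outcome_probability: dict[str, float]
    outcome_label: dict[str, int]

    def to_json(self) -> str:
        payload = {
            "injected_gm_regions": {k: sorted(v) for k, v in self.injected_gm_regions.items()},
            "injected_swm_regions": {k: sorted(v) for k, v in self.injected_swm_regions.items()},
            "resected_regions": {k: sorted(v) for k, v in self.resected_regions.items()},
            "outcome_probability": self.outcome_probability,
            "outcome_label": self.outcome_label,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            {k: set(v) for k, v in d["injected_gm_regions"].items()},
            {k: set(v) for k, v in d["injected_swm_regions"].items()},
            {k: set(v) for k, v in d["resected_regions"].items()},
            d["outcome_probability"],
            {k: int(v) for k, v in d["outcome_label"].items()},
        )


def make_region_ids(n_regions: int) -> list[str]:
    """Hemisphere-labelled region IDs: L_### / R_### pairs, plus a trailing
    midline M_### region when n_regions is odd."""
    per_hemi = n_regions // 2
    ids = [f"L_{i:03d}" for i in range(per_hemi)]
    ids += [f"R_{i:03d}" for i in range(per_hemi)]
    if n_regions % 2:
        ids.append(f"M_{per_hemi:03d}")
    return ids


def _temporal_block(region_ids: list[str], side: str, size: int) -> list[str]:
    prefix = "L_" if side == "left" else "R_"
    return [r for r in region_ids if r.startswith(prefix)][:size]


def _draw_subjects(rng: np.random.Generator, n: int, n_sites: int,
                   age_range: tuple[float, float], prefix: str) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "age": rng.uniform(*age_range, size=n),
            "sex": rng.integers(0, 2, size=n),
            "site": rng.integers(0, n_sites, size=n),
        },
        index=[f"{prefix}{i:04d}" for i in range(n)],
    )
    # guarantee every site has at least 2 subjects so location/scale
    # estimates are defined
    for s in range(n_sites):
        short = 2 - int((meta["site"] == s).sum())
        if short > 0:
            free = meta.index[meta["site"] != s][:short]
            meta.loc[free, "site"] = s
    return meta


def _control_values(rng: np.random.Generator, meta: pd.DataFrame,
                    region_ids: list[str], mod: ModalityParams,
                    means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    n = len(meta)
    shift = meta["site"].to_numpy()[:, None] * mod.site_shift
    scale = mod.site_scale ** meta["site"].to_numpy()[:, None]
    base = (
        means[None, :]
        + mod.age_effect * meta["age"].to_numpy()[:, None]
        + mod.sex_effect * meta["sex"].to_numpy()[:, None]
        + shift
    )
    noise = rng.normal(0.0, 1.0, size=(n, len(region_ids))) * sds[None, :] * scale
    return base + noise


def generate_cohort(config: GeneratorConfig | None = None,
                    ) -> tuple[RegionTable, RegionTable, RegionTable, RegionTable, TruthRecord]:
    """Generate (gm_controls, swm_controls, gm_patients, swm_patients, truth).

    Control values follow region mean + age/sex effects + additive site
    shift, with noise SD scaled multiplicatively per site.  Patients are
    identical in law except that injected regions have GM volume reduced
    (and SWM MD increased) by ``abnormal_effect`` noise SDs.  Outcomes are
    Bernoulli(sigmoid(intercept + slope * proportion of injected regions
    resected)).  Deterministic given ``config.seed``.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    region_ids = make_region_ids(config.n_regions)
    nr = len(region_ids)

    means = {
        GM: rng.uniform(*config.gm.mean_range, size=nr),
        SWM: rng.uniform(*config.swm.mean_range, size=nr),
    }
    sds = {
        GM: rng.uniform(*config.gm.sd_range, size=nr),
        SWM: rng.uniform(*config.swm.sd_range, size=nr),
    }

    c_meta = _draw_subjects(rng, config.n_controls, config.n_sites, config.age_range, "ctrl")
    c_meta["group"] = "control"
    c_meta["tle_side"] = "n/a"
    c_meta["outcome"] = "n/a"
    p_meta = _draw_subjects(rng, config.n_patients, config.n_sites, config.age_range, "pat")
    p_meta["group"] = "patient"
    p_meta["tle_side"] = np.where(rng.random(config.n_patients) < 0.5, "left", "right")

    gm_c = _control_values(rng, c_meta, region_ids, config.gm, means[GM], sds[GM])
    swm_c = _control_values(rng, c_meta, region_ids, config.swm, means[SWM], sds[SWM])
    gm_p = _control_values(rng, p_meta, region_ids, config.gm, means[GM], sds[GM])
    swm_p = _control_values(rng, p_meta, region_ids, config.swm, means[SWM], sds[SWM])

    idx = {r: i for i, r in enumerate(region_ids)}
    inj_gm: dict[str, set[str]] = {}
    inj_swm: dict[str, set[str]] = {}
    resected: dict[str, set[str]] = {}
    probs: dict[str, float] = {}
    labels: dict[str, int] = {}
    outcomes = []

    n_abn = config.abnormal_region_count
    n_shared = int(round(config.abnormal_overlap_fraction * n_abn))

    for row, (pid, srow) in enumerate(p_meta.iterrows()):
        side = srow["tle_side"]
        block = _temporal_block(region_ids, side, config.resection_region_count)
        # epileptogenic candidate zone: the resection block plus a margin
        ez = _temporal_block(region_ids, side,
                             int(np.ceil(1.5 * config.resection_region_count)))
        ez_set = set(ez)

        # injection sites favour the epileptogenic zone: probability mass
        # `focality` spread over the zone, the rest over remaining regions
        base_w = np.empty(nr)
        n_out = nr - len(ez_set)
        for i, r in enumerate(region_ids):
            base_w[i] = (config.focality / len(ez_set) if r in ez_set
                         else (1.0 - config.focality) / n_out)

        def _draw_set(k: int, taken: set[str]) -> list[str]:
            if k == 0:
                return []
            w = base_w.copy()
            for r in taken:
                w[idx[r]] = 0.0
            w /= w.sum()
            picks = rng.choice(nr, size=k, replace=False, p=w)
            return [region_ids[i] for i in picks]

        shared = _draw_set(n_shared, set())
        gm_only = _draw_set(n_abn - n_shared, set(shared))
        swm_only = _draw_set(n_abn - n_shared, set(shared) | set(gm_only))
        gm_set = set(shared) | set(gm_only)
        swm_set = set(shared) | set(swm_only)

        for r in gm_set:
            gm_p[row, idx[r]] -= config.gm.abnormal_effect * sds[GM][idx[r]]
        for r in swm_set:
            swm_p[row, idx[r]] += config.swm.abnormal_effect * sds[SWM][idx[r]]

        res = set(block)
        union_truth = gm_set | swm_set
        prop = len(union_truth & res) / len(union_truth)
        p_good = 1.0 / (1.0 + np.exp(-(config.outcome_intercept
                                       + config.outcome_slope * prop)))
        y = int(rng.random() < p_good)

        inj_gm[pid] = gm_set
        inj_swm[pid] = swm_set
        resected[pid] = res
        probs[pid] = float(p_good)
        labels[pid] = y
        outcomes.append("ILAE1,2" if y else "ILAE3+")

    p_meta["outcome"] = outcomes

    def table(vals: np.ndarray, meta: pd.DataFrame, modality: str) -> RegionTable:
        df = pd.DataFrame(np.clip(vals, np.finfo(float).tiny, None),
                          index=meta.index, columns=region_ids)
        return RegionTable(df, meta.copy(), modality)

    truth = TruthRecord(inj_gm, inj_swm, resected, probs, labels)
    return (
        table(gm_c, c_meta, GM),
        table(swm_c, c_meta, SWM),
        table(gm_p, p_meta, GM),
        table(swm_p, p_meta, SWM),
        truth,
    )
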