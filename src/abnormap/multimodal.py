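"""Union / concordance / discordance of GM and SWM abnormal sets, and
per-patient proportion-of-abnormality-resected scores."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .changepoint import AbnormalitySet

__all__ = ["CombinedAbnormality", "ResectionScore", "combine_sets",
           "score_resection", "CATEGORIES"]

CATEGORIES = ("gm", "swm", "union", "concordant", "discordant")


@dataclass
class CombinedAbnormality:
    patient_id: str
    gm_set: set[str]
    swm_set: set[str]

    @property
    def union_set(self) -> set[str]:
        return self.gm_set | self.swm_set

    @property
    def concordant_set(self) -> set[str]:
        return self.gm_set & self.swm_set

    @property
    def discordant_set(self) -> set[str]:
        return self.gm_set ^ self.swm_set

    def category(self, name: str) -> set[str]:
        return {
            "gm": self.gm_set, "swm": self.swm_set, "union": self.union_set,
            "concordant": self.concordant_set, "discordant": self.discordant_set,
        }[name]


@dataclass
class ResectionScore:
    """Per-category counts and proportion resected; proportions are None
    when the category is empty (undefined, excluded from group stats)."""

    patient_id: str
    n_abnormal: dict[str, int]
    n_resected: dict[str, int]
    proportion: dict[str, float | None]
    complete_concordant_resection: bool | None


def combine_sets(gm: AbnormalitySet, swm: AbnormalitySet) -> CombinedAbnormality:
    if gm.patient_id != swm.patient_id:
        raise ValueError(
            f"patient mismatch: {gm.patient_id!r} vs {swm.patient_id!r}")
    return CombinedAbnormality(gm.patient_id, set(gm.regions), set(swm.regions))


def score_resection(comb: CombinedAbnormality, resected: set[str]) -> ResectionScore:
    """Proportion of each abnormality category inside the resected set.

    complete_concordant_resection is True when every concordant region was
    resected, and None (undefined) when there are no concordant regions.
    """
    n_ab, n_res, prop = {}, {}, {}
    for cat in CATEGORIES:
        s = comb.category(cat)
        n_ab[cat] = len(s)
        n_res[cat] = len(s & resected)
        prop[cat] = (n_res[cat] / n_ab[cat]) if s else None
    conc = comb.concordant_set
    complete = (conc <= resected) if conc else None
    return ResectionScore(comb.patient_id, n_ab, n_res, prop, complete)


def scores_frame(scores: list[ResectionScore]) -> pd.DataFrame:
    """One row per patient, columns per category (None -> NaN)."""
    rows = {}
    for s in scores:
        row = {f"prop_{c}": s.proportion[c] for c in CATEGORIES}
        row.update({f"n_{c}": s.n_abnormal[c] for c in CATEGORIES})
        row["complete_concordant"] = s.complete_concordant_resection
        rows[s.patient_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    for c in CATEGORIES:
        df[f"prop_{c}"] = df[f"prop_{c}"].astype(float)
    return df
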