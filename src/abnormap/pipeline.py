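"""End-to-end orchestration: harmonize -> normative z-scores -> change-point
abnormal sets -> resection scoring -> outcome evaluation.

The tabular entry point takes the four region tables (GM/SWM x
controls/patients) plus per-patient resected region sets and returns the
per-patient category scores and the per-category outcome evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .changepoint import GM, SWM, RankedAbnormalityDetector
from .cohort import RegionTable
from .harmonize import ComBatHarmonizer
from .multimodal import CATEGORIES, combine_sets, score_resection, scores_frame
from .normative import NormativeScorer
from .stats import OutcomeEvaluation, evaluate_category

__all__ = ["PipelineOptions", "PipelineResult", "run_tabular_pipeline"]


@dataclass
class PipelineOptions:
    batch_field: str = "site"
    covariate_fields: tuple[str, ...] = ("age", "sex")
    fit_on: str = "controls"            # or "pooled"
    min_segment: int = 3
    changepoint_mode: str = "ranked_null"
    overlap_threshold: float = 0.10
    bootstrap: int = 0
    seed: int = 0


@dataclass
class PipelineResult:
    zscores: dict[str, pd.DataFrame]
    abnormal_sets: dict[str, dict]
    scores: pd.DataFrame
    evaluations: dict[str, OutcomeEvaluation]
    excluded: dict[str, int] = field(default_factory=dict)


def _harmonize_pair(controls: RegionTable, patients: RegionTable,
                    opts: PipelineOptions) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the batch model (controls-only by default), apply to both tables,
    removing covariate contributions so normative maps are covariate-adjusted."""
    harm = ComBatHarmonizer(keep_covariates=False)
    cov_c = controls.metadata[list(opts.covariate_fields)]
    cov_p = patients.metadata[list(opts.covariate_fields)]
    batch_c = controls.metadata[opts.batch_field].to_numpy()
    batch_p = patients.metadata[opts.batch_field].to_numpy()
    if opts.fit_on == "pooled":
        X = pd.concat([controls.values, patients.values])
        harm.fit(X, batch=np.concatenate([batch_c, batch_p]),
                 covariates=pd.concat([cov_c, cov_p]))
    elif opts.fit_on == "controls":
        harm.fit(controls.values, batch=batch_c, covariates=cov_c)
    else:
        raise ValueError("fit_on must be 'controls' or 'pooled'")
    hc = harm.transform(controls.values, batch=batch_c, covariates=cov_c)
    hp = harm.transform(patients.values, batch=batch_p, covariates=cov_p)
    return hc, hp


def run_tabular_pipeline(gm_controls: RegionTable, swm_controls: RegionTable,
                         gm_patients: RegionTable, swm_patients: RegionTable,
                         resected: dict[str, set[str]],
                         opts: PipelineOptions | None = None) -> PipelineResult:
    opts = opts or PipelineOptions()
    zscores: dict[str, pd.DataFrame] = {}
    sets_by_mod: dict[str, dict] = {}
    for mod, controls, patients in ((GM, gm_controls, gm_patients),
                                    (SWM, swm_controls, swm_patients)):
        hc, hp = _harmonize_pair(controls, patients, opts)
        scorer = NormativeScorer(mod).fit(hc)
        zscores[mod] = scorer.transform(hp)
        det = RankedAbnormalityDetector(
            modality=mod, min_segment=opts.min_segment,
            mode=opts.changepoint_mode).fit(zscores[mod])
        sets_by_mod[mod] = det.detect(zscores[mod])

    patient_ids = list(gm_patients.subject_ids)
    per_patient = []
    for pid in patient_ids:
        comb = combine_sets(sets_by_mod[GM][pid], sets_by_mod[SWM][pid])
        per_patient.append(score_resection(comb, set(resected.get(pid, set()))))
    scores = scores_frame(per_patient)

    outcome = gm_patients.metadata["outcome"]
    labels = (outcome == "ILAE1,2").astype(int)
    labels = labels.reindex(scores.index)

    evaluations: dict[str, OutcomeEvaluation] = {}
    excluded: dict[str, int] = {}
    for cat in CATEGORIES:
        col = scores[f"prop_{cat}"].astype(float)
        defined = col.notna()
        excluded[cat] = int((~defined).sum())
        try:
            evaluations[cat] = evaluate_category(
                col[defined].to_numpy(), labels[defined].to_numpy(),
                category=cat, n_resamples=opts.bootstrap or None,
                seed=opts.seed)
        except ValueError:
            # one outcome group entirely undefined in this category
            continue

    abnormal = {pid: {GM: sets_by_mod[GM][pid], SWM: sets_by_mod[SWM][pid]}
                for pid in patient_ids}
    return PipelineResult(zscores, abnormal, scores, evaluations, excluded)
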