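"""Batch scoring pipeline: derive BMI/IBW/NLR, run every score, code cohort.

The pipeline is deliberately forgiving at the patient level: a missing
measurement never aborts the batch, it turns the affected scores into
not-applicable results with a reason naming the limitation.  Retrospective
databases are ragged; scoring despite missingness is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import yaml

from .anthropometry import (
    AgeClass,
    classify_age,
    compute_bmi,
    compute_bwd,
    compute_ibw,
)
from .cohort_coding import CodedCohort, apply_cohort_coding, summarize
from .core_model import (
    PatientRecord,
    ScoreName,
    ScoreResult,
    UnitsConfig,
    not_applicable,
)
from .glim_diagnosis import GlimThresholds, classify_glim
from .screening_scores import (
    VbdRefRanges,
    classify_ina,
    classify_vbd,
    compute_gnri,
    compute_idm,
    compute_lxa,
    compute_nlr,
    compute_pma,
    compute_pmac,
)

__all__ = ["PipelineConfig", "score_patient", "score_cohort"]

#: Stable output order of the nine scores.
SCORE_ORDER: List[ScoreName] = [
    ScoreName.GLIM,
    ScoreName.BWD,
    ScoreName.GNRI,
    ScoreName.INA,
    ScoreName.LXA,
    ScoreName.PMA,
    ScoreName.PMAC,
    ScoreName.IDM,
    ScoreName.VBD,
]


@dataclass
class PipelineConfig:
    """Everything a scoring run needs besides the data itself."""

    units: UnitsConfig = dc_field(default_factory=UnitsConfig)
    glim: GlimThresholds = dc_field(default_factory=GlimThresholds)
    vbd_refs: VbdRefRanges = dc_field(default_factory=VbdRefRanges)
    scores: Sequence[ScoreName] = dc_field(default_factory=lambda: list(SCORE_ORDER))
    cap_gnri_ratio: bool = True
    gnri_senior_only: bool = True
    vbd_macrocytosis_required: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.scores = [ScoreName(s) for s in self.scores]
        unknown = set(self.scores) - set(SCORE_ORDER)
        if unknown:
            raise ValueError(f"unknown scores selected: {sorted(unknown)}")

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "units" in d:
            kwargs["units"] = UnitsConfig(**d["units"])
        if "glim" in d:
            kwargs["glim"] = GlimThresholds(**d["glim"])
        if "vbd_refs" in d:
            kwargs["vbd_refs"] = VbdRefRanges(**d["vbd_refs"])
        for key in (
            "scores",
            "cap_gnri_ratio",
            "gnri_senior_only",
            "vbd_macrocytosis_required",
            "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "units": {
                "units": dict(self.units.units),
                "columns": dict(self.units.columns),
                "ihb_policy": dict(self.units.ihb_policy),
                "ibw_formula": self.units.ibw_formula,
            },
            "glim": {
                "asaps_min": self.glim.asaps_min,
                "crp_max": self.glim.crp_max,
                "nlr_min": self.glim.nlr_min,
                "bmi_adult": self.glim.bmi_adult,
                "bmi_senior": self.glim.bmi_senior,
            },
            "vbd_refs": {
                "mcv_high": self.vbd_refs.mcv_high,
                "mch_high": self.vbd_refs.mch_high,
                "mchc_low": self.vbd_refs.mchc_low,
            },
            "scores": [s.value for s in self.scores],
            "cap_gnri_ratio": self.cap_gnri_ratio,
            "gnri_senior_only": self.gnri_senior_only,
            "vbd_macrocytosis_required": self.vbd_macrocytosis_required,
            "seed": self.seed,
        }


def _derive(record: PatientRecord, cfg: PipelineConfig):
    """Derived quantities (BMI, IBW, NLR, age class, IHB) or None each."""
    ibw = None
    if record.height is not None and record.sex is not None:
        ibw = compute_ibw(record.height, record.sex, cfg.units.ibw_formula)
    bmi = None
    if record.abw is not None and record.height is not None:
        bmi = compute_bmi(record.abw, record.height)
    nlr = None
    if record.neutc is not None and record.lymc is not None and record.lymc > 0:
        nlr = compute_nlr(record.neutc, record.lymc)
    age_class = classify_age(record.age) if record.age is not None else None
    ihb = cfg.units.ihb_for(record.sex) if record.sex is not None else None
    return bmi, ibw, nlr, age_class, ihb


def score_patient(
    record: PatientRecord, cfg: Optional[PipelineConfig] = None
) -> Dict[ScoreName, ScoreResult]:
    """Compute every selected score for one patient.

    Cohort-relative scores (PMAC, IDM) come back with a provisional code of
    -1; :func:`score_cohort` finalizes them against the cohort quartiles.
    """
    cfg = cfg or PipelineConfig()
    bmi, ibw, nlr, age_class, ihb = _derive(record, cfg)
    out: Dict[ScoreName, ScoreResult] = {}

    for score in cfg.scores:
        if score is ScoreName.GLIM:
            if age_class is None:
                out[score] = not_applicable(score, "missing age")
            elif bmi is None:
                out[score] = not_applicable(score, "missing ABW or height (BMI)")
            elif record.asaps is None:
                out[score] = not_applicable(score, "missing ASAPS")
            elif record.crp is None:
                out[score] = not_applicable(score, "missing CRP")
            elif nlr is None:
                out[score] = not_applicable(score, "missing NLR (NEUTC or LYMPC)")
            else:
                g = classify_glim(bmi, age_class, record.asaps, record.crp, nlr, cfg.glim)
                if g.applicable:
                    out[score] = ScoreResult(
                        score_name=score, code=g.code, extra=dict(g.criteria_fired)
                    )
                else:
                    out[score] = not_applicable(score, g.reason, **g.criteria_fired)
        elif score is ScoreName.BWD:
            if record.abw is None or ibw is None:
                out[score] = not_applicable(score, "missing ABW or height (IBW)")
            else:
                out[score] = compute_bwd(record.abw, ibw)
        elif score is ScoreName.GNRI:
            if cfg.gnri_senior_only and age_class is not AgeClass.SENIOR:
                out[score] = not_applicable(
                    score,
                    "missing age"
                    if age_class is None
                    else "not applicable in younger adult and adult patients",
                )
            elif record.alb is None:
                out[score] = not_applicable(score, "missing ALB")
            elif record.abw is None or ibw is None:
                out[score] = not_applicable(score, "missing ABW or height (IBW)")
            else:
                out[score] = compute_gnri(record.alb, record.abw, ibw, cfg.cap_gnri_ratio)
        elif score is ScoreName.INA:
            out[score] = classify_ina(record.alb, record.lymc)
        elif score is ScoreName.LXA:
            out[score] = compute_lxa(record.lymc, record.alb)
        elif score is ScoreName.PMA:
            out[score] = compute_pma(record.crp, record.alb)
        elif score is ScoreName.PMAC:
            out[score] = compute_pmac(nlr, record.crp, record.alb, record.palb)
        elif score is ScoreName.IDM:
            if record.abw is None:
                out[score] = not_applicable(score, "missing ABW")
            elif ihb is None:
                out[score] = not_applicable(score, "missing sex (IHB policy)")
            else:
                out[score] = compute_idm(record.abw, ihb, record.ahb)
        elif score is ScoreName.VBD:
            out[score] = classify_vbd(
                record.mcv,
                record.mch,
                record.mchc,
                cfg.vbd_refs,
                cfg.vbd_macrocytosis_required,
            )
    return out


def score_cohort(
    records: Sequence[PatientRecord], cfg: Optional[PipelineConfig] = None
) -> CodedCohort:
    """Score a cohort: per-patient scores, cohort quartile coding, summary.

    Deterministic: the same records and config always yield the same output.
    """
    if not records:
        raise ValueError("cannot score an empty cohort")
    cfg = cfg or PipelineConfig()
    seen = set()
    for r in records:
        if r.patient_id in seen:
            raise ValueError(f"duplicate patient_id {r.patient_id!r}")
        seen.add(r.patient_id)
    results = {r.patient_id: score_patient(r, cfg) for r in records}
    cohort = CodedCohort(records=list(records), results=results)
    apply_cohort_coding(cohort)
    cohort.summary = summarize(cohort)
    return cohort
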