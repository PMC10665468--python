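"""Seeded generator of synthetic patient cohorts with planted phenotypes.

There is no public reference dataset for this toolkit, so testing rests on
synthetic cohorts whose nutritional phenotypes are planted by construction:
base laboratory values are drawn from plausible clinical distributions, then
per-phenotype overrides push the relevant analytes decisively across the
classifier thresholds, so the expected code for the forced scores is known
in advance.  The distributions are test fixtures with clinically sensible
magnitudes, not a model of any real population.

Planted phenotypes and the codes they force:

==========================  =============================================
phenotype                   forced expectations
==========================  =============================================
healthy                     GLIM not applicable (BMI kept above cutoff);
                            VBD code 0
undernourished_inflamed     GLIM code 3 (low BMI, ASAPS >= 3, CRP > 10)
undernourished_clean        GLIM code 1 (low BMI, ASAPS 1, quiet markers)
overnourished               BWd code 2 (ABW > 1.15 x IBW)
b_deficient                 VBD code 1 (MCV > 102 fL, MCH > 35 pg)
iron_deficient              IDM applicable (AHB forced >= 21 g/L below
                            the ideal hemoglobin)
==========================  =============================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .anthropometry import AgeClass, classify_age, compute_ibw
from .core_model import DEFAULT_IHB_G_PER_L, PatientRecord, Sex

__all__ = ["Phenotype", "SyntheticTruth", "DEFAULT_MIX", "generate_cohort",
           "inject_missingness"]


class Phenotype(str, enum.Enum):
    HEALTHY = "healthy"
    UNDERNOURISHED_INFLAMED = "undernourished_inflamed"
    UNDERNOURISHED_CLEAN = "undernourished_clean"
    OVERNOURISHED = "overnourished"
    B_DEFICIENT = "b_deficient"
    IRON_DEFICIENT = "iron_deficient"


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted phenotype and the score codes it deterministically forces.

    ``expected_codes`` maps a score name to its forced code, with ``None``
    meaning the score is forced not-applicable (no code); only scores the
    phenotype forces appear.  ``expected_applicable`` asserts applicability
    without pinning a code (used for cohort-relative scores).
    """

    patient_id: str
    phenotype: Phenotype
    expected_codes: Mapping[str, Optional[int]] = field(default_factory=dict)
    expected_applicable: Mapping[str, bool] = field(default_factory=dict)


#: A plausible elective-orthopedic case mix; chosen once, documented in the
#: methods note, and deliberately weighted toward the phenotypes the
#: screening tools exist to find.
DEFAULT_MIX: Dict[Phenotype, float] = {
    Phenotype.HEALTHY: 0.55,
    Phenotype.UNDERNOURISHED_INFLAMED: 0.10,
    Phenotype.UNDERNOURISHED_CLEAN: 0.05,
    Phenotype.OVERNOURISHED: 0.15,
    Phenotype.B_DEFICIENT: 0.05,
    Phenotype.IRON_DEFICIENT: 0.10,
}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= low:
            return float(v)
    return low


def generate_cohort(
    n: int,
    seed: int,
    mix: Optional[Mapping[Phenotype, float]] = None,
) -> Tuple[List[PatientRecord], List[SyntheticTruth]]:
    """Draw ``n`` patients with planted phenotypes; reproducible per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(mix) if mix is not None else dict(DEFAULT_MIX)
    mix = {Phenotype(k): float(v) for k, v in mix.items()}
    total = sum(mix.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"phenotype mix must sum to 1, got {total}")
    if any(v < 0 for v in mix.values()):
        raise ValueError("phenotype proportions must be non-negative")

    rng = np.random.default_rng(seed)
    phenotypes = list(mix)
    probs = np.array([mix[p] for p in phenotypes])

    records: List[PatientRecord] = []
    truths: List[SyntheticTruth] = []
    for i in range(n):
        phenotype = phenotypes[rng.choice(len(phenotypes), p=probs)]
        pid = f"S{seed}-{i:05d}"
        rec, truth = _draw_patient(rng, pid, phenotype)
        records.append(rec)
        truths.append(truth)
    return records, truths


def _draw_patient(
    rng: np.random.Generator, pid: str, phenotype: Phenotype
) -> Tuple[PatientRecord, SyntheticTruth]:
    sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
    age = int(np.clip(round(rng.normal(68, 12)), 18, 95))
    age_class = classify_age(age)
    height = float(rng.normal(175, 7) if sex is Sex.MALE else rng.normal(162, 6))
    height = float(np.clip(height, 145, 205))
    ibw = compute_ibw(height, sex)
    ihb = DEFAULT_IHB_G_PER_L[sex]

    # base draws: a broadly unremarkable surgical patient
    bmi = _truncated_normal(rng, 26, 3, 18.5)
    alb = _truncated_normal(rng, 42, 3, 30)           # g/L
    crp = float(np.exp(rng.normal(np.log(2), 0.5)))   # mg/L
    lymc = _truncated_normal(rng, 2200, 400, 800)     # cells/uL
    neutc = _truncated_normal(rng, 4500, 900, 1000)   # cells/uL
    ahb = _truncated_normal(rng, 145, 10, 70)         # g/L
    mcv = _truncated_normal(rng, 90, 4, 60)
    mch = _truncated_normal(rng, 30, 1.5, 20)
    mchc = _truncated_normal(rng, 34, 1, 28)
    palb = _truncated_normal(rng, 250, 40, 50)        # mg/L
    asaps = int(rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2]))

    glim_cutoff = 22.0 if age_class is AgeClass.SENIOR else 20.0
    expected: Dict[str, Optional[int]] = {}
    expected_app: Dict[str, bool] = {}

    if phenotype is Phenotype.HEALTHY:
        # keep BMI clear of the GLIM cutoff so the diagnosis never applies
        bmi = max(bmi, 23.0)
        asaps = int(rng.choice([1, 2]))
        expected["GLIM"] = None
        expected["VBD"] = 0
    elif phenotype is Phenotype.UNDERNOURISHED_INFLAMED:
        bmi = float(rng.uniform(16.0, glim_cutoff - 1.0))
        asaps = int(rng.choice([3, 4]))
        crp = float(rng.uniform(10.5, 80.0))
        expected["GLIM"] = 3
    elif phenotype is Phenotype.UNDERNOURISHED_CLEAN:
        bmi = float(rng.uniform(16.0, glim_cutoff - 1.0))
        asaps = 1
        crp = float(rng.uniform(0.1, 1.9))
        neutc = lymc * float(rng.uniform(1.0, 1.9))   # NLR < 2
        expected["GLIM"] = 1
    elif phenotype is Phenotype.OVERNOURISHED:
        abw_over = ibw * float(rng.uniform(1.16, 1.40))
        bmi = abw_over / (height / 100.0) ** 2
        expected["BWd"] = 2
    elif phenotype is Phenotype.B_DEFICIENT:
        mcv = float(rng.uniform(103.0, 115.0))
        mch = float(rng.uniform(35.5, 40.0))
        expected["VBD"] = 1
    elif phenotype is Phenotype.IRON_DEFICIENT:
        ahb = ihb - float(rng.uniform(21.0, 45.0))
        expected_app["IDM"] = True

    abw = bmi * (height / 100.0) ** 2
    record = PatientRecord(
        patient_id=pid,
        age=age,
        sex=sex,
        abw=round(abw, 2),
        height=round(height, 1),
        alb=round(alb, 1),
        palb=round(palb, 1),
        crp=round(crp, 2),
        lymc=round(lymc, 0),
        neutc=round(neutc, 0),
        ahb=round(ahb, 1),
        mcv=round(mcv, 1),
        mch=round(mch, 1),
        mchc=round(mchc, 1),
        asaps=asaps,
    )
    truth = SyntheticTruth(
        patient_id=pid,
        phenotype=phenotype,
        expected_codes=expected,
        expected_applicable=expected_app,
    )
    return record, truth


def inject_missingness(
    records: Sequence[PatientRecord],
    rate: float,
    fields: Sequence[str],
    seed: int,
) -> List[PatientRecord]:
    """Blank each named field independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate!r}")
    valid = set(PatientRecord.__dataclass_fields__) - {"patient_id"}
    unknown = set(fields) - valid
    if unknown:
        raise ValueError(f"unknown field names: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out: List[PatientRecord] = []
    for rec in records:
        blank = [f for f in fields if rng.random() < rate]
        out.append(replace(rec, **{f: None for f in blank}) if blank else rec)
    return out
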