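"""Ideal body weight, BMI, age classes, age-adjusted BMI bands, and BWd.

Age classes follow the convention used throughout the toolkit: younger
adults are < 40 years, adults 40-69, seniors >= 70 (age 70 belongs to the
senior class).  BMI categories are age-adjusted: the usual WHO-style bands
apply below 70 years, while seniors use shifted bands in which BMI below
25 kg/m² already counts as underweight, reflecting the protective role of
higher body mass in old age.

BWd is the body-weight-difference score: the deviation of actual body
weight (ABW) from ideal body weight (IBW), flagged as risk of under- or
overnutrition when the deviation exceeds the minimal clinically important
difference of 10% of IBW.
"""

from __future__ import annotations

import enum
from typing import Optional

from .core_model import ScoreName, ScoreResult, Sex, not_applicable

__all__ = [
    "AgeClass",
    "BmiCategory",
    "compute_bmi",
    "compute_ibw",
    "classify_age",
    "classify_bmi",
    "compute_bwd",
]


class AgeClass(str, enum.Enum):
    YOUNGER_ADULT = "younger_adult"   # 18 <= age < 40
    ADULT = "adult"                   # 40 <= age < 70
    SENIOR = "senior"                 # age >= 70


class BmiCategory(str, enum.Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESITY_I = "obesity_I"
    OBESITY_II = "obesity_II"
    OBESITY_III = "obesity_III"


def compute_bmi(abw: float, height: float) -> float:
    """Quetelet index, kg/m², from weight in kg and height in cm."""
    if abw is None or abw <= 0:
        raise ValueError(f"abw must be > 0, got {abw!r}")
    if height is None or height <= 0:
        raise ValueError(f"height must be > 0, got {height!r}")
    return abw / (height / 100.0) ** 2


def compute_ibw(height: float, sex: Sex, formula: str = "lorenz") -> float:
    """Ideal body weight in kg from height (cm) and sex.

    Lorenz (default): H - 100 - (H - 150)/4 for men, H - 100 - (H - 150)/2.5
    for women.  Devine: 50 kg (men) / 45.5 kg (women) + 2.3 kg per inch of
    height over 5 ft.  Lorenz is the default because the geriatric
    nutritional risk index was developed with it.
    """
    if height is None or height <= 0:
        raise ValueError(f"height must be > 0, got {height!r}")
    sex = Sex(sex)
    if formula == "lorenz":
        if sex is Sex.MALE:
            ibw = height - 100.0 - (height - 150.0) / 4.0
        else:
            ibw = height - 100.0 - (height - 150.0) / 2.5
    elif formula == "devine":
        inches_over_5ft = height / 2.54 - 60.0
        base = 50.0 if sex is Sex.MALE else 45.5
        ibw = base + 2.3 * inches_over_5ft
    else:
        raise ValueError(f"unknown IBW formula {formula!r}")
    if ibw <= 0:
        raise ValueError(
            f"IBW formula {formula!r} yields non-positive weight at height {height} cm"
        )
    return ibw


def classify_age(age: int) -> AgeClass:
    if age < 18:
        raise ValueError(f"age must be >= 18, got {age!r}")
    if age < 40:
        return AgeClass.YOUNGER_ADULT
    if age < 70:
        return AgeClass.ADULT
    return AgeClass.SENIOR


# (upper bound, category) pairs; value < bound selects the category.
_ADULT_BANDS = [
    (18.5, BmiCategory.UNDERWEIGHT),
    (25.0, BmiCategory.NORMAL),
    (30.0, BmiCategory.OVERWEIGHT),
    (35.0, BmiCategory.OBESITY_I),
    (40.0, BmiCategory.OBESITY_II),
]
# Senior bands are closed on the upper side (25.0-35.0 normal includes 35.0),
# so the comparison is value <= bound.
_SENIOR_BANDS = [
    (25.0, BmiCategory.UNDERWEIGHT),
    (35.0, BmiCategory.NORMAL),
    (40.0, BmiCategory.OVERWEIGHT),
    (45.0, BmiCategory.OBESITY_I),
    (50.0, BmiCategory.OBESITY_II),
]


def classify_bmi(bmi: float, age_class: AgeClass) -> BmiCategory:
    """Age-adjusted BMI category; total on (0, inf) for every age class."""
    if bmi is None or bmi <= 0:
        raise ValueError(f"bmi must be > 0, got {bmi!r}")
    age_class = AgeClass(age_class)
    if age_class is AgeClass.SENIOR:
        # senior underweight band is [0, 25); the remaining bands are
        # upper-closed: (25, 35] normal, (35, 40] overweight, ...
        if bmi < 25.0:
            return BmiCategory.UNDERWEIGHT
        for bound, cat in _SENIOR_BANDS[1:]:
            if bmi <= bound:
                return cat
        return BmiCategory.OBESITY_III
    for bound, cat in _ADULT_BANDS:
        if bmi < bound:
            return cat
    return BmiCategory.OBESITY_III


def compute_bwd(abw: Optional[float], ibw: Optional[float]) -> ScoreResult:
    """Body weight difference score, ABW - IBW in kg.

    Code 1 (risk of undernutrition) when the loss exceeds 10% of IBW, code 2
    (risk of overnutrition) when the gain exceeds 10% of IBW, code 0 when the
    deviation is within the 10% band; a deviation of exactly 10% is not
    "greater than" the threshold and codes 0.
    """
    if abw is None or ibw is None:
        return not_applicable(ScoreName.BWD, "missing ABW or height (IBW)")
    if abw <= 0 or ibw <= 0:
        raise ValueError("abw and ibw must be > 0")
    value = abw - ibw
    if abw < 0.9 * ibw:
        code = 1
    elif abw > 1.1 * ibw:
        code = 2
    else:
        code = 0
    return ScoreResult(score_name=ScoreName.BWD, value=value, code=code)
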