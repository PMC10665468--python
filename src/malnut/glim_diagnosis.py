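"""Routine-data GLIM diagnostic classifier.

The GLIM framework diagnoses malnutrition from at least one phenotypic plus
one etiologic criterion.  When only routine data are available the
phenotypic criterion is low BMI (< 20 kg/m² below 70 years, < 22 kg/m² from
70) and the etiologic criteria are proxied by disease burden (ASA physical
status >= 2) and inflammation (CRP > 5 mg/L or NLR >= 6):

* code 1, clean undernutrition: low BMI with no disease burden and no
  inflammation;
* code 2, disease-related malnutrition (DRM) without inflammation: low BMI
  with elevated ASA class but quiet inflammatory markers;
* code 3, DRM with inflammation: low BMI with elevated ASA class and at
  least one inflammatory marker elevated.

A patient whose BMI is at or above the cutoff is outside the classifier's
domain (not applicable), as is the combination low-BMI + no disease burden +
inflamed markers, which matches no defined class and is flagged rather than
forced.  When the two inflammation markers disagree, the DRM-with-
inflammation class takes precedence: one elevated marker is taken as
evidence of an inflammatory etiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .anthropometry import AgeClass

__all__ = ["GlimThresholds", "GlimResult", "classify_glim"]


@dataclass(frozen=True)
class GlimThresholds:
    """Cutoffs for the routine-data GLIM criteria (defaults as published)."""

    asaps_min: int = 2        # disease burden: ASAPS >= 2
    crp_max: float = 5.0      # inflammation: CRP > 5 mg/L
    nlr_min: float = 6.0      # inflammation: NLR >= 6
    bmi_adult: float = 20.0   # low BMI below 70 years
    bmi_senior: float = 22.0  # low BMI from 70 years

    def __post_init__(self) -> None:
        if min(self.asaps_min, self.crp_max, self.nlr_min,
               self.bmi_adult, self.bmi_senior) <= 0:
            raise ValueError("GLIM thresholds must be positive")
        if self.bmi_senior < self.bmi_adult:
            raise ValueError("senior BMI cutoff must be >= adult cutoff")


@dataclass(frozen=True)
class GlimResult:
    """Diagnosis code (1/2/3) or not-applicable, with the fired criteria."""

    code: Optional[int]
    applicable: bool
    reason: str = ""
    criteria_fired: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.applicable and self.code is not None:
            raise ValueError("not-applicable GLIM result must carry no code")
        if self.code is not None and not self.criteria_fired.get("low_bmi", False):
            raise ValueError("a GLIM code requires the low-BMI criterion")


def classify_glim(
    bmi: Optional[float],
    age_class: AgeClass,
    asaps: Optional[int],
    crp: Optional[float],
    nlr: Optional[float],
    th: GlimThresholds = GlimThresholds(),
) -> GlimResult:
    """Classify one patient under the routine-data GLIM criteria.

    ``bmi`` kg/m², ``crp`` mg/L, ``nlr`` dimensionless, ``asaps`` 1-6.
    Missing inputs yield a not-applicable result naming the missing field.
    """
    for name, val in (("BMI", bmi), ("ASAPS", asaps), ("CRP", crp), ("NLR", nlr)):
        if val is None:
            return GlimResult(code=None, applicable=False, reason=f"missing {name}")
    if asaps not in range(1, 7):
        raise ValueError(f"asaps must be in 1..6, got {asaps!r}")

    age_class = AgeClass(age_class)
    cutoff = th.bmi_senior if age_class is AgeClass.SENIOR else th.bmi_adult
    low_bmi = bmi < cutoff
    fired = {"low_bmi": low_bmi}
    if not low_bmi:
        return GlimResult(
            code=None,
            applicable=False,
            reason=f"BMI >= cutoff ({cutoff:g})",
            criteria_fired=fired,
        )

    asaps_high = asaps >= th.asaps_min
    crp_high = crp > th.crp_max
    nlr_high = nlr >= th.nlr_min
    fired.update(asaps_high=asaps_high, crp_high=crp_high, nlr_high=nlr_high)

    if asaps_high and (crp_high or nlr_high):
        code = 3
    elif asaps_high:
        code = 2
    elif not crp_high and not nlr_high:
        code = 1
    else:
        # low BMI, no disease burden, but inflamed markers: no defined class
        return GlimResult(
            code=None,
            applicable=False,
            reason="unclassifiable combination (inflammation without disease burden)",
            criteria_fired=fired,
        )
    return GlimResult(code=code, applicable=True, criteria_fired=fired)
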