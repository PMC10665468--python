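"""Laboratory-based malnutrition screening scores.

Seven scores computed from routine labs:

* GNRI  - geriatric nutritional risk index, 1.489·ALB(g/L) + 41.7·ABW/IBW.
* INA   - instant nutritional assessment, joint albumin/lymphocyte classes.
* LxA   - lymphocyte count x albumin product.
* PMA   - CRP/albumin ratio (protein malnutrition with acute inflammation).
* PMAC  - (NLR + CRP)/(ALB + PALB), acute-and-chronic inflammation variant;
          coded cohort-relative (see :mod:`malnut.cohort_coding`).
* IDM   - total-body iron deficit by the Ganzoni equation; coded
          cohort-relative.
* VBD   - functional vitamin-B deficiency from macrocytic red-cell indices.

plus the neutrophil-to-lymphocyte ratio (NLR) and its inflammation grading.

All published cutoffs live in the read-only :data:`THRESHOLDS` registry so
documentation and tests share one source of truth.  Functions take canonical
units (see :mod:`malnut.core_model`) and convert internally to the unit each
printed formula uses; albumin, for instance, enters INA/LxA/PMA/PMAC in g/dL.
"""

from __future__ import annotations

import enum
from types import MappingProxyType
from typing import Optional

from .core_model import ScoreName, ScoreResult, not_applicable

__all__ = [
    "NlrGrade",
    "VbdRefRanges",
    "THRESHOLDS",
    "compute_nlr",
    "grade_nlr",
    "compute_gnri",
    "code_gnri",
    "classify_ina",
    "compute_lxa",
    "code_lxa",
    "compute_pma",
    "code_pma",
    "compute_pmac",
    "compute_idm",
    "classify_vbd",
]


class NlrGrade(str, enum.Enum):
    NORMAL = "normal"       # NLR < 2
    LOW = "low"             # 2 <= NLR < 4
    MILD = "mild"           # 4 <= NLR < 6
    MODERATE = "moderate"   # 6 <= NLR < 8
    SEVERE = "severe"       # NLR >= 8


#: Published cutoffs, one source of truth for code, docs and tests.
THRESHOLDS = MappingProxyType(
    {
        "gnri": (82.0, 92.0, 98.0),          # major / moderate / low / no risk
        "lxa": (4515.0, 7920.0),             # poor / middle / good
        "pma": (0.4, 1.2, 2.0),              # no / low / moderate / high
        "ina_alb_gdl": 3.5,
        "ina_lymc": 1500.0,
        "nlr_grades": (2.0, 4.0, 6.0, 8.0),  # normal / low / mild / moderate / severe
        "bwd_rel": 0.10,                     # MCID, fraction of IBW
    }
)


from dataclasses import dataclass


@dataclass(frozen=True)
class VbdRefRanges:
    """Upper/lower reference limits for the red-cell indices used by VBD."""

    mcv_high: float = 100.0   # fL
    mch_high: float = 34.0    # pg
    mchc_low: float = 32.0    # g/dL

    def __post_init__(self) -> None:
        if min(self.mcv_high, self.mch_high, self.mchc_low) <= 0:
            raise ValueError("VBD reference limits must be strictly positive")


def compute_nlr(neutc: Optional[float], lymc: Optional[float]) -> float:
    """Neutrophil-to-lymphocyte ratio from counts in cells/µL."""
    if neutc is None or lymc is None:
        raise ValueError("NLR requires both neutrophil and lymphocyte counts")
    if lymc <= 0:
        raise ValueError("lymphocyte count must be > 0 for NLR")
    return neutc / lymc


def grade_nlr(nlr: float) -> NlrGrade:
    """Chronic-inflammation grade of an NLR value; total on [0, inf)."""
    if nlr < 0:
        raise ValueError(f"NLR must be >= 0, got {nlr!r}")
    g2, g4, g6, g8 = THRESHOLDS["nlr_grades"]
    if nlr < g2:
        return NlrGrade.NORMAL
    if nlr < g4:
        return NlrGrade.LOW
    if nlr < g6:
        return NlrGrade.MILD
    if nlr < g8:
        return NlrGrade.MODERATE
    return NlrGrade.SEVERE


def code_gnri(value: float) -> int:
    """Risk code for a GNRI value: 3 major (<82), 2 moderate [82,92),
    1 low [92,98], 0 no risk (>98)."""
    major, moderate, low = THRESHOLDS["gnri"]
    if value < major:
        return 3
    if value < moderate:
        return 2
    if value <= low:
        return 1
    return 0


def compute_gnri(
    alb: Optional[float],
    abw: Optional[float],
    ibw: Optional[float],
    cap_ratio: bool = True,
) -> ScoreResult:
    """Geriatric nutritional risk index.

    ``alb`` in g/L; ``abw``/``ibw`` in kg.  The weight ratio ABW/IBW is
    capped at 1 by default, as in the original index (a weight above ideal
    does not offset hypoalbuminemia).
    """
    if alb is None:
        return not_applicable(ScoreName.GNRI, "missing ALB")
    if abw is None or ibw is None:
        return not_applicable(ScoreName.GNRI, "missing ABW or height (IBW)")
    if abw <= 0 or ibw <= 0:
        raise ValueError("abw and ibw must be > 0")
    if alb < 0:
        raise ValueError("alb must be >= 0")
    ratio = abw / ibw
    if cap_ratio and ratio > 1.0:
        ratio = 1.0
    value = 1.489 * alb + 41.7 * ratio
    return ScoreResult(score_name=ScoreName.GNRI, value=value, code=code_gnri(value))


def classify_ina(alb: Optional[float], lymc: Optional[float]) -> ScoreResult:
    """Instant nutritional assessment.

    ``alb`` in g/L (converted internally to g/dL), ``lymc`` in cells/µL.
    Codes: 0 no risk, 1 protein risk (low albumin only), 2 energy risk (low
    lymphocytes only), 3 protein-energy risk (both low).
    """
    if alb is None or lymc is None:
        return not_applicable(ScoreName.INA, "missing ALB or LYMPC")
    alb_gdl = alb / 10.0
    low_alb = alb_gdl < THRESHOLDS["ina_alb_gdl"]
    low_lym = lymc < THRESHOLDS["ina_lymc"]
    code = {
        (False, False): 0,
        (True, False): 1,
        (False, True): 2,
        (True, True): 3,
    }[(low_alb, low_lym)]
    return ScoreResult(score_name=ScoreName.INA, code=code)


def code_lxa(value: float) -> int:
    """2 poor (<= 4515), 1 middle (4515, 7920], 0 good (> 7920)."""
    poor, middle = THRESHOLDS["lxa"]
    if value <= poor:
        return 2
    if value <= middle:
        return 1
    return 0


def compute_lxa(lymc: Optional[float], alb: Optional[float]) -> ScoreResult:
    """Lymphocyte count (cells/µL) x albumin (g/dL) product score."""
    if lymc is None or alb is None:
        return not_applicable(ScoreName.LXA, "missing LYMPC or ALB")
    value = lymc * (alb / 10.0)
    return ScoreResult(score_name=ScoreName.LXA, value=value, code=code_lxa(value))


def code_pma(value: float) -> int:
    """0 no risk (<0.4), 1 low [0.4,1.2), 2 moderate [1.2,2.0), 3 high (>=2.0)."""
    low, moderate, high = THRESHOLDS["pma"]
    if value < low:
        return 0
    if value < moderate:
        return 1
    if value < high:
        return 2
    return 3


def compute_pma(crp: Optional[float], alb: Optional[float]) -> ScoreResult:
    """CRP (mg/L) / albumin (g/dL) ratio score."""
    if crp is None or alb is None or alb == 0:
        return not_applicable(ScoreName.PMA, "missing CRP or ALB")
    value = crp / (alb / 10.0)
    return ScoreResult(score_name=ScoreName.PMA, value=value, code=code_pma(value))


def compute_pmac(
    nlr: Optional[float],
    crp: Optional[float],
    alb: Optional[float],
    palb: Optional[float],
) -> ScoreResult:
    """(NLR + CRP mg/L) / (ALB g/dL + PALB mg/L) composite.

    The continuous value is always returned; the 0-3 code is assigned later
    against the cohort's own quartiles, so the result carries ``code=None``
    until :func:`malnut.cohort_coding.quartile_codes` runs.  To keep the
    applicable/coded contract honest, the uncoded-but-applicable state is
    represented with a provisional code of -1 replaced during cohort coding.
    """
    if nlr is None or crp is None or alb is None or palb is None:
        return not_applicable(ScoreName.PMAC, "missing CRP, NLR, ALB, or PALB")
    denom = alb / 10.0 + palb
    if denom <= 0:
        return not_applicable(ScoreName.PMAC, "missing CRP, NLR, ALB, or PALB")
    value = (nlr + crp) / denom
    return ScoreResult(score_name=ScoreName.PMAC, value=value, code=-1)


def compute_idm(
    abw: Optional[float], ihb: Optional[float], ahb: Optional[float]
) -> ScoreResult:
    """Total-body iron deficit (mg) by the Ganzoni equation.

    ``abw`` in kg; ``ihb`` (ideal) and ``ahb`` (actual) hemoglobin in g/L.
    The classical factor 2.4 presumes the hemoglobin difference in g/dL, so
    the g/L difference is divided by 10 before multiplying; with that
    convention the value is ABW x (IHB - AHB)[g/dL] x 2.4 + 500 mg, exactly
    500 mg when actual equals ideal hemoglobin.  Like PMAC, the 0-3 code is
    cohort-relative and provisional (-1) until cohort coding.
    """
    if abw is None:
        return not_applicable(ScoreName.IDM, "missing ABW")
    if ahb is None or ihb is None:
        return not_applicable(ScoreName.IDM, "missing AHB or IHB")
    if abw <= 0:
        raise ValueError("abw must be > 0")
    if ihb < ahb:
        return not_applicable(ScoreName.IDM, "IHB lower than AHB")
    value = abw * ((ihb - ahb) / 10.0) * 2.4 + 500.0
    return ScoreResult(score_name=ScoreName.IDM, value=value, code=-1)


def classify_vbd(
    mcv: Optional[float],
    mch: Optional[float],
    mchc: Optional[float],
    refs: VbdRefRanges = VbdRefRanges(),
    macrocytosis_required: bool = True,
) -> ScoreResult:
    """Functional vitamin-B deficiency from red-cell indices.

    Default logic targets macrocytic hyperchromic anemia: code 1 iff MCV is
    elevated AND (MCH elevated OR MCHC depressed).  Setting
    ``macrocytosis_required=False`` switches to the alternative precedence
    (MCV high AND MCH high) OR MCHC low.
    """
    if mcv is None or mch is None or mchc is None:
        return not_applicable(ScoreName.VBD, "missing MCV, MCH or MCHC")
    mcv_up = mcv > refs.mcv_high
    mch_up = mch > refs.mch_high
    mchc_down = mchc < refs.mchc_low
    if macrocytosis_required:
        deficient = mcv_up and (mch_up or mchc_down)
    else:
        deficient = (mcv_up and mch_up) or mchc_down
    return ScoreResult(score_name=ScoreName.VBD, code=1 if deficient else 0)
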