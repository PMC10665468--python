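"""Canonical domain types, unit conversion, and the applicability contract.

Every score in this package works on a :class:`PatientRecord` holding values
in one fixed set of canonical units (albumin g/L, prealbumin mg/L, CRP mg/L,
cell counts cells/µL, hemoglobin g/L, MCHC g/dL).  Formulas that are printed
in other units (e.g. albumin in g/dL for the CRP/albumin ratio) convert
internally; storage never mixes dialects, which prevents silent factor-of-10
errors.

Missingness is explicit: an absent measurement is ``None``, never a sentinel
number, and each score checks its own requirement list before computing.  A
score that cannot be computed returns a :class:`ScoreResult` with
``applicable=False`` and a human-readable reason naming the limitation that
fired.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "Sex",
    "ScoreName",
    "Analyte",
    "PatientRecord",
    "ScoreResult",
    "UnitsConfig",
    "CANONICAL_UNITS",
    "UNIT_FACTORS",
    "to_canonical",
    "from_canonical",
    "not_applicable",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class ScoreName(str, enum.Enum):
    """The nine scores of the toolkit (one diagnostic, eight screening)."""

    GLIM = "GLIM"
    BWD = "BWd"
    GNRI = "GNRI"
    INA = "INA"
    LXA = "LxA"
    PMA = "PMA"
    PMAC = "PMAC"
    IDM = "IDM"
    VBD = "VBD"


class Analyte(str, enum.Enum):
    ALBUMIN = "albumin"
    PREALBUMIN = "prealbumin"
    CRP = "crp"
    LYMPHOCYTES = "lymphocytes"
    NEUTROPHILS = "neutrophils"
    HEMOGLOBIN = "hemoglobin"
    MCV = "mcv"
    MCH = "mch"
    MCHC = "mchc"
    WEIGHT = "weight"
    HEIGHT = "height"


#: Canonical storage unit per analyte.
CANONICAL_UNITS: Mapping[Analyte, str] = {
    Analyte.ALBUMIN: "g/L",
    Analyte.PREALBUMIN: "mg/L",
    Analyte.CRP: "mg/L",
    Analyte.LYMPHOCYTES: "cells/uL",
    Analyte.NEUTROPHILS: "cells/uL",
    Analyte.HEMOGLOBIN: "g/L",
    Analyte.MCV: "fL",
    Analyte.MCH: "pg",
    Analyte.MCHC: "g/dL",
    Analyte.WEIGHT: "kg",
    Analyte.HEIGHT: "cm",
}

#: Supported source-unit dialects per analyte, as exact multiplicative
#: factors onto the canonical unit.
UNIT_FACTORS: Mapping[Analyte, Mapping[str, float]] = {
    Analyte.ALBUMIN: {"g/L": 1.0, "g/dL": 10.0, "mg/mL": 1.0},
    Analyte.PREALBUMIN: {"mg/L": 1.0, "mg/dL": 10.0, "g/L": 1000.0},
    Analyte.CRP: {"mg/L": 1.0, "mg/dL": 10.0, "ug/mL": 1.0},
    Analyte.LYMPHOCYTES: {"cells/uL": 1.0, "10^9/L": 1000.0, "10^3/uL": 1000.0},
    Analyte.NEUTROPHILS: {"cells/uL": 1.0, "10^9/L": 1000.0, "10^3/uL": 1000.0},
    Analyte.HEMOGLOBIN: {"g/L": 1.0, "g/dL": 10.0},
    Analyte.MCV: {"fL": 1.0},
    Analyte.MCH: {"pg": 1.0},
    Analyte.MCHC: {"g/dL": 1.0, "g/L": 0.1},
    Analyte.WEIGHT: {"kg": 1.0, "g": 0.001},
    Analyte.HEIGHT: {"cm": 1.0, "m": 100.0, "mm": 0.1},
}


class UnitError(ValueError):
    """Raised for a unit dialect not supported for an analyte."""


def to_canonical(raw_value: float, analyte: Analyte, source_unit: str) -> float:
    """Convert ``raw_value`` from ``source_unit`` to the analyte's canonical unit.

    Conversion is exact multiplication by a fixed factor; the supported
    dialects are listed in :data:`UNIT_FACTORS`.
    """
    analyte = Analyte(analyte)
    try:
        factor = UNIT_FACTORS[analyte][source_unit]
    except KeyError:
        supported = ", ".join(UNIT_FACTORS[analyte])
        raise UnitError(
            f"unsupported unit {source_unit!r} for analyte {analyte.value!r}; "
            f"supported: {supported}"
        ) from None
    return raw_value * factor


def from_canonical(value: float, analyte: Analyte, target_unit: str) -> float:
    """Inverse of :func:`to_canonical`."""
    analyte = Analyte(analyte)
    try:
        factor = UNIT_FACTORS[analyte][target_unit]
    except KeyError:
        supported = ", ".join(UNIT_FACTORS[analyte])
        raise UnitError(
            f"unsupported unit {target_unit!r} for analyte {analyte.value!r}; "
            f"supported: {supported}"
        ) from None
    return value / factor


def _check_nonneg(name: str, value: Optional[float], strict: bool = False) -> None:
    if value is None:
        return
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if strict and value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")
    if not strict and value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One subject's demographics, anthropometry, labs and ASA class.

    All values are in canonical units.  Every field except ``patient_id`` may
    be ``None`` (missing).  Units: age years, weight kg, height cm, albumin
    g/L, prealbumin mg/L, CRP mg/L, counts cells/µL, hemoglobin g/L, MCV fL,
    MCH pg, MCHC g/dL; ``asaps`` is the ASA physical status class 1 (healthy)
    to 6 (brain-dead).
    """

    patient_id: str
    age: Optional[int] = None
    sex: Optional[Sex] = None
    abw: Optional[float] = None       # actual body weight, kg
    height: Optional[float] = None    # cm
    alb: Optional[float] = None       # serum albumin, g/L
    palb: Optional[float] = None      # prealbumin, mg/L
    crp: Optional[float] = None       # C-reactive protein, mg/L
    lymc: Optional[float] = None      # lymphocyte count, cells/uL
    neutc: Optional[float] = None     # neutrophil count, cells/uL
    ahb: Optional[float] = None       # actual hemoglobin, g/L
    mcv: Optional[float] = None       # fL
    mch: Optional[float] = None       # pg
    mchc: Optional[float] = None      # g/dL
    asaps: Optional[int] = None       # ASA physical status, 1..6

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be a non-empty string")
        if self.age is not None:
            if self.age < 18:
                raise ValueError(
                    f"age must be >= 18 (adult cohorts only), got {self.age}"
                )
        if self.sex is not None:
            object.__setattr__(self, "sex", Sex(self.sex))
        _check_nonneg("abw", self.abw, strict=True)
        _check_nonneg("height", self.height, strict=True)
        for name in ("alb", "palb", "crp", "lymc", "neutc", "ahb", "mcv", "mch", "mchc"):
            _check_nonneg(name, getattr(self, name))
        if self.asaps is not None and self.asaps not in range(1, 7):
            raise ValueError(f"asaps must be in 1..6, got {self.asaps!r}")

    def with_missing(self, *fields: str) -> "PatientRecord":
        """Return a copy with the named fields blanked."""
        return replace(self, **{f: None for f in fields})


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of one score for one patient.

    ``value`` is the continuous score where the score has one (absent for
    purely nominal scores such as INA, VBD, GLIM).  ``code`` is the ordinal
    risk/diagnosis code.  When the score is not applicable, ``value`` and
    ``code`` are absent and ``reason`` explains which limitation fired.
    """

    score_name: ScoreName
    value: Optional[float] = None
    code: Optional[int] = None
    applicable: bool = True
    reason: str = ""
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "score_name", ScoreName(self.score_name))
        if not self.applicable:
            if self.code is not None or self.value is not None:
                raise ValueError(
                    "not-applicable result must carry no value and no code"
                )
            if not self.reason:
                raise ValueError("not-applicable result requires a reason")
        else:
            if self.code is None:
                raise ValueError("applicable result requires a code")


def not_applicable(score_name: ScoreName, reason: str, **extra: object) -> ScoreResult:
    """Build a not-applicable :class:`ScoreResult` with a mandatory reason."""
    if not reason:
        raise ValueError("a not-applicable result requires a non-empty reason")
    return ScoreResult(
        score_name=ScoreName(score_name), applicable=False, reason=reason, extra=extra
    )


# Default ideal hemoglobin (Ganzoni target), g/L by sex.
DEFAULT_IHB_G_PER_L: Mapping[Sex, float] = {Sex.MALE: 150.0, Sex.FEMALE: 140.0}


@dataclass
class UnitsConfig:
    """Declared source units and column mapping for CSV ingestion.

    ``units`` maps analyte name to the source-unit dialect of the input file;
    anything omitted is assumed already canonical.  ``columns`` maps the
    record field name (``alb``, ``crp`` ...) to the CSV column holding it;
    omitted fields are treated as absent from the file.  ``ihb_policy`` gives
    the ideal hemoglobin in g/L by sex used by the iron-deficit score.
    """

    units: dict = field(default_factory=dict)        # analyte -> source unit
    columns: dict = field(default_factory=dict)      # field -> column name
    ihb_policy: dict = field(
        default_factory=lambda: {s.value: v for s, v in DEFAULT_IHB_G_PER_L.items()}
    )
    ibw_formula: str = "lorenz"

    def __post_init__(self) -> None:
        seen: dict = {}
        for fld, col in self.columns.items():
            if col in seen:
                raise ValueError(
                    f"column {col!r} mapped to both {seen[col]!r} and {fld!r}"
                )
            seen[col] = fld
        for analyte, unit in self.units.items():
            a = Analyte(analyte)
            if unit not in UNIT_FACTORS[a]:
                supported = ", ".join(UNIT_FACTORS[a])
                raise UnitError(
                    f"unsupported unit {unit!r} for analyte {a.value!r}; "
                    f"supported: {supported}"
                )
        if self.ibw_formula not in ("lorenz", "devine"):
            raise ValueError(f"unknown IBW formula {self.ibw_formula!r}")

    def ihb_for(self, sex: Sex) -> float:
        return float(self.ihb_policy[Sex(sex).value])
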