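"""CSV ingestion and scored-output writing.

The CSV dialect is fixed: comma-separated, header row required, ``.`` as
decimal separator, UTF-8.  Column names default to the record field names
(``patient_id``, ``age``, ``sex``, ``abw``, ``height``, ``alb``, ``palb``,
``crp``, ``lymc``, ``neutc``, ``ahb``, ``mcv``, ``mch``, ``mchc``,
``asaps``); a :class:`~malnut.core_model.UnitsConfig` can remap columns and
declare non-canonical source units, which are converted at ingestion.
Malformed numeric cells become missing values with a logged warning naming
the row and column; a duplicate patient id or an absent mapped column is a
hard error.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional

import pandas as pd

from .cohort_coding import CodedCohort
from .core_model import Analyte, PatientRecord, ScoreName, UnitsConfig, to_canonical
from .pipeline import SCORE_ORDER

logger = logging.getLogger("malnut")

__all__ = ["read_cohort", "write_scores", "write_summary"]

#: Record field -> analyte used for unit conversion (None: unitless/integer).
FIELD_ANALYTE: Dict[str, Optional[Analyte]] = {
    "abw": Analyte.WEIGHT,
    "height": Analyte.HEIGHT,
    "alb": Analyte.ALBUMIN,
    "palb": Analyte.PREALBUMIN,
    "crp": Analyte.CRP,
    "lymc": Analyte.LYMPHOCYTES,
    "neutc": Analyte.NEUTROPHILS,
    "ahb": Analyte.HEMOGLOBIN,
    "mcv": Analyte.MCV,
    "mch": Analyte.MCH,
    "mchc": Analyte.MCHC,
}

NUMERIC_FIELDS = list(FIELD_ANALYTE)
INT_FIELDS = ["age", "asaps"]
ALL_FIELDS = ["patient_id", "age", "sex"] + NUMERIC_FIELDS + ["asaps"]

_SEX_ALIASES = {"male": "male", "m": "male", "female": "female", "f": "female"}


def _parse_float(cell: object, row: int, column: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(text)
    except ValueError:
        logger.warning("row %d, column %r: malformed value %r treated as missing",
                       row, column, text)
        return None


def read_cohort(path: str, cfg: Optional[UnitsConfig] = None) -> List[PatientRecord]:
    """Read a patient CSV into canonical-unit records."""
    cfg = cfg or UnitsConfig()
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if frame.empty and frame.columns.empty:
        raise ValueError(f"{path}: empty file")

    colmap = {f: cfg.columns.get(f, f) for f in ALL_FIELDS}
    missing_mapped = [
        col for f, col in colmap.items() if f in cfg.columns and col not in frame.columns
    ]
    if missing_mapped:
        raise ValueError(f"{path}: mapped columns absent from header: {missing_mapped}")
    if colmap["patient_id"] not in frame.columns:
        raise ValueError(f"{path}: no {colmap['patient_id']!r} column")

    records: List[PatientRecord] = []
    seen = set()
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # 1-based, after header
        pid = str(row[colmap["patient_id"]]).strip()
        if not pid:
            raise ValueError(f"{path}: row {rownum}: empty patient_id")
        if pid in seen:
            raise ValueError(f"{path}: duplicate patient_id {pid!r}")
        seen.add(pid)

        kwargs: dict = {"patient_id": pid}
        for f in INT_FIELDS:
            col = colmap[f]
            if col in frame.columns:
                v = _parse_float(row[col], rownum, col)
                kwargs[f] = None if v is None else int(round(v))
        col = colmap["sex"]
        if col in frame.columns:
            raw = str(row[col]).strip().lower()
            kwargs["sex"] = _SEX_ALIASES.get(raw) if raw else None
            if raw and kwargs["sex"] is None:
                logger.warning("row %d, column %r: unrecognized sex %r treated as missing",
                               rownum, col, raw)
        for f in NUMERIC_FIELDS:
            col = colmap[f]
            if col not in frame.columns:
                continue
            v = _parse_float(row[col], rownum, col)
            if v is not None:
                analyte = FIELD_ANALYTE[f]
                unit = cfg.units.get(analyte.value)
                if unit is not None:
                    v = to_canonical(v, analyte, unit)
            kwargs[f] = v
        records.append(PatientRecord(**kwargs))
    if not records:
        raise ValueError(f"{path}: no data rows")
    return records


def write_scores(cohort: CodedCohort, path: str) -> None:
    """Write one row per patient with value/code/applicable/reason per score.

    Column order is stable; a not-applicable score leaves its value and code
    cells empty and populates the reason (a cohort too small for quartile
    coding still reports the continuous PMAC/IDM value).
    """
    rows = []
    for record in cohort.records:
        row: dict = {"patient_id": record.patient_id}
        per = cohort.results[record.patient_id]
        for score in SCORE_ORDER:
            if score not in per:
                continue
            res = per[score]
            prefix = score.value
            value = res.value
            if value is None:
                value = res.extra.get("uncoded_value")
            row[f"{prefix}_value"] = "" if value is None else repr(float(value))
            row[f"{prefix}_code"] = "" if res.code is None else res.code
            row[f"{prefix}_applicable"] = int(res.applicable)
            row[f"{prefix}_reason"] = res.reason
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def write_summary(cohort: CodedCohort, path: str) -> None:
    """Write the per-score code counts/proportions summary as CSV."""
    cohort.summary.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
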