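"""Cohort-relative quartile coding and cohort-level summaries.

Two scores (PMAC and IDM) have no published cutoffs; their 0-3 codes are
assigned against the scoring cohort's own quartiles: below the 25th
percentile codes 0, [25th, 50th) codes 1, [50th, 75th) codes 2, and at or
above the 75th percentile codes 3.  Percentiles are estimated by linear
interpolation over the non-missing values (the inclusive method, R type 7 /
numpy default), so ties share a code and an all-equal cohort degenerates to
everyone at code 3 (every value >= its own 75th percentile).  A cohort with
fewer than four codable values cannot define quartiles; coding is then
refused explicitly rather than silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import PatientRecord, ScoreName, ScoreResult, not_applicable

__all__ = ["MIN_COHORT_FOR_QUARTILES", "quartile_codes", "CodedCohort", "summarize"]

MIN_COHORT_FOR_QUARTILES = 4


def quartile_codes(values: Sequence[Optional[float]]) -> List[Optional[int]]:
    """Code each value against the cohort's own quartiles.

    ``None`` entries stay ``None`` (they keep their not-applicable status);
    fewer than four non-missing values yields all-``None``.
    """
    present = np.asarray([v for v in values if v is not None], dtype=float)
    if present.size < MIN_COHORT_FOR_QUARTILES:
        return [None] * len(values)
    q25, q50, q75 = np.percentile(present, [25, 50, 75], method="linear")

    def code(v: float) -> int:
        if v < q25:
            return 0
        if v < q50:
            return 1
        if v < q75:
            return 2
        return 3

    return [None if v is None else code(v) for v in values]


@dataclass
class CodedCohort:
    """A scored cohort: records, per-patient score results, and a summary."""

    records: List[PatientRecord]
    results: Dict[str, Dict[ScoreName, ScoreResult]]  # patient_id -> score -> result
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        ids = {r.patient_id for r in self.records}
        if set(self.results) != ids:
            raise ValueError("results must cover exactly the cohort's patient ids")

    @property
    def scores(self) -> List[ScoreName]:
        for per_patient in self.results.values():
            return sorted(per_patient, key=lambda s: s.value)
        return []


def apply_cohort_coding(cohort: "CodedCohort") -> None:
    """Replace provisional codes of cohort-relative scores with quartile codes.

    PMAC and IDM results arrive with a provisional code of -1; this pass
    recodes them in place against the cohort's applicable values.  When the
    cohort is too small for quartiles the result becomes not-applicable but
    the continuous value is preserved under ``extra['uncoded_value']`` so
    users pooling cohorts can still retrieve it.
    """
    for score in (ScoreName.PMAC, ScoreName.IDM):
        ids = [
            pid
            for pid, per in cohort.results.items()
            if score in per and per[score].applicable
        ]
        values = [cohort.results[pid][score].value for pid in ids]
        codes = quartile_codes(values)
        for pid, value, code in zip(ids, values, codes):
            if code is None:
                res = not_applicable(
                    score,
                    "insufficient cohort size for percentile coding",
                    uncoded_value=value,
                )
            else:
                res = ScoreResult(score_name=score, value=value, code=code)
            cohort.results[pid][score] = res


def summarize(cohort: CodedCohort) -> pd.DataFrame:
    """Per-score counts and proportions by code, plus not-applicable reasons.

    One row per (score, kind, key): kind ``code`` rows carry count and the
    proportion among applicable patients; kind ``not_applicable`` rows carry
    counts per reason.  Counts conserve cohort size per score.
    """
    if not cohort.records:
        raise ValueError("cannot summarize an empty cohort")
    rows = []
    score_names = sorted(
        {s for per in cohort.results.values() for s in per}, key=lambda s: s.value
    )
    for score in score_names:
        results = [per[score] for per in cohort.results.values() if score in per]
        applicable = [r for r in results if r.applicable]
        n_app = len(applicable)
        code_counts: Dict[int, int] = {}
        for r in applicable:
            code_counts[r.code] = code_counts.get(r.code, 0) + 1
        for code in sorted(code_counts):
            rows.append(
                {
                    "score": score.value,
                    "kind": "code",
                    "key": str(code),
                    "count": code_counts[code],
                    "proportion": code_counts[code] / n_app,
                }
            )
        reason_counts: Dict[str, int] = {}
        for r in results:
            if not r.applicable:
                reason_counts[r.reason] = reason_counts.get(r.reason, 0) + 1
        for reason in sorted(reason_counts):
            rows.append(
                {
                    "score": score.value,
                    "kind": "not_applicable",
                    "key": reason,
                    "count": reason_counts[reason],
                    "proportion": float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["score", "kind", "key", "count", "proportion"])
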