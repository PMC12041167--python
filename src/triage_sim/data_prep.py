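"""Raw export -> analysis-ready patients.

Mirrors the data-preparation stage of the study: parse the export, take
the first SAPS II and TISS score of each patient, detect COVID-19 from
ICD-10 codes and diagnosis free text, keep the first ICU stay only,
compute whole-day lengths of stay, count secondary diagnoses, and drop
implausible records (wrong number of main diagnoses, missing values,
negative length of stay) with a per-record exclusion report.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

from .errors import ExportFormatError
from .records import EXPORT_COLUMNS, RawPatientRecord, row_to_record

#: ICD-10 codes and free-text lexicon identifying a COVID-19 diagnosis.
COVID_CODES = ("U07.1", "U07.2")
COVID_LEXICON = ("covid", "sars-cov-2", "coronavirus")

#: Exclusion rules in the order they are checked (first violated rule wins).
RULE_MAIN_DIAGNOSES = "main_diagnoses"
RULE_MISSING_VALUES = "missing_values"
RULE_NEGATIVE_LOS = "negative_los"


@dataclass(frozen=True)
class PreparedPatient:
    """One analysis-ready patient (all triage criteria precomputed)."""

    patient_id: str
    age: float
    saps: float  # first SAPS II score
    tiss: float  # first TISS score
    n_secondary: int
    covid: bool
    icu_los: int  # whole days, first ICU stay
    hosp_los: int  # whole days
    died: bool


@dataclass
class ExclusionReport:
    n_input: int
    n_kept: int
    exclusions: list = field(default_factory=list)  # [(patient_id, rule), ...]


def parse_export(path) -> list:
    """Read a raw-export CSV into records; malformed rows raise with the
    1-based data row number."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ExportFormatError("empty file: missing header row")
        missing = [c for c in EXPORT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ExportFormatError(f"missing columns: {missing}")
        return [row_to_record(row, i) for i, row in enumerate(reader, start=1)]


def first_scores(record: RawPatientRecord) -> Tuple[Optional[float], Optional[float]]:
    """First SAPS II and TISS value by date; ties keep file order; empty
    series yield None (an exclusion-triggering missing value)."""

    def first(series):
        if not series:
            return None
        best = min(range(len(series)), key=lambda i: (series[i][0], i))
        return series[best][1]

    return first(record.saps_series), first(record.tiss_series)


def detect_covid(record: RawPatientRecord) -> bool:
    """COVID-19 if any diagnosis carries a U07 code or lexicon text."""
    codes = [d.code for d in record.main_diagnoses] + list(record.secondary_diagnoses)
    if any(c in COVID_CODES for c in codes):
        return True
    texts = [d.text.lower() for d in record.main_diagnoses]
    return any(term in text for text in texts for term in COVID_LEXICON)


def select_first_icu_stay(record: RawPatientRecord):
    """Earliest-starting ICU interval; equal starts keep the longer stay."""
    if not record.icu_stays:
        return None
    return min(record.icu_stays, key=lambda se: (se[0], se[0] - se[1]))


def compute_los(start: dt.date, end: dt.date) -> int:
    """Calendar-day difference end - start (same-day stay = 0); negative
    for implausible input, which the filter catches."""
    return (end - start).days


def _violated_rule(record: RawPatientRecord) -> Optional[str]:
    if len(record.main_diagnoses) != 1:
        return RULE_MAIN_DIAGNOSES
    saps, tiss = first_scores(record)
    mandatory = (
        record.age,
        saps,
        tiss,
        select_first_icu_stay(record),
        record.hosp_start,
        record.hosp_end,
        record.died,
    )
    if any(v is None for v in mandatory):
        return RULE_MISSING_VALUES
    icu_start, icu_end = select_first_icu_stay(record)
    if compute_los(icu_start, icu_end) < 0 or compute_los(
        record.hosp_start, record.hosp_end
    ) < compute_los(icu_start, icu_end):
        # hospital LOS shorter than ICU LOS implies a negative stay segment
        return RULE_NEGATIVE_LOS
    return None


def filter_and_prepare(records: Iterable[RawPatientRecord]):
    """Apply the plausibility filter and derive all analysis fields.

    Returns ``(kept, report)``; each exclusion is listed once under the
    first rule it violates, in the order main-diagnosis count, missing
    values, negative LOS.
    """
    kept, excluded = [], []
    n_input = 0
    for record in records:
        n_input += 1
        rule = _violated_rule(record)
        if rule is not None:
            excluded.append((record.patient_id, rule))
            continue
        saps, tiss = first_scores(record)
        icu_start, icu_end = select_first_icu_stay(record)
        kept.append(
            PreparedPatient(
                patient_id=record.patient_id,
                age=float(record.age),
                saps=float(saps),
                tiss=float(tiss),
                n_secondary=len(record.secondary_diagnoses),
                covid=detect_covid(record),
                icu_los=compute_los(icu_start, icu_end),
                hosp_los=compute_los(record.hosp_start, record.hosp_end),
                died=bool(record.died),
            )
        )
    return kept, ExclusionReport(
        n_input=n_input, n_kept=len(kept), exclusions=excluded
    )


PREPARED_COLUMNS = (
    "patient_id",
    "age",
    "saps",
    "tiss",
    "n_secondary",
    "covid",
    "icu_los",
    "hosp_los",
    "died",
)


def prepared_to_frame(patients: Sequence[PreparedPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(p, c) for c in PREPARED_COLUMNS] for p in patients],
        columns=list(PREPARED_COLUMNS),
    )


def frame_to_prepared(frame: pd.DataFrame) -> list:
    return [
        PreparedPatient(
            patient_id=str(row.patient_id),
            age=float(row.age),
            saps=float(row.saps),
            tiss=float(row.tiss),
            n_secondary=int(row.n_secondary),
            covid=bool(row.covid),
            icu_los=int(row.icu_los),
            hosp_los=int(row.hosp_los),
            died=bool(row.died),
        )
        for row in frame.itertuples(index=False)
    ]
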