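"""Raw-export record model and its CSV dialect.

The raw export emulates a pseudonymized hospital-information-system dump:
one row per patient with demographics, the SAPS II and TISS score series,
diagnoses, ICU and hospital stay dates, and the in-hospital death flag.

Dialect (UTF-8, header row, comma separated, ISO-8601 dates):

    patient_id, age, saps_events, tiss_events, main_diagnoses,
    secondary_diagnoses, icu_start, icu_end, hosp_start, hosp_end, died

* ``*_events`` columns hold ``date:value`` pairs joined by ``;``
  (file order is significant: it breaks ties between equal dates);
* diagnosis lists are joined by ``|``; each entry is an ICD-10 code,
  optionally followed by free text after the first space;
* ``icu_start`` / ``icu_end`` hold ``;``-joined date lists, pairing the
  i-th start with the i-th end (multiple ICU stays per hospital stay);
* ``died`` is ``1`` or ``0``; any mandatory field may be empty, which is
  a missing value (handled by the plausibility filter, not the parser).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .errors import ExportFormatError

EXPORT_COLUMNS = (
    "patient_id",
    "age",
    "saps_events",
    "tiss_events",
    "main_diagnoses",
    "secondary_diagnoses",
    "icu_start",
    "icu_end",
    "hosp_start",
    "hosp_end",
    "died",
)


class Diagnosis(NamedTuple):
    code: str
    text: str = ""


@dataclass
class RawPatientRecord:
    """One row of the raw export (nothing filtered, nothing derived)."""

    patient_id: str
    age: Optional[float] = None
    saps_series: list = field(default_factory=list)  # [(date, value), ...]
    tiss_series: list = field(default_factory=list)
    main_diagnoses: list = field(default_factory=list)  # [Diagnosis, ...]
    secondary_diagnoses: list = field(default_factory=list)  # [code, ...]
    icu_stays: list = field(default_factory=list)  # [(start, end), ...]
    hosp_start: Optional[dt.date] = None
    hosp_end: Optional[dt.date] = None
    died: Optional[bool] = None


def _fmt_num(value: float) -> str:
    return format(float(value), "g")


def _fmt_series(series) -> str:
    return ";".join(f"{d.isoformat()}:{_fmt_num(v)}" for d, v in series)


def _fmt_diagnoses(diagnoses) -> str:
    parts = []
    for d in diagnoses:
        parts.append(f"{d.code} {d.text}".strip() if d.text else d.code)
    return "|".join(parts)


def record_to_row(record: RawPatientRecord) -> list:
    starts = ";".join(s.isoformat() for s, _ in record.icu_stays)
    ends = ";".join(e.isoformat() for _, e in record.icu_stays)
    return [
        record.patient_id,
        "" if record.age is None else _fmt_num(record.age),
        _fmt_series(record.saps_series),
        _fmt_series(record.tiss_series),
        _fmt_diagnoses(record.main_diagnoses),
        "|".join(record.secondary_diagnoses),
        starts,
        ends,
        "" if record.hosp_start is None else record.hosp_start.isoformat(),
        "" if record.hosp_end is None else record.hosp_end.isoformat(),
        "" if record.died is None else ("1" if record.died else "0"),
    ]


def _parse_date(text: str, row_no: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ExportFormatError(f"row {row_no}: bad date {text!r}") from exc


def _parse_series(cell: str, row_no: int) -> list:
    if not cell:
        return []
    out = []
    for item in cell.split(";"):
        try:
            stamp, value = item.rsplit(":", 1)
            out.append((_parse_date(stamp, row_no), float(value)))
        except (ValueError, ExportFormatError) as exc:
            raise ExportFormatError(f"row {row_no}: bad event {item!r}") from exc
    return out


def _parse_diagnoses(cell: str) -> list:
    out = []
    for item in cell.split("|"):
        if not item:
            continue
        code, _, text = item.partition(" ")
        out.append(Diagnosis(code=code, text=text))
    return out


def row_to_record(row: dict, row_no: int) -> RawPatientRecord:
    """Decode one CSV row (dict keyed by EXPORT_COLUMNS) into a record."""
    missing = [c for c in EXPORT_COLUMNS if row.get(c) is None]
    if missing:
        raise ExportFormatError(f"row {row_no}: missing columns {missing}")
    starts = [s for s in row["icu_start"].split(";") if s]
    ends = [e for e in row["icu_end"].split(";") if e]
    if len(starts) != len(ends):
        raise ExportFormatError(f"row {row_no}: unpaired ICU stay dates")
    stays = [
        (_parse_date(s, row_no), _parse_date(e, row_no)) for s, e in zip(starts, ends)
    ]
    died_cell = row["died"]
    if died_cell not in ("", "0", "1"):
        raise ExportFormatError(f"row {row_no}: bad death flag {died_cell!r}")
    try:
        age = float(row["age"]) if row["age"] else None
    except ValueError as exc:
        raise ExportFormatError(f"row {row_no}: bad age {row['age']!r}") from exc
    return RawPatientRecord(
        patient_id=row["patient_id"],
        age=age,
        saps_series=_parse_series(row["saps_events"], row_no),
        tiss_series=_parse_series(row["tiss_events"], row_no),
        main_diagnoses=_parse_diagnoses(row["main_diagnoses"]),
        secondary_diagnoses=[c for c in row["secondary_diagnoses"].split("|") if c],
        icu_stays=stays,
        hosp_start=_parse_date(row["hosp_start"], row_no) if row["hosp_start"] else None,
        hosp_end=_parse_date(row["hosp_end"], row_no) if row["hosp_end"] else None,
        died=None if died_cell == "" else died_cell == "1",
    )
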