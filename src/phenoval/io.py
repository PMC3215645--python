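"""Delimited-text readers/writers for the EHR extract schema.

An extract directory holds six UTF-8 comma-separated files, each with a
header row:

``patients.csv``
    patient_id, sex, age, ckd_flag, pregnant_flag, symptoms_flag
``episodes.csv``
    patient_id, icpc_code, label, date
``glucose.csv``
    patient_id, date, kind, value_mg_dl
``bp.csv``
    patient_id, visit_id, date, systolic, diastolic
``medications.csv``
    patient_id, date, drug_class
``history.csv``
    patient_id, condition, date

Dates are ISO-8601 (``YYYY-MM-DD``), booleans are ``true``/``false``.
``read_cohort(write_cohort(c)) == c`` field-for-field.  Glucose values may
optionally be supplied in mmol/l (converted at 1 mmol/l = 18 mg/dl).
"""

from __future__ import annotations

import datetime as _dt
import os
from pathlib import Path
from typing import Callable

import pandas as pd

from .records import (
    BPReading,
    Cohort,
    Episode,
    GlucoseMeasurement,
    HistoryNote,
    MedicationRecord,
    PatientBundle,
)

__all__ = ["read_cohort", "write_cohort", "SchemaError", "ParseError", "EXTRACT_FILES"]

MMOL_TO_MGDL = 18.0

EXTRACT_FILES = {
    "patients": ("patients.csv", ["patient_id", "sex", "age", "ckd_flag", "pregnant_flag", "symptoms_flag"]),
    "episodes": ("episodes.csv", ["patient_id", "icpc_code", "label", "date"]),
    "glucose": ("glucose.csv", ["patient_id", "date", "kind", "value_mg_dl"]),
    "bp": ("bp.csv", ["patient_id", "visit_id", "date", "systolic", "diastolic"]),
    "medications": ("medications.csv", ["patient_id", "date", "drug_class"]),
    "history": ("history.csv", ["patient_id", "condition", "date"]),
}


class SchemaError(ValueError):
    """The extract directory does not conform to the expected schema."""


class ParseError(ValueError):
    """A row could not be parsed; the message names the file and line."""


def _parse_bool(s: str) -> bool:
    s = str(s).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_date(s: str) -> _dt.date:
    return _dt.date.fromisoformat(str(s).strip())


def _read_table(directory: Path, key: str) -> pd.DataFrame:
    fname, columns = EXTRACT_FILES[key]
    path = directory / fname
    if not path.is_file():
        raise SchemaError(f"missing extract file {fname!r} in {directory}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise SchemaError(
            f"{fname}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


def _rows(df: pd.DataFrame, fname: str):
    # data rows start on line 2 (after the header)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        yield i, row


def read_cohort(directory_path: str | os.PathLike, glucose_unit: str = "mg/dl") -> Cohort:
    """Read an extract directory into a :class:`Cohort`.

    Parameters
    ----------
    directory_path:
        Directory containing the six extract files.
    glucose_unit:
        ``"mg/dl"`` (default) or ``"mmol/l"``; the latter converts values on
        input at 18 mg/dl per mmol/l.

    Raises
    ------
    SchemaError
        If a file is missing, has wrong columns, or a child row references an
        unknown patient_id.
    ParseError
        If a row cannot be converted, naming the file and line number.
    """
    if glucose_unit not in ("mg/dl", "mmol/l"):
        raise ValueError(f"glucose_unit must be 'mg/dl' or 'mmol/l', got {glucose_unit!r}")
    factor = 1.0 if glucose_unit == "mg/dl" else MMOL_TO_MGDL
    directory = Path(directory_path)

    tables = {key: _read_table(directory, key) for key in EXTRACT_FILES}

    patients: dict[str, PatientBundle] = {}
    order: list[str] = []
    fname = EXTRACT_FILES["patients"][0]
    for line, row in _rows(tables["patients"], fname):
        try:
            bundle = PatientBundle(
                patient_id=row.patient_id,
                sex=row.sex,
                age=int(row.age),
                ckd_flag=_parse_bool(row.ckd_flag),
                pregnant_flag=_parse_bool(row.pregnant_flag),
                hyperglycemia_symptoms_flag=_parse_bool(row.symptoms_flag),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{fname}, line {line}: {exc}") from exc
        if bundle.patient_id in patients:
            raise SchemaError(f"{fname}, line {line}: duplicate patient_id {bundle.patient_id!r}")
        patients[bundle.patient_id] = bundle
        order.append(bundle.patient_id)

    def _attach(key: str, build: Callable, target: Callable) -> None:
        fname = EXTRACT_FILES[key][0]
        for line, row in _rows(tables[key], fname):
            pid = row.patient_id
            if pid not in patients:
                raise SchemaError(
                    f"{fname}, line {line}: unknown patient_id {pid!r} (orphan record)"
                )
            try:
                record = build(row)
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{fname}, line {line}: {exc}") from exc
            target(patients[pid]).append(record)

    _attach(
        "episodes",
        lambda r: Episode(icpc_code=r.icpc_code, label=r.label, date=_parse_date(r.date)),
        lambda b: b.episodes,
    )
    _attach(
        "glucose",
        lambda r: GlucoseMeasurement(
            date=_parse_date(r.date), kind=r.kind, value=float(r.value_mg_dl) * factor
        ),
        lambda b: b.glucose,
    )
    _attach(
        "bp",
        lambda r: BPReading(
            visit_id=r.visit_id,
            date=_parse_date(r.date),
            systolic=float(r.systolic),
            diastolic=float(r.diastolic),
        ),
        lambda b: b.bp,
    )
    _attach(
        "medications",
        lambda r: MedicationRecord(date=_parse_date(r.date), drug_class=r.drug_class),
        lambda b: b.medications,
    )
    _attach(
        "history",
        lambda r: HistoryNote(condition=r.condition, date=_parse_date(r.date)),
        lambda b: b.history_notes,
    )

    return Cohort((patients[pid] for pid in order), provenance=str(directory))


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def _fmt_num(v: float) -> str:
    # integral floats written without a trailing .0 is NOT wanted: repr round-trips
    return repr(float(v)) if not float(v).is_integer() else str(int(v)) + ".0"


def write_cohort(cohort: Cohort, directory_path: str | os.PathLike) -> None:
    """Write ``cohort`` as the six-file extract schema (creates the directory).

    The inverse of :func:`read_cohort`: a written cohort reads back
    field-for-field identical, including record order.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)

    pat_rows, epi_rows, glu_rows, bp_rows, med_rows, his_rows = [], [], [], [], [], []
    for b in cohort:
        pat_rows.append(
            (b.patient_id, b.sex.value, b.age, _fmt_bool(b.ckd_flag),
             _fmt_bool(b.pregnant_flag), _fmt_bool(b.hyperglycemia_symptoms_flag))
        )
        for ep in b.episodes:
            epi_rows.append((b.patient_id, ep.icpc_code, ep.label, ep.date.isoformat()))
        for g in b.glucose:
            glu_rows.append((b.patient_id, g.date.isoformat(), g.kind.value, _fmt_num(g.value)))
        for r in b.bp:
            bp_rows.append((b.patient_id, r.visit_id, r.date.isoformat(),
                            _fmt_num(r.systolic), _fmt_num(r.diastolic)))
        for m in b.medications:
            med_rows.append((b.patient_id, m.date.isoformat(), m.drug_class.value))
        for h in b.history_notes:
            his_rows.append((b.patient_id, h.condition.value, h.date.isoformat()))

    for key, rows in [
        ("patients", pat_rows), ("episodes", epi_rows), ("glucose", glu_rows),
        ("bp", bp_rows), ("medications", med_rows), ("history", his_rows),
    ]:
        fname, columns = EXTRACT_FILES[key]
        pd.DataFrame(rows, columns=columns).to_csv(directory / fname, index=False)
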