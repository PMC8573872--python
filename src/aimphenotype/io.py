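"""Readers and writers for the cohort bundle format.

A cohort bundle is a directory of eight CSV tables — ``patients.csv`` plus one
table per event type — with ISO-8601 dates at day granularity.  The format is
deliberately plain so fixtures stay human-auditable.  A JSON-per-cohort
alternative (one document holding a list of patient objects) is provided for
programmatic exchange, with a JSON Schema derived from the pydantic model.

Loading is *total*: every input row either becomes exactly one typed event or
is reported as a rejection naming its table and row number, so row counts
always reconcile.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pydantic

from .errors import CohortValidationError, Rejection, SchemaError
from .events import (
    EVENT_FIELDS,
    EVENT_TYPES,
    PatientRecord,
)

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "birth_date"],
    "diagnoses": ["patient_id", "date", "concept", "provider_specialty", "source_section", "uncertain"],
    "labs": [
        "patient_id", "date", "kind", "specimen", "organism", "positive",
        "quantity", "quantity_units", "histology_findings",
    ],
    "procedures": ["patient_id", "date", "cpt_code", "description"],
    "medications": ["patient_id", "date", "drug_class", "name"],
    "imaging": ["patient_id", "date", "modality", "findings"],
    "vaccinations": ["patient_id", "date", "vaccine"],
    "exams": ["patient_id", "date", "temperature_f", "cough", "rale_crackle_crepitation"],
}

_LIST_COLUMNS = {"histology_findings", "findings"}  # semicolon-joined multi-valued cells
_BOOL_COLUMNS = {"uncertain", "positive", "cough", "rale_crackle_crepitation"}
_FLOAT_COLUMNS = {"quantity", "temperature_f"}


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return str(int(value)) if value == int(value) else repr(value)
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, tuple):
        return ";".join(v.value if hasattr(v, "value") else str(v) for v in value)
    if hasattr(value, "value"):  # Enum
        return str(value.value)
    return str(value)


def write_cohort(patients: Iterable[PatientRecord], path: str | Path) -> Path:
    """Write a cohort bundle; output is byte-deterministic for a given cohort.

    Rows are ordered by patient_id, then event date (ties keep the record's
    stable order).  Returns the bundle directory path.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ordered = sorted(patients, key=lambda p: p.patient_id)

    tables: dict[str, list[list[str]]] = {name: [] for name in TABLE_COLUMNS}
    for p in ordered:
        tables["patients"].append([p.patient_id, p.birth_date.isoformat()])
        for fld in EVENT_FIELDS:
            cols = TABLE_COLUMNS[fld][1:]  # skip patient_id
            for ev in getattr(p, fld):
                row = [p.patient_id] + [_format_cell(getattr(ev, c)) for c in cols]
                tables[fld].append(row)

    for name, rows in tables.items():
        with open(path / f"{name}.csv", "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(TABLE_COLUMNS[name])
            writer.writerows(rows)
    return path


@dataclass
class LoadReport:
    """Outcome of a total load: typed patients plus per-row rejections."""

    patients: list[PatientRecord] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)
    rows_read: dict[str, int] = field(default_factory=dict)

    @property
    def n_loaded_events(self) -> int:
        return sum(p.n_events for p in self.patients)


def _parse_cell(column: str, raw: str, temperature_unit: str):
    raw = raw.strip()
    if raw == "":
        return () if column in _LIST_COLUMNS else None
    if column in _BOOL_COLUMNS:
        low = raw.lower()
        if low in {"true", "1", "yes"}:
            return True
        if low in {"false", "0", "no"}:
            return False
        raise ValueError(f"invalid boolean {raw!r} in column {column!r}")
    if column in _FLOAT_COLUMNS:
        value = float(raw)
        if column == "temperature_f" and temperature_unit == "c":
            value = value * 9 / 5 + 32
        return value
    if column in _LIST_COLUMNS:
        return tuple(part for part in raw.split(";") if part)
    if column == "date" or column == "birth_date":
        return dt.date.fromisoformat(raw)
    return raw


def _read_table(path: Path, name: str) -> list[dict[str, str]]:
    file = path / f"{name}.csv"
    if not file.exists():
        raise SchemaError(f"bundle is missing table {name}.csv")
    with open(file, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in TABLE_COLUMNS[name] if c not in header]
        if missing:
            raise SchemaError(f"table {name}.csv is missing column(s): {', '.join(missing)}")
        return list(reader)


def read_cohort_report(
    path: str | Path, *, temperature_unit: Literal["f", "c"] = "f"
) -> LoadReport:
    """Load a cohort bundle, collecting a rejection for every invalid row.

    ``temperature_unit='c'`` converts exam temperatures from Celsius on load
    (F = C x 9/5 + 32); all in-memory temperatures are Fahrenheit.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"cohort bundle directory not found: {path}")
    report = LoadReport()

    patient_rows = _read_table(path, "patients")
    report.rows_read["patients"] = len(patient_rows)
    births: dict[str, dt.date] = {}
    for i, row in enumerate(patient_rows, start=1):
        pid = (row.get("patient_id") or "").strip()
        try:
            if not pid:
                raise ValueError("empty patient_id")
            if pid in births:
                raise ValueError(f"duplicate patient_id {pid!r}")
            births[pid] = dt.date.fromisoformat(row["birth_date"].strip())
        except (ValueError, KeyError) as exc:
            report.rejections.append(Rejection("patients", i, str(exc)))

    events: dict[str, dict[str, list]] = {pid: {f: [] for f in EVENT_FIELDS} for pid in births}
    for name in EVENT_FIELDS:
        rows = _read_table(path, name)
        report.rows_read[name] = len(rows)
        model = EVENT_TYPES[name]
        cols = TABLE_COLUMNS[name][1:]
        for i, row in enumerate(rows, start=1):
            pid = (row.get("patient_id") or "").strip()
            try:
                if pid not in births:
                    raise ValueError(f"unknown patient_id {pid!r}")
                kwargs = {c: _parse_cell(c, row.get(c, ""), temperature_unit) for c in cols}
                # drop absent optionals so model defaults apply
                kwargs = {k: v for k, v in kwargs.items() if v is not None}
                ev = model(**kwargs)
                if ev.date < births[pid]:
                    raise ValueError(
                        f"event date {ev.date.isoformat()} predates birth date "
                        f"{births[pid].isoformat()}"
                    )
                events[pid][name].append(ev)
            except (ValueError, pydantic.ValidationError) as exc:
                report.rejections.append(Rejection(name, i, _summarize_error(exc)))

    for pid in sorted(births):
        report.patients.append(
            PatientRecord(patient_id=pid, birth_date=births[pid], **events[pid])
        )
    return report


def _summarize_error(exc: Exception) -> str:
    if isinstance(exc, pydantic.ValidationError):
        parts = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<model>"
            parts.append(f"{loc}: {err['msg']}")
        return "; ".join(parts)
    return str(exc)


def read_cohort(
    path: str | Path, *, temperature_unit: Literal["f", "c"] = "f"
) -> list[PatientRecord]:
    """Load a cohort bundle; raise :class:`CohortValidationError` on any bad row."""
    report = read_cohort_report(path, temperature_unit=temperature_unit)
    if report.rejections:
        raise CohortValidationError(report.rejections)
    return report.patients


# ---------------------------------------------------------------------------
# JSON alternative
# ---------------------------------------------------------------------------

def write_cohort_json(patients: Iterable[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    ordered = sorted(patients, key=lambda p: p.patient_id)
    payload = [p.model_dump(mode="json") for p in ordered]
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_cohort_json(path: str | Path) -> list[PatientRecord]:
    data = json.loads(Path(path).read_text())
    return [PatientRecord.model_validate(obj) for obj in data]


def cohort_json_schema() -> dict:
    """JSON Schema for one patient object of the JSON cohort format."""
    return PatientRecord.model_json_schema()


def write_gold_labels(labels, path: str | Path) -> Path:
    """Write generator gold labels as CSV (patient_id, aim_id, label)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "aim_id", "label"])
        for lab in labels:
            writer.writerow([lab.patient_id, lab.aim_id, lab.label])
    return path


def read_gold_labels(path: str | Path):
    from .synthetic import GoldLabel  # local import to avoid a cycle

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            GoldLabel(
                patient_id=row["patient_id"],
                aim_id=int(row["aim_id"]),
                label=row["label"],
            )
            for row in reader
        ]
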