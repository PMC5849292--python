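"""Coded-EHR data model and tabular readers/writers.

The package consumes minimal coded extracts of a primary-care EHR: one table
of patients (demographics and clinic listing), one of dated ICD-10 diagnosis
records, one of ATC-coded prescription intervals, and one of clinics.
Everything downstream — risk scoring, alert evaluation, trial censuses —
operates on the types defined here.

Conventions
-----------
* All dates are calendar dates (ISO-8601 in files, :class:`datetime.date`
  in memory).
* Prescription intervals are closed on both ends: a prescription is *active*
  on date ``d`` when ``start_date <= d <= end_date``; an open (ongoing)
  prescription has ``end_date=None`` and is active for every ``d >= start``.
* ICD-10 codes are compared dot-insensitively and case-insensitively;
  ``I48.1`` and ``i481`` denote the same code.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "DiagnosisRecord",
    "PrescriptionRecord",
    "CodedPatientRecord",
    "Clinic",
    "Registry",
    "RegistryError",
    "normalize_icd10",
    "active_prescriptions",
    "read_registry",
    "write_registry",
    "registry_to_json",
    "registry_from_json",
]

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,4}$")
_ATC_RE = re.compile(r"^[A-V][0-9]{2}[A-Z]{2}[0-9]{2}$")


class RegistryError(ValueError):
    """Raised for schema, referential-integrity, or invariant violations."""


def normalize_icd10(code: str) -> str:
    """Return the canonical dot-free uppercase form of an ICD-10 code.

    >>> normalize_icd10("i48.1")
    'I481'
    """
    out = code.strip().upper().replace(".", "")
    if not out:
        raise RegistryError("empty ICD-10 code")
    if not _ICD10_RE.match(out):
        raise RegistryError(f"malformed ICD-10 code: {code!r}")
    return out


def _normalize_atc(code: str) -> str:
    out = code.strip().upper()
    if not out:
        raise RegistryError("empty ATC code")
    return out


@dataclass(frozen=True)
class DiagnosisRecord:
    """A dated ICD-10 coded diagnosis."""

    icd10_code: str
    onset_date: date

    def __post_init__(self) -> None:
        object.__setattr__(self, "icd10_code", normalize_icd10(self.icd10_code))


@dataclass(frozen=True)
class PrescriptionRecord:
    """An ATC-coded prescription interval; ``end_date=None`` means ongoing."""

    atc_code: str
    start_date: date
    end_date: date | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atc_code", _normalize_atc(self.atc_code))
        if self.end_date is not None and self.start_date > self.end_date:
            raise RegistryError(
                f"prescription {self.atc_code}: start {self.start_date} "
                f"after end {self.end_date}"
            )

    def active_on(self, on_date: date) -> bool:
        """Closed-interval containment: start <= on_date <= end (or open end)."""
        if on_date < self.start_date:
            return False
        return self.end_date is None or on_date <= self.end_date


class Sex:
    """Two-valued administrative sex as coded in the registry."""

    FEMALE = "female"
    MALE = "male"
    VALUES = (FEMALE, MALE)


@dataclass
class CodedPatientRecord:
    """One patient: demographics plus dated diagnosis and prescription codes."""

    patient_id: str
    birth_date: date
    sex: str
    clinic_id: str
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in Sex.VALUES:
            raise RegistryError(
                f"patient {self.patient_id}: sex must be one of {Sex.VALUES}, "
                f"got {self.sex!r}"
            )

    def validate_dates(self) -> None:
        """Birth must precede every recorded clinical date."""
        for d in self.diagnoses:
            if d.onset_date < self.birth_date:
                raise RegistryError(
                    f"patient {self.patient_id}: diagnosis {d.icd10_code} "
                    f"onset {d.onset_date} precedes birth {self.birth_date}"
                )
        for p in self.prescriptions:
            if p.start_date < self.birth_date:
                raise RegistryError(
                    f"patient {self.patient_id}: prescription {p.atc_code} "
                    f"start {p.start_date} precedes birth {self.birth_date}"
                )

    def has_code_prefix(self, prefixes: Iterable[str], as_of: date) -> bool:
        """True when some diagnosis with onset <= as_of matches a dot-free prefix."""
        pref = tuple(normalize_icd10(p) if len(p) >= 3 else p.upper() for p in prefixes)
        return any(
            d.onset_date <= as_of and d.icd10_code.startswith(pref)
            for d in self.diagnoses
        )


@dataclass(frozen=True)
class Clinic:
    """A primary-care clinic with its listed-population size."""

    clinic_id: str
    list_size: int
    open: bool = True

    def __post_init__(self) -> None:
        if self.list_size <= 0:
            raise RegistryError(
                f"clinic {self.clinic_id}: list_size must be positive"
            )


@dataclass
class Registry:
    """A county: clinics, patients, and the study census window."""

    clinics: dict[str, Clinic]
    patients: dict[str, CodedPatientRecord]
    census_start: date
    census_end: date

    def __post_init__(self) -> None:
        if self.census_start >= self.census_end:
            raise RegistryError("census_start must precede census_end")

    def validate(self) -> None:
        for pid, pat in self.patients.items():
            if pid != pat.patient_id:
                raise RegistryError(f"patient key {pid} != record id {pat.patient_id}")
            if pat.clinic_id not in self.clinics:
                raise RegistryError(
                    f"patient {pid} references unknown clinic {pat.clinic_id!r}"
                )
            pat.validate_dates()

    def patients_of_clinic(self, clinic_id: str) -> list[CodedPatientRecord]:
        return [p for p in self.patients.values() if p.clinic_id == clinic_id]


def active_prescriptions(
    patient: CodedPatientRecord,
    on_date: date,
    atc_set: Iterable[str],
) -> list[PrescriptionRecord]:
    """Prescriptions in ``atc_set`` whose closed interval contains ``on_date``.

    ATC matching is by prefix, so a class code such as ``B01AA`` selects every
    agent in the class. The result is always a subset of the patient's
    prescription list and grows monotonically with ``atc_set``.
    """
    prefixes = tuple(_normalize_atc(c) for c in atc_set)
    return [
        p
        for p in patient.prescriptions
        if p.atc_code.startswith(prefixes) and p.active_on(on_date)
    ]


# ---------------------------------------------------------------------------
# Tabular I/O — four CSV tables (UTF-8, header row, ISO dates)
# ---------------------------------------------------------------------------

PATIENTS_COLUMNS = ["patient_id", "birth_date", "sex", "clinic_id"]
DIAGNOSES_COLUMNS = ["patient_id", "icd10_code", "onset_date"]
PRESCRIPTIONS_COLUMNS = ["patient_id", "atc_code", "start_date", "end_date"]
CLINICS_COLUMNS = ["clinic_id", "list_size", "open"]
META_FILE = "registry.json"

_TABLE_FILES = {
    "patients": "patients.csv",
    "diagnoses": "diagnoses.csv",
    "prescriptions": "prescriptions.csv",
    "clinics": "clinics.csv",
}


def _parse_date(value: str, *, where: str) -> date:
    try:
        return date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RegistryError(f"unparsable date {value!r} in {where}") from exc


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise RegistryError(f"{path.name}: missing columns {missing}")
    return df


def read_registry(directory: str | Path, *, strict: bool = True) -> Registry:
    """Load a registry from its four CSV tables (plus ``registry.json`` metadata).

    In strict mode (default) any malformed row aborts the load; with
    ``strict=False`` row errors are collected and raised together at the end,
    so a data audit sees every problem at once. Rows are never silently
    dropped — a bad row either stops the load or appears in the error report.
    """
    directory = Path(directory)
    errors: list[str] = []

    def fail(msg: str) -> None:
        if strict:
            raise RegistryError(msg)
        errors.append(msg)

    meta_path = directory / META_FILE
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        census_start = _parse_date(meta["census_start"], where=META_FILE)
        census_end = _parse_date(meta["census_end"], where=META_FILE)
    else:
        census_start, census_end = date(2016, 1, 11), date(2017, 1, 11)

    clinics_df = _read_table(directory / _TABLE_FILES["clinics"], CLINICS_COLUMNS)
    clinics: dict[str, Clinic] = {}
    for i, row in clinics_df.iterrows():
        try:
            clinics[row["clinic_id"]] = Clinic(
                clinic_id=row["clinic_id"],
                list_size=int(row["list_size"]),
                open=str(row["open"]).strip().lower() in ("true", "1", "yes"),
            )
        except (RegistryError, ValueError) as exc:
            fail(f"clinics.csv row {i}: {exc}")

    patients_df = _read_table(directory / _TABLE_FILES["patients"], PATIENTS_COLUMNS)
    patients: dict[str, CodedPatientRecord] = {}
    for i, row in patients_df.iterrows():
        try:
            if row["clinic_id"] not in clinics:
                raise RegistryError(
                    f"patient {row['patient_id']} references unknown clinic "
                    f"{row['clinic_id']!r}"
                )
            if row["patient_id"] in patients:
                raise RegistryError(f"duplicate patient_id {row['patient_id']!r}")
            patients[row["patient_id"]] = CodedPatientRecord(
                patient_id=row["patient_id"],
                birth_date=_parse_date(row["birth_date"], where=f"patients.csv row {i}"),
                sex=row["sex"].strip().lower(),
                clinic_id=row["clinic_id"],
            )
        except RegistryError as exc:
            fail(f"patients.csv row {i}: {exc}")

    dx_df = _read_table(directory / _TABLE_FILES["diagnoses"], DIAGNOSES_COLUMNS)
    for i, row in dx_df.iterrows():
        try:
            pat = patients.get(row["patient_id"])
            if pat is None:
                raise RegistryError(f"unknown patient_id {row['patient_id']!r}")
            pat.diagnoses.append(
                DiagnosisRecord(
                    icd10_code=row["icd10_code"],
                    onset_date=_parse_date(row["onset_date"], where=f"diagnoses.csv row {i}"),
                )
            )
        except RegistryError as exc:
            fail(f"diagnoses.csv row {i}: {exc}")

    rx_df = _read_table(directory / _TABLE_FILES["prescriptions"], PRESCRIPTIONS_COLUMNS)
    for i, row in rx_df.iterrows():
        try:
            pat = patients.get(row["patient_id"])
            if pat is None:
                raise RegistryError(f"unknown patient_id {row['patient_id']!r}")
            end_raw = str(row["end_date"]).strip()
            pat.prescriptions.append(
                PrescriptionRecord(
                    atc_code=row["atc_code"],
                    start_date=_parse_date(row["start_date"], where=f"prescriptions.csv row {i}"),
                    end_date=None if not end_raw else _parse_date(
                        end_raw, where=f"prescriptions.csv row {i}"
                    ),
                )
            )
        except RegistryError as exc:
            fail(f"prescriptions.csv row {i}: {exc}")

    if errors:
        raise RegistryError(
            f"{len(errors)} malformed rows:\n" + "\n".join(errors)
        )

    reg = Registry(
        clinics=clinics,
        patients=patients,
        census_start=census_start,
        census_end=census_end,
    )
    reg.validate()
    return reg


def write_registry(registry: Registry, directory: str | Path) -> None:
    """Write the four CSV tables plus metadata; inverse of :func:`read_registry`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "birth_date": p.birth_date.isoformat(),
                "sex": p.sex,
                "clinic_id": p.clinic_id,
            }
            for p in registry.patients.values()
        ],
        columns=PATIENTS_COLUMNS,
    ).to_csv(directory / _TABLE_FILES["patients"], index=False)

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "icd10_code": d.icd10_code,
                "onset_date": d.onset_date.isoformat(),
            }
            for p in registry.patients.values()
            for d in p.diagnoses
        ],
        columns=DIAGNOSES_COLUMNS,
    ).to_csv(directory / _TABLE_FILES["diagnoses"], index=False)

    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "atc_code": rx.atc_code,
                "start_date": rx.start_date.isoformat(),
                "end_date": "" if rx.end_date is None else rx.end_date.isoformat(),
            }
            for p in registry.patients.values()
            for rx in p.prescriptions
        ],
        columns=PRESCRIPTIONS_COLUMNS,
    ).to_csv(directory / _TABLE_FILES["prescriptions"], index=False)

    pd.DataFrame(
        [
            {"clinic_id": c.clinic_id, "list_size": c.list_size, "open": c.open}
            for c in registry.clinics.values()
        ],
        columns=CLINICS_COLUMNS,
    ).to_csv(directory / _TABLE_FILES["clinics"], index=False)

    (directory / META_FILE).write_text(
        json.dumps(
            {
                "census_start": registry.census_start.isoformat(),
                "census_end": registry.census_end.isoformat(),
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# JSON bundle — convenient single-file round trip for fixtures
# ---------------------------------------------------------------------------

def registry_to_json(registry: Registry) -> str:
    """Serialize a registry to a single JSON document."""
    return json.dumps(
        {
            "census_start": registry.census_start.isoformat(),
            "census_end": registry.census_end.isoformat(),
            "clinics": [
                {"clinic_id": c.clinic_id, "list_size": c.list_size, "open": c.open}
                for c in registry.clinics.values()
            ],
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "birth_date": p.birth_date.isoformat(),
                    "sex": p.sex,
                    "clinic_id": p.clinic_id,
                    "diagnoses": [
                        [d.icd10_code, d.onset_date.isoformat()] for d in p.diagnoses
                    ],
                    "prescriptions": [
                        [
                            rx.atc_code,
                            rx.start_date.isoformat(),
                            None if rx.end_date is None else rx.end_date.isoformat(),
                        ]
                        for rx in p.prescriptions
                    ],
                }
                for p in registry.patients.values()
            ],
        }
    )


def registry_from_json(text: str) -> Registry:
    """Inverse of :func:`registry_to_json`."""
    raw = json.loads(text)
    reg = Registry(
        clinics={
            c["clinic_id"]: Clinic(c["clinic_id"], int(c["list_size"]), bool(c["open"]))
            for c in raw["clinics"]
        },
        patients={
            p["patient_id"]: CodedPatientRecord(
                patient_id=p["patient_id"],
                birth_date=date.fromisoformat(p["birth_date"]),
                sex=p["sex"],
                clinic_id=p["clinic_id"],
                diagnoses=[
                    DiagnosisRecord(code, date.fromisoformat(d))
                    for code, d in p["diagnoses"]
                ],
                prescriptions=[
                    PrescriptionRecord(
                        code,
                        date.fromisoformat(s),
                        None if e is None else date.fromisoformat(e),
                    )
                    for code, s, e in p["prescriptions"]
                ],
            )
            for p in raw["patients"]
        },
        census_start=date.fromisoformat(raw["census_start"]),
        census_end=date.fromisoformat(raw["census_end"]),
    )
    reg.validate()
    return reg
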