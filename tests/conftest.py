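"""Shared fixtures: hand-built micro-registries and a small simulated county."""

from __future__ import annotations

from datetime import date

import pytest

from afcds import (
    BehaviorConfig,
    Clinic,
    CodedPatientRecord,
    CountyConfig,
    DiagnosisRecord,
    PrescriptionRecord,
    Registry,
    adherence_census,
    generate_county,
    randomize,
    simulate_followup,
    stratify_clinics,
)

STUDY_START = date(2016, 1, 11)
STUDY_END = date(2017, 1, 11)


def make_patient(
    pid="p1",
    birth=date(1940, 5, 1),
    sex="male",
    clinic="c1",
    diagnoses=(),
    prescriptions=(),
) -> CodedPatientRecord:
    return CodedPatientRecord(
        patient_id=pid,
        birth_date=birth,
        sex=sex,
        clinic_id=clinic,
        diagnoses=[DiagnosisRecord(*d) for d in diagnoses],
        prescriptions=[PrescriptionRecord(*p) for p in prescriptions],
    )


@pytest.fixture
def tiny_registry() -> Registry:
    """Three patients at two clinics: treated AF, untreated AF, no AF."""
    patients = {
        "p1": make_patient(
            "p1",
            birth=date(1940, 5, 1),  # age 75 at study start
            sex="male",
            clinic="c1",
            diagnoses=[("I48", date(2010, 3, 1)), ("I10", date(2005, 1, 1))],
            prescriptions=[("B01AA03", date(2015, 6, 1), None)],
        ),
        "p2": make_patient(
            "p2",
            birth=date(1946, 2, 1),  # age 69
            sex="male",
            clinic="c1",
            diagnoses=[("I48.1", date(2014, 7, 1))],
            prescriptions=[("B01AF01", date(2015, 1, 1), date(2015, 12, 31))],
        ),
        "p3": make_patient(
            "p3",
            birth=date(1950, 9, 9),
            sex="female",
            clinic="c2",
            diagnoses=[("E11", date(2012, 1, 1))],
        ),
    }
    return Registry(
        clinics={
            "c1": Clinic("c1", 8000),
            "c2": Clinic("c2", 12000),
        },
        patients=patients,
        census_start=STUDY_START,
        census_end=STUDY_END,
    )


SMALL_COUNTY = dict(
    n_clinics=10,
    clinic_size_mean=4000.0,
    clinic_size_sd=1500.0,
    total_population=None,
)


@pytest.fixture(scope="session")
def small_trial():
    """A reduced county simulated over 12 months, shared across tests.

    Ten clinics of ~4,000 inhabitants (~1,250 AF patients county-wide) keep
    the full generate -> randomize -> simulate -> census chain fast while
    preserving every mechanism of the full county-scale configuration.
    """
    cfg = CountyConfig(seed=11, **SMALL_COUNTY)
    registry = generate_county(cfg)
    baseline = adherence_census(registry, registry.census_start)
    adh = {s.clinic_id: s.proportion for s in baseline if s.denominator > 0}
    sizes = {c.clinic_id: c.list_size for c in registry.clinics.values()}
    assignment = randomize(stratify_clinics(sizes, adh), seed=12)
    result = simulate_followup(
        registry, assignment, BehaviorConfig(), months=12, seed=13
    )
    return {
        "config": cfg,
        "assignment": assignment,
        "arm_of": {a.clinic_id: a.arm for a in assignment},
        "baseline": baseline,
        "result": result,
    }
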