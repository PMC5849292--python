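"""CHA2DS2-VASc risk scoring and the anticoagulation eligibility rule.

Maps coded ICD-10 diagnoses to the clinical risk factors of the CHA2DS2-VASc
algorithm, computes the additive score (range 0-9), and applies the guideline
rule used for measuring adherence: a patient with atrial fibrillation or
flutter qualifies for oral anticoagulant (OAC) therapy when the score is >= 1
*excluding* a point arising solely from female sex. The "non-sex" score
(range 0-8) is carried alongside the total for exactly this purpose.

Component weights (ESC guideline convention):

====================================  ======
congestive heart failure                 1
hypertension                             1
age >= 75 years                          2
diabetes mellitus                        1
prior stroke / TIA / thromboembolism     2
vascular disease                         1
age 65-74 years                          1
female sex                               1
====================================  ======

Code lists are configuration, not constants of the algorithm: the engine
ships sensible ICD-10/ATC defaults but accepts any :class:`CodeMap` loaded
from YAML/JSON, so a site's authoritative lists can be substituted verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .ehr_model import (
    CodedPatientRecord,
    DiagnosisRecord,
    Sex,
    active_prescriptions,
    normalize_icd10,
)

__all__ = [
    "RISK_FACTOR_NAMES",
    "COMPONENT_POINTS",
    "CodeMap",
    "RiskAssessment",
    "DEFAULT_CODE_MAP",
    "DEFAULT_RISK_TABLE",
    "ConfigurationError",
    "age_completed_years",
    "map_codes_to_risk_factors",
    "chads_vasc_score",
    "is_eligible_for_oac",
    "annual_stroke_risk",
    "load_code_map",
]


class ConfigurationError(ValueError):
    """Invalid code map, risk table, or factor name."""


#: Clinical (diagnosis-derived) risk factors; age and sex are handled separately.
RISK_FACTOR_NAMES = frozenset(
    {
        "congestive_heart_failure",
        "hypertension",
        "diabetes",
        "stroke_tia_thromboembolism",
        "vascular_disease",
    }
)

#: Points per score component.
COMPONENT_POINTS: Mapping[str, int] = {
    "chf": 1,
    "hypertension": 1,
    "age_ge75": 2,
    "diabetes": 1,
    "prior_stroke_tia_te": 2,
    "vascular": 1,
    "age_65_74": 1,
    "female_sex": 1,
}

_FACTOR_TO_COMPONENT = {
    "congestive_heart_failure": "chf",
    "hypertension": "hypertension",
    "diabetes": "diabetes",
    "stroke_tia_thromboembolism": "prior_stroke_tia_te",
    "vascular_disease": "vascular",
}


@dataclass(frozen=True)
class CodeMap:
    """ICD-10 prefix lists per risk factor plus the ATC/outcome code sets.

    Prefix matching is dot-insensitive: ``I48`` matches ``I48.0``/``I480``.
    """

    risk_factors: Mapping[str, frozenset[str]]
    oac_atc: frozenset[str]
    af_codes: frozenset[str]
    outcome_codes: frozenset[str]
    bleeding_codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.af_codes:
            raise ConfigurationError("af_codes must be non-empty")
        if set(self.risk_factors) != set(RISK_FACTOR_NAMES):
            raise ConfigurationError(
                f"risk factor names must be exactly {sorted(RISK_FACTOR_NAMES)}, "
                f"got {sorted(self.risk_factors)}"
            )
        norm = {
            name: frozenset(normalize_icd10(c) for c in codes)
            for name, codes in self.risk_factors.items()
        }
        object.__setattr__(self, "risk_factors", norm)
        object.__setattr__(
            self, "af_codes", frozenset(normalize_icd10(c) for c in self.af_codes)
        )
        object.__setattr__(
            self,
            "outcome_codes",
            frozenset(normalize_icd10(c) for c in self.outcome_codes),
        )
        object.__setattr__(
            self,
            "bleeding_codes",
            frozenset(normalize_icd10(c) for c in self.bleeding_codes),
        )
        object.__setattr__(
            self, "oac_atc", frozenset(c.strip().upper() for c in self.oac_atc)
        )


# Default map. Anticoagulants are the four agents used for the adherence
# definition: warfarin B01AA03, rivaroxaban B01AF01, apixaban B01AF02,
# dabigatran B01AE07. Prior stroke/TIA/thromboembolism reuses the
# thromboembolic outcome codes (I63, I64, G45, I74). Bleeding defaults to
# the major gastrointestinal/intracranial haemorrhage blocks.
DEFAULT_CODE_MAP = CodeMap(
    risk_factors={
        "congestive_heart_failure": frozenset({"I50"}),
        "hypertension": frozenset({"I10", "I11", "I12", "I13", "I15"}),
        "diabetes": frozenset({"E10", "E11", "E12", "E13", "E14"}),
        "stroke_tia_thromboembolism": frozenset({"I63", "I64", "G45", "I74"}),
        "vascular_disease": frozenset({"I21", "I252", "I70", "I73"}),
    },
    oac_atc=frozenset({"B01AA03", "B01AF01", "B01AF02", "B01AE07"}),
    af_codes=frozenset({"I48"}),
    outcome_codes=frozenset({"I63", "I64", "G45", "I74"}),
    bleeding_codes=frozenset({"I60", "I61", "I62", "K920", "K921", "K922", "D62"}),
)

# Display-only annual stroke risk (%) by total score, from Swedish cohort
# rates; required to be non-decreasing at load. Values are configuration.
DEFAULT_RISK_TABLE: Mapping[int, float] = {
    0: 0.3,
    1: 0.9,
    2: 2.9,
    3: 4.6,
    4: 6.7,
    5: 10.0,
    6: 13.6,
    7: 15.7,
    8: 15.9,
    9: 17.4,
}


@dataclass(frozen=True)
class RiskAssessment:
    """A computed CHA2DS2-VASc assessment for one patient at one date."""

    components: Mapping[str, int]
    total_score: int
    nonsex_score: int
    eligible: bool
    annual_stroke_risk_pct: float | None = None

    def __post_init__(self) -> None:
        if sum(self.components.values()) != self.total_score:
            raise ConfigurationError("component points do not sum to total_score")
        if not 0 <= self.total_score <= 9:
            raise ConfigurationError("total_score out of range 0-9")


def age_completed_years(birth_date: date, as_of: date) -> int:
    """Age in completed years at the assessment date."""
    years = as_of.year - birth_date.year
    if (as_of.month, as_of.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def map_codes_to_risk_factors(
    diagnoses: Sequence[DiagnosisRecord],
    as_of: date,
    code_map: CodeMap = DEFAULT_CODE_MAP,
) -> set[str]:
    """Risk factors evidenced by diagnoses with onset on or before ``as_of``.

    A factor is present iff some diagnosis dated <= ``as_of`` has a dot-free
    code beginning with one of the factor's configured prefixes.
    """
    present: set[str] = set()
    codes = [d.icd10_code for d in diagnoses if d.onset_date <= as_of]
    for factor, prefixes in code_map.risk_factors.items():
        pref = tuple(prefixes)
        if any(c.startswith(pref) for c in codes):
            present.add(factor)
    return present


def chads_vasc_score(
    factors: Iterable[str],
    age_years: int,
    sex: str,
    *,
    eligible: bool = False,
    annual_stroke_risk_pct: float | None = None,
) -> RiskAssessment:
    """Score a factor set plus age band and sex under the published weighting."""
    if age_years < 0:
        raise ConfigurationError("age_years must be non-negative")
    factors = set(factors)
    unknown = factors - RISK_FACTOR_NAMES
    if unknown:
        raise ConfigurationError(f"unknown risk factor names: {sorted(unknown)}")

    components = {name: 0 for name in COMPONENT_POINTS}
    for f in factors:
        comp = _FACTOR_TO_COMPONENT[f]
        components[comp] = COMPONENT_POINTS[comp]
    if age_years >= 75:
        components["age_ge75"] = COMPONENT_POINTS["age_ge75"]
    elif age_years >= 65:
        components["age_65_74"] = COMPONENT_POINTS["age_65_74"]
    if sex == Sex.FEMALE:
        components["female_sex"] = COMPONENT_POINTS["female_sex"]
    elif sex != Sex.MALE:
        raise ConfigurationError(f"sex must be one of {Sex.VALUES}, got {sex!r}")

    total = sum(components.values())
    return RiskAssessment(
        components=components,
        total_score=total,
        nonsex_score=total - components["female_sex"],
        eligible=eligible,
        annual_stroke_risk_pct=annual_stroke_risk_pct,
    )


def assess_patient(
    record: CodedPatientRecord,
    as_of: date,
    code_map: CodeMap = DEFAULT_CODE_MAP,
    risk_table: Mapping[int, float] | None = None,
) -> RiskAssessment:
    """Full assessment of a patient record: factors, score, eligibility rule."""
    factors = map_codes_to_risk_factors(record.diagnoses, as_of, code_map)
    age = age_completed_years(record.birth_date, as_of)
    base = chads_vasc_score(factors, age, record.sex)
    has_af = record.has_code_prefix(code_map.af_codes, as_of)
    eligible = has_af and base.nonsex_score >= 1
    risk = (
        annual_stroke_risk(base.total_score, risk_table)
        if risk_table is not None
        else None
    )
    return RiskAssessment(
        components=base.components,
        total_score=base.total_score,
        nonsex_score=base.nonsex_score,
        eligible=eligible,
        annual_stroke_risk_pct=risk,
    )


def is_eligible_for_oac(
    record: CodedPatientRecord,
    as_of: date,
    code_map: CodeMap = DEFAULT_CODE_MAP,
) -> bool:
    """Guideline rule: AF/flutter diagnosed on or before ``as_of`` and a
    CHA2DS2-VASc score >= 1 not counting the female-sex point."""
    return assess_patient(record, as_of, code_map).eligible


def has_active_oac(
    record: CodedPatientRecord,
    on_date: date,
    code_map: CodeMap = DEFAULT_CODE_MAP,
) -> bool:
    """True when the patient holds an active prescription for any configured OAC."""
    return bool(active_prescriptions(record, on_date, code_map.oac_atc))


def validate_risk_table(risk_table: Mapping[int, float]) -> Mapping[int, float]:
    missing = [s for s in range(10) if s not in risk_table]
    if missing:
        raise ConfigurationError(f"risk table missing scores {missing}")
    vals = [risk_table[s] for s in range(10)]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ConfigurationError("risk table must be non-decreasing in score")
    return risk_table


def annual_stroke_risk(
    total_score: int,
    risk_table: Mapping[int, float] | None = None,
) -> float:
    """Displayed annual stroke risk (%) for a total score, by table lookup."""
    table = validate_risk_table(
        DEFAULT_RISK_TABLE if risk_table is None else risk_table
    )
    if not 0 <= total_score <= 9:
        raise ConfigurationError(f"total score {total_score} outside 0-9")
    return table[total_score]


def load_code_map(path: str | Path) -> tuple[CodeMap, Mapping[int, float]]:
    """Load a (CodeMap, risk table) pair from a YAML/JSON config file.

    Schema::

        risk_factors: {hypertension: [I10, ...], ...}
        oac_atc: [B01AA03, ...]
        af_codes: [I48]
        outcome_codes: [I63, I64, G45, I74]
        bleeding_codes: [...]
        risk_table: {0: 0.3, 1: 0.9, ...}   # optional
    """
    raw = yaml.safe_load(Path(path).read_text())
    code_map = CodeMap(
        risk_factors={k: frozenset(v) for k, v in raw["risk_factors"].items()},
        oac_atc=frozenset(raw["oac_atc"]),
        af_codes=frozenset(raw["af_codes"]),
        outcome_codes=frozenset(raw.get("outcome_codes", ())),
        bleeding_codes=frozenset(raw.get("bleeding_codes", ())),
    )
    table_raw = raw.get("risk_table", DEFAULT_RISK_TABLE)
    risk_table = validate_risk_table({int(k): float(v) for k, v in table_raw.items()})
    return code_map, risk_table
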