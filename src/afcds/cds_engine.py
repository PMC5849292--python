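"""Alert lifecycle of the decision-support tool.

The tool is evaluated whenever a patient chart is opened ("login"). An alert
fires iff three conditions hold simultaneously: the patient carries an AF or
atrial-flutter diagnosis dated on or before the login, the guideline
eligibility rule is satisfied (non-sex CHA2DS2-VASc >= 1), and no configured
oral anticoagulant prescription is active on the login date. A patient
already on guideline-conforming therapy never triggers an alert.

The responding physician either prescribes an anticoagulant, postpones the
decision, or refrains; refraining requires one of three prespecified reasons
(patient preference, contraindication, other) and "other" requires free
text. Every decision produces a deterministic EHR note. Accounting
helpers summarise the event log: the monthly series of *first* alerts per
unique patient, and the partition of unique refusing patients by reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import pandas as pd

from .ehr_model import CodedPatientRecord, PrescriptionRecord, active_prescriptions
from .risk_engine import CodeMap, DEFAULT_CODE_MAP, RiskAssessment, assess_patient

__all__ = [
    "Decision",
    "RefrainReason",
    "AlertContext",
    "CdsEvent",
    "DecisionValidationError",
    "evaluate_at_login",
    "record_decision",
    "first_alert_series",
    "deviation_summary",
    "events_to_frame",
    "write_event_log",
    "read_event_log",
]


class DecisionValidationError(ValueError):
    """A captured decision violates the decision-form invariants."""


class Decision:
    PRESCRIBE = "prescribe"
    POSTPONE = "postpone"
    REFRAIN = "refrain"
    NONE = "none"
    VALUES = (PRESCRIBE, POSTPONE, REFRAIN, NONE)


class RefrainReason:
    PATIENT_PREFERENCE = "patient_preference"
    CONTRAINDICATION = "contraindication"
    OTHER = "other"
    VALUES = (PATIENT_PREFERENCE, CONTRAINDICATION, OTHER)


#: Anticoagulant choices as displayed, alphabetical by substance name.
DISPLAY_CHOICES = (
    ("apixaban", "B01AF02"),
    ("dabigatran", "B01AE07"),
    ("rivaroxaban", "B01AF01"),
    ("warfarin", "B01AA03"),
)


@dataclass(frozen=True)
class AlertContext:
    """What the pop-up shows: the patient, date, and risk assessment."""

    patient_id: str
    login_date: date
    assessment: RiskAssessment
    choices: tuple[tuple[str, str], ...] = DISPLAY_CHOICES


@dataclass(frozen=True)
class CdsEvent:
    """One login evaluation: whether an alert fired and the decision captured."""

    patient_id: str
    login_date: date
    alert_shown: bool
    first_time_for_patient: bool = False
    decision: str = Decision.NONE
    prescribed_atc: str | None = None
    refrain_reason: str | None = None
    other_reason_text: str | None = None
    generated_note: str = ""

    def __post_init__(self) -> None:
        if self.decision not in Decision.VALUES:
            raise DecisionValidationError(f"unknown decision {self.decision!r}")
        if self.decision != Decision.NONE and not self.alert_shown:
            raise DecisionValidationError("a decision requires an alert")
        if (self.decision == Decision.REFRAIN) != (self.refrain_reason is not None):
            raise DecisionValidationError(
                "refrain_reason must be present iff decision is refrain"
            )
        if self.refrain_reason is not None and self.refrain_reason not in RefrainReason.VALUES:
            raise DecisionValidationError(
                f"unknown refrain reason {self.refrain_reason!r}"
            )
        needs_text = self.refrain_reason == RefrainReason.OTHER
        has_text = bool(self.other_reason_text and self.other_reason_text.strip())
        if needs_text and not has_text:
            raise DecisionValidationError(
                "a free-text reason is mandatory when refraining for 'other'"
            )
        if not needs_text and self.other_reason_text:
            raise DecisionValidationError(
                "other_reason_text only accompanies refrain_reason='other'"
            )
        if (self.decision == Decision.PRESCRIBE) != (self.prescribed_atc is not None):
            raise DecisionValidationError(
                "prescribed_atc must be present iff decision is prescribe"
            )


def evaluate_at_login(
    record: CodedPatientRecord,
    login_date: date,
    code_map: CodeMap = DEFAULT_CODE_MAP,
    risk_table: Mapping[int, float] | None = None,
) -> AlertContext | None:
    """Evaluate the activation rule at a chart login.

    Returns an :class:`AlertContext` iff the patient (a) has an AF/flutter
    code on or before the login date, (b) satisfies the eligibility rule,
    and (c) has no active prescription from the configured OAC set on the
    login date; otherwise ``None``. The evaluation is a pure function of
    ``(record, login_date, code_map)``.
    """
    assessment = assess_patient(record, login_date, code_map, risk_table)
    if not assessment.eligible:
        return None
    if active_prescriptions(record, login_date, code_map.oac_atc):
        return None
    return AlertContext(
        patient_id=record.patient_id,
        login_date=login_date,
        assessment=assessment,
    )


def generate_note(
    context: AlertContext,
    decision: str,
    prescribed_atc: str | None,
    refrain_reason: str | None,
    other_reason_text: str | None,
) -> str:
    """Deterministic EHR note template; byte-identical for identical inputs."""
    a = context.assessment
    lines = [
        f"[CDS {context.login_date.isoformat()}] Stroke-prevention alert for "
        f"patient {context.patient_id}.",
        f"CHA2DS2-VASc {a.total_score} (non-sex {a.nonsex_score})"
        + (
            f"; estimated annual stroke risk {a.annual_stroke_risk_pct:.1f}%."
            if a.annual_stroke_risk_pct is not None
            else "."
        ),
        f"Decision: {decision}.",
    ]
    if decision == Decision.PRESCRIBE:
        lines.append(f"Prescribed anticoagulant ATC {prescribed_atc}.")
    elif decision == Decision.REFRAIN:
        lines.append(f"Reason for refraining: {refrain_reason}.")
        if other_reason_text:
            lines.append(f"Stated reason: {other_reason_text}")
    return "\n".join(lines)


def record_decision(
    context: AlertContext,
    record: CodedPatientRecord,
    decision: str,
    *,
    prescribed_atc: str | None = None,
    refrain_reason: str | None = None,
    other_reason_text: str | None = None,
    first_time_for_patient: bool = False,
) -> CdsEvent:
    """Capture a physician decision for a shown alert.

    A ``prescribe`` decision appends a new open-ended prescription to the
    patient record (in place), so the patient stops alerting from the next
    login onwards. Validation of the decision form happens in
    :class:`CdsEvent`; an invalid combination (refrain without a reason,
    "other" without text, prescribe without an agent) raises
    :class:`DecisionValidationError` and leaves the record untouched.
    """
    if context is None:
        raise DecisionValidationError("no alert context: nothing to decide")
    if decision == Decision.PRESCRIBE and prescribed_atc is None:
        raise DecisionValidationError("prescribe requires an ATC code")
    event = CdsEvent(
        patient_id=context.patient_id,
        login_date=context.login_date,
        alert_shown=True,
        first_time_for_patient=first_time_for_patient,
        decision=decision,
        prescribed_atc=prescribed_atc,
        refrain_reason=refrain_reason,
        other_reason_text=other_reason_text,
        generated_note=generate_note(
            context, decision, prescribed_atc, refrain_reason, other_reason_text
        ),
    )
    if decision == Decision.PRESCRIBE:
        record.prescriptions.append(
            PrescriptionRecord(
                atc_code=prescribed_atc,
                start_date=context.login_date,
                end_date=None,
            )
        )
    return event


def first_alert_series(
    events: Iterable[CdsEvent],
    period_start: date,
    period_end: date,
) -> pd.Series:
    """Monthly counts of alerts shown *for the first time* to unique patients.

    Each alerted patient contributes exactly once, in the month of their
    earliest alert within the window; the series therefore sums to the
    number of distinct alerted patients.
    """
    months = pd.period_range(period_start, period_end, freq="M")
    firsts: dict[str, date] = {}
    for ev in events:
        if not ev.alert_shown:
            continue
        if not period_start <= ev.login_date <= period_end:
            continue
        prev = firsts.get(ev.patient_id)
        if prev is None or ev.login_date < prev:
            firsts[ev.patient_id] = ev.login_date
    counts = pd.Series(0, index=months, dtype=int)
    for d in firsts.values():
        counts[pd.Period(d, freq="M")] += 1
    return counts


def deviation_summary(events: Iterable[CdsEvent]) -> dict[str, int]:
    """Unique refusing patients partitioned by their *latest* recorded reason.

    A patient with several refrain events is counted once, under the most
    recently recorded reason (ties broken by event order). Counts over the
    three reasons sum to the number of distinct refusing patients.
    """
    latest: dict[str, tuple[date, str]] = {}
    for ev in events:
        if ev.decision != Decision.REFRAIN:
            continue
        prev = latest.get(ev.patient_id)
        if prev is None or ev.login_date >= prev[0]:
            latest[ev.patient_id] = (ev.login_date, ev.refrain_reason)
    out = {reason: 0 for reason in RefrainReason.VALUES}
    for _, reason in latest.values():
        out[reason] += 1
    return out


# ---------------------------------------------------------------------------
# Event-log I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "patient_id",
    "login_date",
    "alert_shown",
    "first_time_for_patient",
    "decision",
    "prescribed_atc",
    "refrain_reason",
    "other_reason_text",
    "generated_note",
]


def events_to_frame(events: Sequence[CdsEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "login_date": e.login_date.isoformat(),
                "alert_shown": e.alert_shown,
                "first_time_for_patient": e.first_time_for_patient,
                "decision": e.decision,
                "prescribed_atc": e.prescribed_atc or "",
                "refrain_reason": e.refrain_reason or "",
                "other_reason_text": e.other_reason_text or "",
                "generated_note": e.generated_note,
            }
            for e in events
        ],
        columns=_EVENT_COLUMNS,
    )


def write_event_log(events: Sequence[CdsEvent], path: str | Path, *, fmt: str = "csv") -> None:
    """Write the event log as CSV (default) or JSON-lines."""
    path = Path(path)
    df = events_to_frame(events)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_event_log(path: str | Path) -> list[CdsEvent]:
    path = Path(path)
    if path.suffix == ".jsonl":
        rows = [json.loads(line) for line in path.read_text().splitlines() if line]
        df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            CdsEvent(
                patient_id=r["patient_id"],
                login_date=date.fromisoformat(r["login_date"]),
                alert_shown=str(r["alert_shown"]).lower() in ("true", "1"),
                first_time_for_patient=str(r["first_time_for_patient"]).lower()
                in ("true", "1"),
                decision=r["decision"],
                prescribed_atc=r["prescribed_atc"] or None,
                refrain_reason=r["refrain_reason"] or None,
                other_reason_text=r["other_reason_text"] or None,
                generated_note=r["generated_note"],
            )
        )
    return out
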