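"""Cluster-level adherence summaries and the trial's statistical analyses.

The primary endpoint is the clinic-level proportion of guideline-eligible
AF patients holding an active oral-anticoagulant prescription at a census
date. The primary analysis is a weighted least-squares regression of the
follow-up clinic proportion on the randomized arm indicator, adjusted for
the baseline clinic proportion and weighted by cluster size:

    p_fu,j = b0 + b1 * arm_j + b2 * p_base,j + e_j,   weight w_j = n_fu,j

with classical normal-theory (t-based) confidence intervals. Between-clinic
clustering is quantified with the one-way random-effects intraclass
correlation ICC(1,1) of Shrout & Fleiss, computed on the patient-level
binary outcomes (exactly recoverable from clinic numerator/denominator
pairs). Event rates (thromboembolism, bleeding) are compared between arms
with an uncorrected Pearson chi-squared test on the 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ehr_model import Registry, active_prescriptions
from .risk_engine import CodeMap, DEFAULT_CODE_MAP, assess_patient
from .trial_design import Arm, StratumAssignment

__all__ = [
    "ClinicSummary",
    "PrimaryResult",
    "EventComparison",
    "AnalysisError",
    "adherence_census",
    "pooled_and_mean_adherence",
    "primary_analysis",
    "primary_analysis_arrays",
    "icc_shrout_fleiss",
    "icc_from_counts",
    "event_comparison",
    "quartile_subgroup",
    "safety_extraction",
    "read_cluster_table_xlsx",
    "write_cluster_table_xlsx",
    "analyze_cluster_table",
]


class AnalysisError(ValueError):
    """Degenerate or invalid analysis inputs."""


@dataclass(frozen=True)
class ClinicSummary:
    """Per-clinic adherence numerator/denominator at one census date."""

    clinic_id: str
    census_date: date
    numerator: int
    denominator: int
    arm: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise AnalysisError(
                f"clinic {self.clinic_id}: numerator {self.numerator} outside "
                f"[0, {self.denominator}]"
            )

    @property
    def proportion(self) -> float:
        if self.denominator == 0:
            return math.nan
        return self.numerator / self.denominator


@dataclass(frozen=True)
class PrimaryResult:
    """Arm effect on follow-up adherence from the weighted adjusted regression."""

    effect_estimate: float
    ci95: tuple[float, float]
    p_value: float
    n_clusters_per_arm: tuple[int, int]
    weights_used: str
    intercept: float
    baseline_coefficient: float
    effect_se: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.effect_estimate <= hi:
            raise AnalysisError("ci95 must contain the effect estimate")


@dataclass(frozen=True)
class EventComparison:
    """2x2 comparison of event counts between arms."""

    events_a: int
    n_a: int
    events_b: int
    n_b: int
    rate_per_1000_a: float
    rate_per_1000_b: float
    rate_ci95_a: tuple[float, float]
    rate_ci95_b: tuple[float, float]
    chi2_statistic: float
    p_value: float


def adherence_census(
    registry: Registry,
    census_date: date,
    code_map: CodeMap = DEFAULT_CODE_MAP,
    arms: Mapping[str, str] | None = None,
) -> list[ClinicSummary]:
    """Per-clinic adherence at a census date.

    Denominator: patients listed at the clinic with an AF/flutter diagnosis
    on or before the census date and non-sex CHA2DS2-VASc >= 1 (a woman whose
    only point is female sex is excluded). Numerator: the subset with an
    active prescription from the configured OAC set on the census date.
    Patients diagnosed during the study enter denominators only from their
    onset date. Clinics with no eligible patients are returned with
    denominator 0 (downstream analyses exclude them).
    """
    num: dict[str, int] = {c: 0 for c in registry.clinics}
    den: dict[str, int] = {c: 0 for c in registry.clinics}
    for pat in registry.patients.values():
        assessment = assess_patient(pat, census_date, code_map)
        if not assessment.eligible:
            continue
        den[pat.clinic_id] += 1
        if active_prescriptions(pat, census_date, code_map.oac_atc):
            num[pat.clinic_id] += 1
    return [
        ClinicSummary(
            clinic_id=cid,
            census_date=census_date,
            numerator=num[cid],
            denominator=den[cid],
            arm=None if arms is None else arms.get(cid),
        )
        for cid in sorted(registry.clinics)
    ]


def pooled_and_mean_adherence(summaries: Sequence[ClinicSummary]) -> dict[str, float]:
    """Three arm-level adherence summaries, explicitly labelled.

    ``pooled`` is the patient-level quotient sum(num)/sum(den); ``unweighted_mean``
    averages clinic proportions equally; ``weighted_mean`` weights clinic
    proportions by denominator (algebraically equal to ``pooled``, reported
    separately for auditability). Zero-denominator clinics are excluded.
    """
    inc = [s for s in summaries if s.denominator > 0]
    if not inc:
        raise AnalysisError("no clinic with a positive denominator")
    nums = np.array([s.numerator for s in inc], dtype=float)
    dens = np.array([s.denominator for s in inc], dtype=float)
    props = nums / dens
    return {
        "pooled": float(nums.sum() / dens.sum()),
        "unweighted_mean": float(props.mean()),
        "weighted_mean": float((props * dens).sum() / dens.sum()),
        "n_clinics": len(inc),
    }


@dataclass(frozen=True)
class _WLSFit:
    params: np.ndarray
    se: np.ndarray
    ci95: np.ndarray
    p_values: np.ndarray
    p_value: float


def _wls_fit(y, X, w) -> _WLSFit:
    res = sm.WLS(y, X, weights=w).fit()
    ci = np.asarray(res.conf_int())
    return _WLSFit(
        params=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        ci95=ci,
        p_values=np.asarray(res.pvalues, dtype=float),
        p_value=float(res.pvalues[1]),
    )


def primary_analysis_arrays(
    base_num: np.ndarray,
    base_den: np.ndarray,
    fu_num: np.ndarray,
    fu_den: np.ndarray,
    arm_indicator: np.ndarray,
    *,
    weights: str = "followup",
) -> PrimaryResult:
    """Weighted baseline-adjusted regression on raw cluster count arrays.

    ``arm_indicator`` is 1 for intervention clinics. Weights are the
    follow-up eligible denominators by default (``weights='baseline'``
    selects baseline denominators instead).
    """
    base_num = np.asarray(base_num, dtype=float)
    base_den = np.asarray(base_den, dtype=float)
    fu_num = np.asarray(fu_num, dtype=float)
    fu_den = np.asarray(fu_den, dtype=float)
    arm_indicator = np.asarray(arm_indicator, dtype=float)

    keep = (base_den > 0) & (fu_den > 0)
    if keep.sum() < 3:
        raise AnalysisError("need at least 3 clinics with data at both censuses")
    y = fu_num[keep] / fu_den[keep]
    x_base = base_num[keep] / base_den[keep]
    arm = arm_indicator[keep]
    w = fu_den[keep] if weights == "followup" else base_den[keep]
    # a constant baseline column is collinear with the intercept (degenerate
    # but legal input); the adjustment term is then dropped
    adjust = bool(np.ptp(x_base) > 0)
    X = np.column_stack(
        [np.ones(len(y)), arm] + ([x_base] if adjust else [])
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AnalysisError("design matrix is rank-deficient")
    fit = _wls_fit(y, X, w)
    return PrimaryResult(
        effect_estimate=float(fit.params[1]),
        ci95=(float(fit.ci95[1, 0]), float(fit.ci95[1, 1])),
        p_value=fit.p_value,
        n_clusters_per_arm=(int(arm.sum()), int(len(arm) - arm.sum())),
        weights_used=weights,
        intercept=float(fit.params[0]),
        baseline_coefficient=float(fit.params[2]) if adjust else 0.0,
        effect_se=float(fit.se[1]),
    )


def primary_analysis(
    baseline: Sequence[ClinicSummary],
    followup: Sequence[ClinicSummary],
    assignment: Sequence[StratumAssignment] | Mapping[str, str],
    *,
    weights: str = "followup",
) -> PrimaryResult:
    """The trial's primary analysis on per-clinic census summaries.

    Clinics must appear in both censuses with positive denominators;
    others are excluded (e.g. a clinic closed during follow-up).
    """
    arm_of = (
        {a.clinic_id: a.arm for a in assignment}
        if not isinstance(assignment, Mapping)
        else dict(assignment)
    )
    base_by = {s.clinic_id: s for s in baseline}
    fu_by = {s.clinic_id: s for s in followup}
    common = sorted(set(base_by) & set(fu_by) & set(arm_of))
    rows = [
        (base_by[c], fu_by[c], 1.0 if arm_of[c] == Arm.CDS else 0.0)
        for c in common
    ]
    return primary_analysis_arrays(
        base_num=np.array([b.numerator for b, _, _ in rows]),
        base_den=np.array([b.denominator for b, _, _ in rows]),
        fu_num=np.array([f.numerator for _, f, _ in rows]),
        fu_den=np.array([f.denominator for _, f, _ in rows]),
        arm_indicator=np.array([a for _, _, a in rows]),
        weights=weights,
    )


def icc_shrout_fleiss(values: Sequence[float], groups: Sequence) -> float:
    """One-way random-effects ICC(1,1) from individual values and group labels.

    ICC(1,1) = (MSB - MSW) / (MSB + (n0 - 1) MSW), with n0 the standard
    unbalanced-design average group size (N - sum n_j^2 / N) / (k - 1).
    Negative estimates are returned as computed, not truncated.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)})
    sizes = df.groupby("g")["y"].count()
    k = len(sizes)
    N = int(sizes.sum())
    if k < 2 or N < 2:
        raise AnalysisError("ICC requires >= 2 groups and >= 2 observations")
    means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    denom = msb + (n0 - 1) * msw
    if denom == 0:
        return 0.0
    return (msb - msw) / denom


def icc_from_counts(numerators: Sequence[int], denominators: Sequence[int]) -> float:
    """ICC(1,1) on patient-level binary outcomes reconstructed from clinic
    numerator/denominator pairs (exact for binary data, without expanding
    individual rows)."""
    x = np.asarray(numerators, dtype=float)
    n = np.asarray(denominators, dtype=float)
    keep = n > 0
    x, n = x[keep], n[keep]
    k = len(n)
    N = float(n.sum())
    if k < 2 or N < 2:
        raise AnalysisError("ICC requires >= 2 groups and >= 2 observations")
    p = x / n
    grand = x.sum() / N
    ssb = float((n * (p - grand) ** 2).sum())
    # within-cluster sum of squares of 0/1 values around the cluster mean
    ssw = float((n * p * (1 - p)).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - float((n**2).sum()) / N) / (k - 1)
    denom = msb + (n0 - 1) * msw
    if denom == 0:
        return 0.0
    return (msb - msw) / denom


def _rate_ci(events: int, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for a rate per 1,000."""
    if n == 0:
        return (math.nan, math.nan)
    p = events / n
    half = 1.96 * math.sqrt(p * (1 - p) / n)
    return (1000 * max(p - half, 0.0), 1000 * min(p + half, 1.0))


def event_comparison(
    events_a: int, n_a: int, events_b: int, n_b: int
) -> EventComparison:
    """Pearson chi-squared (no continuity correction) on a 2x2 event table."""
    for ev, n in ((events_a, n_a), (events_b, n_b)):
        if not 0 <= ev <= n:
            raise AnalysisError(f"event count {ev} outside [0, {n}]")
    if events_a + events_b == 0 or events_a + events_b == n_a + n_b:
        chi2, p = 0.0, 1.0
    else:
        table = np.array(
            [[events_a, n_a - events_a], [events_b, n_b - events_b]]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EventComparison(
        events_a=events_a,
        n_a=n_a,
        events_b=events_b,
        n_b=n_b,
        rate_per_1000_a=1000 * events_a / n_a if n_a else math.nan,
        rate_per_1000_b=1000 * events_b / n_b if n_b else math.nan,
        rate_ci95_a=_rate_ci(events_a, n_a),
        rate_ci95_b=_rate_ci(events_b, n_b),
        chi2_statistic=float(chi2),
        p_value=float(p),
    )


def quartile_subgroup(
    baseline: Sequence[ClinicSummary],
    followup: Sequence[ClinicSummary],
    assignment: Sequence[StratumAssignment] | Mapping[str, str],
    *,
    weights: str = "followup",
) -> dict:
    """Primary analysis restricted to the first and fourth quartiles of
    baseline adherence.

    Quartile boundaries are the 25th/75th percentiles of clinic baseline
    proportions; a subgroup with fewer than two clinics in either arm is
    flagged inestimable rather than fitted.
    """
    arm_of = (
        {a.clinic_id: a.arm for a in assignment}
        if not isinstance(assignment, Mapping)
        else dict(assignment)
    )
    inc = [s for s in baseline if s.denominator > 0 and s.clinic_id in arm_of]
    if len(inc) < 8:
        raise AnalysisError("quartile subgroup analysis needs >= 8 clinics")
    props = np.array([s.proportion for s in inc])
    q1, q3 = np.percentile(props, [25, 75])
    if q1 == q3:
        return {
            "q1_threshold": float(q1),
            "q4_threshold": float(q3),
            "first_quartile": {"estimable": False, "reason": "degenerate quartiles"},
            "fourth_quartile": {"estimable": False, "reason": "degenerate quartiles"},
        }

    out: dict = {"q1_threshold": float(q1), "q4_threshold": float(q3)}
    for label, member in (
        ("first_quartile", [s for s in inc if s.proportion <= q1]),
        ("fourth_quartile", [s for s in inc if s.proportion >= q3]),
    ):
        ids = {s.clinic_id for s in member}
        arms = [arm_of[c] for c in ids]
        n_cds = sum(a == Arm.CDS for a in arms)
        n_ctl = len(arms) - n_cds
        entry: dict = {
            "clinics": sorted(ids),
            "range": (
                float(min(s.proportion for s in member)),
                float(max(s.proportion for s in member)),
            ),
        }
        if n_cds < 2 or n_ctl < 2:
            entry.update(estimable=False, reason="fewer than 2 clinics per arm")
        else:
            res = primary_analysis(
                [s for s in baseline if s.clinic_id in ids],
                [s for s in followup if s.clinic_id in ids],
                arm_of,
                weights=weights,
            )
            entry.update(
                estimable=True,
                effect_estimate=res.effect_estimate,
                ci95=res.ci95,
                p_value=res.p_value,
            )
        out[label] = entry
    return out


def safety_extraction(
    outcomes: pd.DataFrame,
    registry: Registry,
    assignment: Sequence[StratumAssignment] | Mapping[str, str],
    at_months: int,
    *,
    study_start: date | None = None,
    code_map: CodeMap = DEFAULT_CODE_MAP,
    event_type: str = "bleeding",
) -> dict:
    """Interim safety-board extraction of bleeding among newly initiated patients.

    The denominator in each arm is the number of patients initiated on an
    OAC after study commencement (first qualifying prescription start after
    the study start date); the numerator is the subset with a bleeding event
    on or before the extraction date. The chi-squared arm comparison on that
    proportion is returned alongside the per-1,000-AF-patients variant of
    the rate, which uses all AF patients at the extraction date as
    denominator.
    """
    if at_months < 0:
        raise AnalysisError("extraction months must be non-negative")
    start = study_start or registry.census_start
    extraction_date = start + timedelta(days=round(at_months * 365.25 / 12))
    if extraction_date < start:
        raise AnalysisError("extraction date precedes study start")
    arm_of = (
        {a.clinic_id: a.arm for a in assignment}
        if not isinstance(assignment, Mapping)
        else dict(assignment)
    )

    initiated: dict[str, set[str]] = {Arm.CDS: set(), Arm.CONTROL: set()}
    af_patients: dict[str, set[str]] = {Arm.CDS: set(), Arm.CONTROL: set()}
    oac = tuple(code_map.oac_atc)
    for pat in registry.patients.values():
        arm = arm_of.get(pat.clinic_id)
        if arm is None:
            continue
        if pat.has_code_prefix(code_map.af_codes, extraction_date):
            af_patients[arm].add(pat.patient_id)
        starts = [
            rx.start_date
            for rx in pat.prescriptions
            if rx.atc_code.startswith(oac)
        ]
        if starts and start < min(starts) <= extraction_date:
            initiated[arm].add(pat.patient_id)

    ev = outcomes[
        (outcomes["type"] == event_type)
        & (pd.to_datetime(outcomes["date"]).dt.date <= extraction_date)
    ]
    bleeders = set(ev["patient_id"])
    num = {arm: len(initiated[arm] & bleeders) for arm in initiated}
    den = {arm: len(initiated[arm]) for arm in initiated}

    result: dict = {
        "extraction_date": extraction_date.isoformat(),
        "months": at_months,
        "initiated": den,
        "events_among_initiated": num,
    }
    if den[Arm.CDS] == 0 and den[Arm.CONTROL] == 0:
        result["comparison"] = None
        result["warning"] = "no initiations; comparison skipped"
    else:
        result["comparison"] = event_comparison(
            num[Arm.CDS], max(den[Arm.CDS], 1),
            num[Arm.CONTROL], max(den[Arm.CONTROL], 1),
        )
    # per-1,000-AF-patients variant of the same numerators
    result["per_1000_af_patients"] = event_comparison(
        len(af_patients[Arm.CDS] & bleeders), max(len(af_patients[Arm.CDS]), 1),
        len(af_patients[Arm.CONTROL] & bleeders), max(len(af_patients[Arm.CONTROL]), 1),
    )
    return result


# ---------------------------------------------------------------------------
# Cluster-level table import/export (XLSX) and turnkey analysis
# ---------------------------------------------------------------------------

CLUSTER_TABLE_COLUMNS = [
    "clinic_id",
    "arm",
    "baseline_numerator",
    "baseline_denominator",
    "followup_numerator",
    "followup_denominator",
]


def read_cluster_table_xlsx(path: str | Path) -> pd.DataFrame:
    """Read a cluster-level results workbook (one row per clinic)."""
    df = pd.read_excel(path)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    missing = [c for c in CLUSTER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AnalysisError(f"cluster table missing columns {missing}")
    return df[CLUSTER_TABLE_COLUMNS]


def write_cluster_table_xlsx(df: pd.DataFrame, path: str | Path) -> None:
    df[CLUSTER_TABLE_COLUMNS].to_excel(path, index=False)


def analyze_cluster_table(df: pd.DataFrame, *, weights: str = "followup") -> dict:
    """Primary analysis + ICC directly from a cluster-level table."""
    res = primary_analysis_arrays(
        base_num=df["baseline_numerator"].to_numpy(),
        base_den=df["baseline_denominator"].to_numpy(),
        fu_num=df["followup_numerator"].to_numpy(),
        fu_den=df["followup_denominator"].to_numpy(),
        arm_indicator=(df["arm"].astype(str).str.lower() == Arm.CDS).to_numpy(float),
        weights=weights,
    )
    icc = icc_from_counts(
        df["followup_numerator"].to_numpy(), df["followup_denominator"].to_numpy()
    )
    return {"primary": res, "icc_followup": icc}
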