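"""County generation, marginal calibration, and the follow-up simulator."""

from datetime import date

import numpy as np
import pytest

from afcds import (
    BehaviorConfig,
    Clinic,
    CountyConfig,
    CountyConfigError,
    Registry,
    adherence_census,
    generate_county,
    marginal_report,
    registry_to_json,
    simulate_followup,
)
from afcds.cds_engine import Decision
from afcds.ehr_model import active_prescriptions
from afcds.risk_engine import DEFAULT_CODE_MAP
from .conftest import SMALL_COUNTY, STUDY_END, STUDY_START, make_patient


class TestConfigValidation:
    def test_prevalence_bounds(self):
        with pytest.raises(CountyConfigError):
            CountyConfig(seed=1, af_prevalence=1.5)

    def test_age_bands_must_sum_to_one(self):
        with pytest.raises(CountyConfigError):
            CountyConfig(seed=1, age_band_probs=(0.5, 0.5, 0.5))

    def test_behavior_probability_bounds(self):
        with pytest.raises(CountyConfigError):
            BehaviorConfig(p_background_initiation=-0.1)
        with pytest.raises(CountyConfigError):
            BehaviorConfig(refrain_reason_probs=(0.5, 0.5, 0.5))


class TestGeneration:
    def test_deterministic_given_seed(self):
        cfg = CountyConfig(seed=5, n_clinics=4, clinic_size_mean=3000, clinic_size_sd=800, total_population=None)
        assert registry_to_json(generate_county(cfg)) == registry_to_json(generate_county(cfg))

    def test_different_seeds_differ(self):
        a = CountyConfig(seed=5, n_clinics=4, clinic_size_mean=3000, clinic_size_sd=800, total_population=None)
        b = CountyConfig(seed=6, n_clinics=4, clinic_size_mean=3000, clinic_size_sd=800, total_population=None)
        assert registry_to_json(generate_county(a)) != registry_to_json(generate_county(b))

    def test_zero_prevalence_gives_empty_cohort(self):
        cfg = CountyConfig(seed=2, n_clinics=5, af_prevalence=0.0)
        reg = generate_county(cfg)
        assert len(reg.clinics) == 5 and len(reg.patients) == 0

    def test_registry_is_internally_valid(self):
        cfg = CountyConfig(seed=3, **SMALL_COUNTY)
        reg = generate_county(cfg)
        reg.validate()
        assert all(c.list_size >= 1000 for c in reg.clinics.values())

    def test_treated_patients_are_eligible(self):
        """An OAC at baseline is only ever assigned to guideline-eligible patients."""
        from afcds.risk_engine import assess_patient

        cfg = CountyConfig(seed=4, n_clinics=4, clinic_size_mean=2500, clinic_size_sd=500, total_population=None)
        reg = generate_county(cfg)
        for p in reg.patients.values():
            if active_prescriptions(p, STUDY_START, DEFAULT_CODE_MAP.oac_atc):
                assert assess_patient(p, STUDY_START).eligible


class TestMarginalReport:
    def test_empty_registry_empty_report(self):
        reg = Registry(
            clinics={"c1": Clinic("c1", 1000)}, patients={},
            census_start=STUDY_START, census_end=STUDY_END,
        )
        assert marginal_report(reg).empty

    def test_exact_fractions_on_handbuilt_registry(self):
        patients = {
            "a": make_patient("a", birth=date(1938, 1, 1), sex="female", clinic="c1",
                              diagnoses=[("I48", date(2014, 1, 1)), ("I10", date(2010, 1, 1))]),
            "b": make_patient("b", birth=date(1948, 1, 1), sex="male", clinic="c1",
                              diagnoses=[("I48", date(2014, 1, 1))]),
            "c": make_patient("c", birth=date(1960, 1, 1), sex="male", clinic="c1",
                              diagnoses=[("I48", date(2014, 1, 1)), ("E11", date(2012, 1, 1))],
                              prescriptions=[("B01AA03", date(2015, 1, 1), None)]),
            "d": make_patient("d", birth=date(1980, 1, 1), sex="male", clinic="c1",
                              diagnoses=[("I48", date(2014, 1, 1))]),
        }
        reg = Registry(
            clinics={"c1": Clinic("c1", 1000)}, patients=patients,
            census_start=STUDY_START, census_end=STUDY_END,
        )
        rep = marginal_report(reg)
        assert rep.loc["hypertension", "realized"] == pytest.approx(0.25)
        assert rep.loc["diabetes", "realized"] == pytest.approx(0.25)
        assert rep.loc["female", "realized"] == pytest.approx(0.25)
        assert rep.loc["age_ge75", "realized"] == pytest.approx(0.25)
        # three of four are eligible (d has score 0); one of those treated
        assert rep.loc["adherence", "realized"] == pytest.approx(1 / 3)

    def test_small_county_marginals_near_targets(self, small_trial):
        cfg = small_trial["config"]
        reg = generate_county(cfg)  # fresh copy; the shared one was simulated
        rep = marginal_report(reg, cfg)
        # ~1,200 AF patients: binomial error well under 5 pp on every marginal
        assert (rep["abs_deviation"].drop("adherence") < 0.05).all()


class TestFollowupSimulation:
    def test_requires_full_assignment(self, small_trial):
        cfg = CountyConfig(seed=21, n_clinics=4, clinic_size_mean=2500, clinic_size_sd=500, total_population=None)
        reg = generate_county(cfg)
        with pytest.raises(CountyConfigError, match="without an arm"):
            simulate_followup(reg, {"C00": "cds"}, BehaviorConfig(), seed=1)

    def test_deterministic_event_log(self):
        cfg = CountyConfig(seed=22, n_clinics=4, clinic_size_mean=2000, clinic_size_sd=400, total_population=None)
        arm = {f"C{i:02d}": ("cds" if i % 2 else "control") for i in range(4)}
        logs = []
        for _ in range(2):
            reg = generate_county(cfg)
            res = simulate_followup(reg, arm, BehaviorConfig(), seed=9)
            logs.append((res.encounters.to_csv(), res.cds_events, res.outcomes.to_csv()))
        assert logs[0] == logs[1]

    def test_no_initiation_pathways_only_discontinuation(self):
        """With every initiation probability zero, adherence can only fall."""
        cfg = CountyConfig(seed=23, n_clinics=4, clinic_size_mean=2500, clinic_size_sd=500, total_population=None)
        reg = generate_county(cfg)
        arm = {f"C{i:02d}": ("cds" if i % 2 else "control") for i in range(4)}
        beh = BehaviorConfig(
            p_background_initiation=0.0,
            p_prescribe_given_alert=0.0,
            p_initiate_at_diagnosis=0.0,
            new_af_incidence_per_1000py=0.0,
            close_one_control_clinic=False,
        )
        res = simulate_followup(reg, arm, beh, seed=2)
        started = [
            rx
            for p in res.registry.patients.values()
            for rx in p.prescriptions
            if rx.start_date > STUDY_START
        ]
        assert started == []
        stopped = [
            rx
            for p in res.registry.patients.values()
            for rx in p.prescriptions
            if rx.end_date is not None and rx.end_date > STUDY_START
        ]
        assert len(stopped) > 0  # discontinuations still occur

    def test_zero_hazards_no_clinical_events(self):
        cfg = CountyConfig(seed=24, n_clinics=3, clinic_size_mean=2000, clinic_size_sd=300, total_population=None)
        reg = generate_county(cfg)
        arm = {f"C{i:02d}": "control" for i in range(3)}
        beh = BehaviorConfig(
            te_hazard_treated=0.0, te_hazard_untreated=0.0,
            bleeding_hazard_treated=0.0, close_one_control_clinic=False,
        )
        res = simulate_followup(reg, arm, beh, seed=3)
        assert res.outcomes.empty

    def test_closure_preserves_patients_and_empties_clinic(self, small_trial):
        res = small_trial["result"]
        closed = res.closed_clinic
        assert closed is not None
        assert small_trial["arm_of"][closed] == "control"
        assert not res.registry.clinics[closed].open
        assert all(p.clinic_id != closed for p in res.registry.patients.values())
        # reassigned patients live at real clinics; total count conserved
        res.registry.validate()

    def test_new_entrants_absent_from_baseline_census(self, small_trial):
        res = small_trial["result"]
        reg = res.registry
        for pid in res.new_patient_ids:
            onset = reg.patients[pid].diagnoses[0].onset_date
            assert onset > reg.census_start

    def test_conservation_eligible_split(self, small_trial):
        """Per clinic, adherent + non-adherent = eligible at the final census."""
        reg = small_trial["result"].registry
        for s in adherence_census(reg, reg.census_end):
            assert 0 <= s.numerator <= s.denominator

    def test_prescribe_events_add_prescriptions(self, small_trial):
        res = small_trial["result"]
        reg = res.registry
        for ev in res.cds_events:
            if ev.decision == Decision.PRESCRIBE:
                starts = [
                    rx for rx in reg.patients[ev.patient_id].prescriptions
                    if rx.start_date == ev.login_date and rx.atc_code == ev.prescribed_atc
                ]
                assert starts
        assert any(ev.decision == Decision.PRESCRIBE for ev in res.cds_events)

    def test_alerts_only_in_intervention_arm(self, small_trial):
        """Every CDS event belongs to a patient listed (possibly after the
        closure reassignment) at an intervention-arm clinic."""
        res = small_trial["result"]
        arm_of = small_trial["arm_of"]
        reg = res.registry
        assert res.cds_events
        for ev in res.cds_events:
            assert arm_of[reg.patients[ev.patient_id].clinic_id] == "cds"
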