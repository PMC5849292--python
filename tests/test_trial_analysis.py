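"""Censuses, the weighted adjusted regression, ICC, and event comparisons."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afcds import (
    AnalysisError,
    Clinic,
    ClinicSummary,
    Registry,
    adherence_census,
    analyze_cluster_table,
    event_comparison,
    icc_from_counts,
    icc_shrout_fleiss,
    pooled_and_mean_adherence,
    primary_analysis,
    quartile_subgroup,
    read_cluster_table_xlsx,
    safety_extraction,
    write_cluster_table_xlsx,
)
from afcds.trial_analysis import primary_analysis_arrays
from .conftest import STUDY_END, STUDY_START, make_patient

CENSUS = STUDY_START


def summaries(pairs, census=CENSUS, arms=None):
    return [
        ClinicSummary(
            clinic_id=f"c{i}", census_date=census, numerator=n, denominator=d,
            arm=None if arms is None else arms[i],
        )
        for i, (n, d) in enumerate(pairs)
    ]


class TestAdherenceCensus:
    def _registry(self):
        patients = {}
        # clinic c1: three eligible, two treated
        for i, treated in enumerate([True, True, False]):
            rx = [("B01AF02", date(2015, 1, 1), None)] if treated else []
            patients[f"e{i}"] = make_patient(
                f"e{i}", birth=date(1938, 1, 1), sex="male", clinic="c1",
                diagnoses=[("I48", date(2012, 1, 1))], prescriptions=rx,
            )
        # female whose only point is her sex: never in the denominator
        patients["f1"] = make_patient(
            "f1", birth=date(1970, 1, 1), sex="female", clinic="c1",
            diagnoses=[("I48", date(2012, 1, 1))],
        )
        # diagnosed mid-study: counted only from onset
        patients["n1"] = make_patient(
            "n1", birth=date(1935, 1, 1), sex="male", clinic="c1",
            diagnoses=[("I48", date(2016, 6, 1))],
        )
        return Registry(
            clinics={"c1": Clinic("c1", 5000), "c2": Clinic("c2", 5000)},
            patients=patients,
            census_start=STUDY_START,
            census_end=STUDY_END,
        )

    def test_direct_count_on_handbuilt_clinic(self):
        got = {s.clinic_id: s for s in adherence_census(self._registry(), CENSUS)}
        assert (got["c1"].numerator, got["c1"].denominator) == (2, 3)

    def test_empty_clinic_flagged_zero_over_zero(self):
        got = {s.clinic_id: s for s in adherence_census(self._registry(), CENSUS)}
        assert (got["c2"].numerator, got["c2"].denominator) == (0, 0)
        assert np.isnan(got["c2"].proportion)

    def test_new_patient_enters_from_onset(self):
        reg = self._registry()
        before = {s.clinic_id: s for s in adherence_census(reg, CENSUS)}
        after = {s.clinic_id: s for s in adherence_census(reg, STUDY_END)}
        assert after["c1"].denominator == before["c1"].denominator + 1

    def test_invalid_summary_rejected(self):
        with pytest.raises(AnalysisError):
            ClinicSummary("c1", CENSUS, numerator=4, denominator=3)


class TestPooledAndMeans:
    def test_hand_arithmetic(self):
        got = pooled_and_mean_adherence(summaries([(1, 2), (3, 4)]))
        assert got["pooled"] == pytest.approx(4 / 6)
        assert got["unweighted_mean"] == pytest.approx(0.625)

    def test_single_clinic_all_equal(self):
        got = pooled_and_mean_adherence(summaries([(3, 4)]))
        assert got["pooled"] == got["unweighted_mean"] == got["weighted_mean"] == 0.75

    def test_published_baseline_counts_quotient(self):
        # intervention-arm baseline census: 5,186 of 7,370 treated
        got = pooled_and_mean_adherence(summaries([(5186, 7370)]))
        assert got["pooled"] == pytest.approx(0.7037, abs=5e-5)

    def test_all_zero_denominators_rejected(self):
        with pytest.raises(AnalysisError):
            pooled_and_mean_adherence(summaries([(0, 0)]))


def wls_normal_equations(y, X, w):
    """Independent closed-form oracle: solve X'WX b = X'Wy and classical SEs."""
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ W @ resid) / (len(y) - X.shape[1])
    cov = sigma2 * np.linalg.inv(XtWX)
    return beta, np.sqrt(np.diag(cov))


class TestPrimaryAnalysis:
    def test_identical_proportions_give_zero_effect(self):
        base = summaries([(7, 10)] * 6)
        fu = summaries([(7, 10)] * 6)
        arms = {f"c{i}": "cds" if i < 3 else "control" for i in range(6)}
        res = primary_analysis(base, fu, arms)
        assert res.effect_estimate == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 11))
        base_den = rng.integers(20, 400, k)
        fu_den = rng.integers(20, 400, k)
        base_num = rng.binomial(base_den, 0.7)
        fu_num = rng.binomial(fu_den, 0.72)
        arm = (np.arange(k) % 2).astype(float)
        res = primary_analysis_arrays(base_num, base_den, fu_num, fu_den, arm)
        y = fu_num / fu_den
        X = np.column_stack([np.ones(k), arm, base_num / base_den])
        beta, se = wls_normal_equations(y, X, fu_den.astype(float))
        assert res.effect_estimate == pytest.approx(beta[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.baseline_coefficient == pytest.approx(beta[2], abs=1e-10)
        assert res.effect_se == pytest.approx(se[1], abs=1e-10)

    def test_baseline_weighting_option(self):
        rng = np.random.default_rng(3)
        k = 8
        base_den = rng.integers(50, 200, k)
        fu_den = rng.integers(50, 200, k)
        base_num = rng.binomial(base_den, 0.7)
        fu_num = rng.binomial(fu_den, 0.7)
        arm = (np.arange(k) % 2).astype(float)
        res = primary_analysis_arrays(
            base_num, base_den, fu_num, fu_den, arm, weights="baseline"
        )
        y = fu_num / fu_den
        X = np.column_stack([np.ones(k), arm, base_num / base_den])
        beta, _ = wls_normal_equations(y, X, base_den.astype(float))
        assert res.effect_estimate == pytest.approx(beta[1], abs=1e-10)
        assert res.weights_used == "baseline"

    def test_too_few_clinics_rejected(self):
        with pytest.raises(AnalysisError):
            primary_analysis_arrays([5], [10], [5], [10], [1.0])

    @given(shift=st.floats(-0.2, 0.2))
    @settings(max_examples=30, deadline=None)
    def test_arm_effect_invariant_to_baseline_shift(self, shift):
        rng = np.random.default_rng(7)
        k = 10
        den = np.full(k, 1000)
        base_p = rng.uniform(0.4, 0.6, k)
        fu_num = rng.binomial(den, 0.7)
        arm = (np.arange(k) % 2).astype(float)
        r1 = primary_analysis_arrays(base_p * 1000, den, fu_num, den, arm)
        r2 = primary_analysis_arrays((base_p + shift) * 1000, den, fu_num, den, arm)
        assert r2.effect_estimate == pytest.approx(r1.effect_estimate, abs=1e-6)


class TestICC:
    def test_identical_balanced_clusters_no_between_variance(self):
        # 10 clusters, each 7/10: MSB is below MSW, estimate <= 0
        icc = icc_from_counts([7] * 10, [10] * 10)
        assert icc <= 0.0

    def test_perfectly_segregated_clusters(self):
        icc = icc_from_counts([10, 10, 0, 0], [10, 10, 10, 10])
        assert icc == pytest.approx(1.0)

    def test_counts_and_expanded_forms_agree(self):
        rng = np.random.default_rng(5)
        den = rng.integers(5, 40, 12)
        num = rng.binomial(den, rng.uniform(0.3, 0.9, 12))
        values, groups = [], []
        for j, (x, n) in enumerate(zip(num, den)):
            values += [1.0] * x + [0.0] * (n - x)
            groups += [j] * n
        assert icc_from_counts(num, den) == pytest.approx(
            icc_shrout_fleiss(values, groups), abs=1e-12
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(AnalysisError):
            icc_from_counts([5], [10])

    def test_parameter_recovery_beta_binomial(self):
        rng = np.random.default_rng(11)
        a, b = 0.70 * 99, 0.30 * 99  # mean 0.70, ICC 0.01
        est = []
        for _ in range(200):
            p = rng.beta(a, b, 43)
            den = np.full(43, 300)
            est.append(icc_from_counts(rng.binomial(den, p), den))
        assert np.mean(est) == pytest.approx(0.01, abs=0.005)


class TestEventComparison:
    def test_identical_arms(self):
        got = event_comparison(50, 1000, 50, 1000)
        assert got.chi2_statistic == pytest.approx(0.0)
        assert got.p_value == pytest.approx(1.0)
        assert got.rate_per_1000_a == 50

    def test_chi2_matches_textbook_formula(self):
        # 2x2 table {10, 990; 20, 980}: chi2 = sum (O-E)^2 / E
        table = np.array([[10, 990], [20, 980]], float)
        rowsum = table.sum(1, keepdims=True)
        colsum = table.sum(0, keepdims=True)
        expected = rowsum @ colsum / table.sum()
        chi2_hand = float(((table - expected) ** 2 / expected).sum())
        got = event_comparison(10, 1000, 20, 1000)
        assert got.chi2_statistic == pytest.approx(chi2_hand, abs=1e-10)

    def test_zero_events_everywhere(self):
        got = event_comparison(0, 100, 0, 200)
        assert got.p_value == 1.0

    def test_events_exceeding_n_rejected(self):
        with pytest.raises(AnalysisError):
            event_comparison(11, 10, 0, 10)


class TestQuartileSubgroup:
    def test_degenerate_equal_baselines_flagged(self):
        base = summaries([(70, 100)] * 8)
        fu = summaries([(72, 100)] * 8)
        arms = {f"c{i}": "cds" if i % 2 else "control" for i in range(8)}
        got = quartile_subgroup(base, fu, arms)
        assert not got["first_quartile"]["estimable"]

    def test_constructed_subgroup_effects_recovered(self):
        # four baseline tiers of four clinics (two per arm each); the bottom
        # tier gets +6pp under intervention, the top tier +1pp, no drift in
        # control, so the quartiles are exactly the outer tiers
        tiers = [0.55, 0.65, 0.75, 0.85]
        base_p = np.array([t + 0.002 * i for t in tiers for i in range(4)])
        arms = {f"c{i}": ("cds" if i % 2 else "control") for i in range(16)}
        den = 2000
        fu_p = base_p.copy()
        for i in range(16):
            if arms[f"c{i}"] == "cds":
                fu_p[i] += 0.06 if i < 4 else (0.01 if i >= 12 else 0.03)
        base = summaries([(round(p * den), den) for p in base_p])
        fu = summaries([(round(p * den), den) for p in fu_p])
        got = quartile_subgroup(base, fu, arms)
        assert got["first_quartile"]["estimable"] and got["fourth_quartile"]["estimable"]
        assert (
            got["first_quartile"]["effect_estimate"]
            > got["fourth_quartile"]["effect_estimate"]
        )
        assert got["first_quartile"]["effect_estimate"] == pytest.approx(0.06, abs=0.02)

    def test_too_few_clinics_rejected(self):
        base = summaries([(70, 100)] * 4)
        with pytest.raises(AnalysisError):
            quartile_subgroup(base, base, {f"c{i}": "cds" for i in range(4)})


class TestSafetyExtraction:
    def _setting(self):
        patients = {}
        arms = {}
        for arm, clinic in (("cds", "c1"), ("control", "c2")):
            arms[clinic] = arm
            for i in range(100):
                pid = f"{clinic}-{i}"
                patients[pid] = make_patient(
                    pid, birth=date(1940, 1, 1), sex="male", clinic=clinic,
                    diagnoses=[("I48", date(2015, 1, 1))],
                    prescriptions=[("B01AF02", date(2016, 2, 1), None)],  # initiated after start
                )
        reg = Registry(
            clinics={"c1": Clinic("c1", 5000), "c2": Clinic("c2", 5000)},
            patients=patients,
            census_start=STUDY_START,
            census_end=STUDY_END,
        )
        bleeds = [("c1-0", "2016-03-01"), ("c1-1", "2016-04-01"),
                  ("c2-0", "2016-03-01"), ("c2-1", "2016-05-01"),
                  ("c2-2", "2016-06-01"), ("c2-3", "2016-11-01")]
        outcomes = pd.DataFrame(
            [{"patient_id": p, "date": d, "type": "bleeding"} for p, d in bleeds]
        )
        return reg, arms, outcomes

    def test_hand_built_rates(self):
        reg, arms, outcomes = self._setting()
        got = safety_extraction(outcomes, reg, arms, at_months=12)
        assert got["initiated"] == {"cds": 100, "control": 100}
        cmp_ = got["comparison"]
        assert (cmp_.events_a, cmp_.events_b) == (2, 4)
        assert cmp_.rate_per_1000_a == pytest.approx(20)
        assert cmp_.rate_per_1000_b == pytest.approx(40)

    def test_extraction_respects_date_cutoff(self):
        reg, arms, outcomes = self._setting()
        got = safety_extraction(outcomes, reg, arms, at_months=3)
        # the 3-month cutoff (2016-04-11) keeps events up to early April and
        # drops the May/June/November ones
        assert got["extraction_date"] == "2016-04-11"
        assert got["comparison"].events_a == 2 and got["comparison"].events_b == 1

    def test_no_initiations_warns(self):
        reg, arms, outcomes = self._setting()
        for p in reg.patients.values():
            p.prescriptions.clear()
        got = safety_extraction(outcomes, reg, arms, at_months=6)
        assert got["comparison"] is None and "warning" in got


class TestClusterTableIO:
    def test_xlsx_round_trip_and_analysis(self, tmp_path):
        """A synthetic cluster-level workbook with a planted +2pp intervention
        effect analyzed through the import pipeline."""
        rng = np.random.default_rng(8)
        k = 42
        arm = np.array(["cds"] * 21 + ["control"] * 21)
        den_b = rng.integers(150, 500, k)
        den_f = den_b + rng.integers(0, 30, k)
        p = rng.uniform(0.65, 0.75, k)
        df = pd.DataFrame(
            {
                "clinic_id": [f"c{i}" for i in range(k)],
                "arm": arm,
                "baseline_numerator": rng.binomial(den_b, p),
                "baseline_denominator": den_b,
                "followup_numerator": rng.binomial(
                    den_f, np.clip(p + 0.012 + 0.02 * (arm == "cds"), 0, 1)
                ),
                "followup_denominator": den_f,
            }
        )
        path = tmp_path / "clusters_synthetic.xlsx"
        write_cluster_table_xlsx(df, path)
        back = read_cluster_table_xlsx(path)
        pd.testing.assert_frame_equal(back, df)
        got = analyze_cluster_table(back)
        assert got["primary"].effect_estimate == pytest.approx(0.02, abs=0.012)
        assert got["primary"].n_clusters_per_arm == (21, 21)
        assert -0.05 < got["icc_followup"] < 0.05

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.xlsx"
        pd.DataFrame({"clinic_id": ["a"]}).to_excel(path, index=False)
        with pytest.raises(AnalysisError, match="missing columns"):
            read_cluster_table_xlsx(path)
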