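"""Survival modelling, concordance, NRI, bootstrap, calibration."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index as lifelines_c

from astraj.errors import DegenerateModelError, InvalidInputError, UndefinedMetricError
from astraj.survival import (
    bootstrap_ci,
    calibration_table,
    categorical_nri,
    fit_cox_ladder,
    harrell_c,
    predicted_mortality,
    reclassification_analysis,
)


def brute_force_c(times, events, risk):
    """O(n^2) pair enumeration with explicit comparability rules."""
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or not events[i]:
                continue
            if times[i] < times[j] or (times[i] == times[j] and not events[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


@pytest.fixture(scope="module")
def survival_frame(trajectory_cohort):
    df = trajectory_cohort.subjects.copy()
    df["cluster_label"] = trajectory_cohort.truth.values
    return df


class TestHarrellC:
    def test_perfect_and_reversed_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        risk = np.array([4.0, 3.0, 2.0, 1.0])
        assert harrell_c(t, e, risk) == 1.0
        assert harrell_c(t, e, -risk) == 0.0

    def test_matches_exhaustive_enumeration_with_censoring(self):
        rng = np.random.default_rng(11)
        n = 100
        t = np.round(rng.exponential(2.0, n), 2)      # ties on purpose
        e = (rng.uniform(size=n) > 0.3).astype(int)
        risk = np.round(rng.normal(size=n), 1)
        assert harrell_c(t, e, risk) == pytest.approx(
            brute_force_c(t, e, risk), abs=1e-12)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(12)
        n = 150
        t = rng.exponential(2.0, n)
        e = (rng.uniform(size=n) > 0.3).astype(int)
        risk = rng.normal(size=n)
        # lifelines orders by predicted survival time (higher = longer)
        assert harrell_c(t, e, risk) == pytest.approx(
            lifelines_c(t, -risk, e), abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(2.0, 60)
        e = (rng.uniform(size=60) > 0.3).astype(int)
        risk = rng.uniform(0.1, 5.0, 60)
        assert harrell_c(t, e, risk) == harrell_c(t, e, np.log(risk))

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(2.0, 50)
        e = np.ones(50, dtype=int)
        risk = rng.normal(size=50)
        assert harrell_c(t, e, risk) + harrell_c(t, e, -risk) == pytest.approx(1.0)

    def test_no_comparable_pairs_undefined(self):
        with pytest.raises(UndefinedMetricError):
            harrell_c([1.0, 2.0], [0, 0], [0.1, 0.2])


class TestCoxLadder:
    def test_cluster_terms_present_in_all_models(self, survival_frame):
        for model_id in (1, 2, 3):
            _, table = fit_cox_ladder(survival_frame, model_id)
            terms = set(table["term"])
            assert "cluster_AcceleratedProgression" in terms
            assert "cluster_PersistentlyHigh" in terms
            assert (table["ci_low"] <= table["hr"]).all()
            assert (table["hr"] <= table["ci_high"]).all()

    def test_model_covariate_sets_nest(self, survival_frame):
        _, t1 = fit_cox_ladder(survival_frame, 1)
        _, t2 = fit_cox_ladder(survival_frame, 2)
        _, t3 = fit_cox_ladder(survival_frame, 3)
        assert set(t1["term"]) < set(t2["term"]) < set(t3["term"])

    def test_too_few_events_rejected(self, survival_frame):
        few = survival_frame.head(20).copy()
        few["event"] = 0
        few.loc[few.index[:2], "event"] = 1
        with pytest.raises(DegenerateModelError):
            fit_cox_ladder(few, 1)

    def test_single_cluster_rejected(self, survival_frame):
        df = survival_frame.copy()
        df["cluster_label"] = "StableLow"
        with pytest.raises(InvalidInputError):
            fit_cox_ladder(df, 1)


class TestPredictedMortality:
    def test_uninformative_covariate_reduces_to_pooled_km(self, survival_frame):
        df = survival_frame.copy()
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(size=len(df))
        cph = CoxPHFitter()
        cph.fit(df[["noise", "survival_time_years", "event"]],
                duration_col="survival_time_years", event_col="event")
        probs = predicted_mortality(cph, df[["noise"]], 2.0)
        kmf = KaplanMeierFitter()
        kmf.fit(df["survival_time_years"], df["event"])
        pooled = 1.0 - float(kmf.predict(2.0))
        assert np.mean(probs) == pytest.approx(pooled, abs=0.02)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(1)
        lam, n = 0.2, 4000
        t = rng.exponential(1 / lam, n)
        df = pd.DataFrame({"survival_time_years": t,
                           "event": np.ones(n, dtype=int),
                           "x": rng.normal(size=n)})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="survival_time_years", event_col="event")
        probs = predicted_mortality(cph, df[["x"]], 3.0)
        assert np.mean(probs) == pytest.approx(1 - np.exp(-3 * lam), abs=0.02)

    def test_probabilities_bounded_and_monotone_in_horizon(self, survival_frame):
        df = survival_frame.copy()
        cph = CoxPHFitter()
        cph.fit(df[["sts_score", "survival_time_years", "event"]],
                duration_col="survival_time_years", event_col="event")
        p1 = predicted_mortality(cph, df[["sts_score"]], 1.0)
        p3 = predicted_mortality(cph, df[["sts_score"]], 3.0)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        assert (p3 >= p1 - 1e-12).all()

    def test_horizon_beyond_followup_warns(self, survival_frame):
        cph = CoxPHFitter()
        cph.fit(survival_frame[["sts_score", "survival_time_years", "event"]],
                duration_col="survival_time_years", event_col="event")
        with pytest.warns(UserWarning, match="beyond last observed"):
            predicted_mortality(cph, survival_frame[["sts_score"]], 50.0)


class TestCategoricalNri:
    def test_identity_gives_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 0.2, 50)
        t = rng.exponential(5, 50)
        e = np.ones(50, dtype=int)
        res = categorical_nri(p, p, t, e, 1.0)
        assert res.nri_events == 0.0
        assert res.nri_nonevents == 0.0
        assert res.nri_overall == 0.0

    def test_maximum_improvement_equals_two(self):
        # full follow-up: every event moved up a bin, every non-event down
        e = np.array([1, 1, 1, 0, 0, 0])
        t = np.array([0.5, 0.5, 0.5, 5.0, 5.0, 5.0])
        base = np.array([0.06, 0.06, 0.06, 0.06, 0.06, 0.06])
        aug = np.array([0.09, 0.09, 0.09, 0.03, 0.03, 0.03])
        res = categorical_nri(base, aug, t, e, 1.0)
        assert res.nri_overall == pytest.approx(2.0)

    def test_hand_enumerated_twelve_subject_toy(self):
        """Full follow-up; expected values enumerated by hand.

        Events (4): 2 up, 1 down, 1 unmoved -> (2-1)/4 = 0.25.
        Non-events (8): 3 down, 2 up, 3 unmoved -> (3-2)/8 = 0.125.
        """
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        t = np.where(e == 1, 0.5, 3.0)
        base = np.array([0.03, 0.03, 0.09, 0.06,
                         0.09, 0.09, 0.09, 0.03, 0.03, 0.06, 0.06, 0.06])
        aug = np.array([0.06, 0.06, 0.06, 0.06,
                        0.06, 0.06, 0.03, 0.06, 0.06, 0.06, 0.06, 0.06])
        res = categorical_nri(base, aug, t, e, 1.0)
        assert res.nri_events == pytest.approx(0.25)
        assert res.nri_nonevents == pytest.approx(0.125)
        assert res.nri_overall == pytest.approx(0.375)

    def test_km_equals_counting_under_full_followup(self):
        rng = np.random.default_rng(3)
        n = 80
        base = rng.uniform(0.01, 0.2, n)
        aug = np.clip(base + rng.normal(0, 0.03, n), 0.005, 0.5)
        t = rng.exponential(2.5, n)       # full follow-up: every time is
        e = np.ones(n, dtype=int)         # an observed event
        km = categorical_nri(base, aug, t, e, 2.0, censoring="km")
        cc = categorical_nri(base, aug, t, e, 2.0, censoring="complete_case")
        assert km.nri_overall == pytest.approx(cc.nri_overall, abs=1e-12)
        assert km.nri_events == pytest.approx(cc.nri_events, abs=1e-12)

    def test_decomposition_identity(self, survival_frame):
        res = reclassification_analysis(survival_frame, "sts_score", 1.0,
                                        n_boot=0, mode="face_value")
        assert res.nri_overall == pytest.approx(
            res.nri_events + res.nri_nonevents, abs=1e-12)

    def test_no_events_undefined(self):
        p = np.array([0.03, 0.06])
        with pytest.raises(UndefinedMetricError):
            categorical_nri(p, p, np.array([5.0, 6.0]),
                            np.array([0, 0]), 1.0)

    def test_bad_categories_rejected(self):
        p = np.array([0.03, 0.06])
        with pytest.raises(InvalidInputError):
            categorical_nri(p, p, np.array([1.0, 0.5]), np.array([1, 1]),
                            1.0, categories=(0.1, 0.05))


class TestBootstrapCi:
    def test_constant_statistic_zero_width(self, survival_frame):
        ci = bootstrap_ci(lambda df: 1.23, survival_frame, n_boot=50, seed=0)
        assert ci == (1.23, 1.23)

    def test_seed_determinism(self, survival_frame):
        stat = lambda df: df["sts_score"].mean()
        a = bootstrap_ci(stat, survival_frame, n_boot=100, seed=7)
        b = bootstrap_ci(stat, survival_frame, n_boot=100, seed=7)
        assert a == b

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (100, 400):
            df = pd.DataFrame({"x": rng.normal(size=n)})
            per_seed = []
            for s in range(5):
                lo, hi = bootstrap_ci(lambda d: d["x"].mean(), df,
                                      n_boot=200, seed=s)
                per_seed.append(hi - lo)
            widths.append(np.mean(per_seed))
        # ~1/sqrt(n): quadrupling n should halve the width
        assert widths[1] / widths[0] == pytest.approx(0.5, abs=0.15)

    def test_failing_statistic_raises(self, survival_frame):
        def bad(df):
            raise RuntimeError("boom")
        with pytest.raises(DegenerateModelError):
            bootstrap_ci(bad, survival_frame, n_boot=20, seed=0)


class TestCalibration:
    def test_bins_partition_all_subjects(self, survival_frame):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.01, 0.5, len(survival_frame))
        table = calibration_table(p, survival_frame["survival_time_years"],
                                  survival_frame["event"], 2.0)
        assert table["n"].sum() == len(survival_frame)
        assert len(table) == 10

    def test_constant_predictions_single_bin_pooled_km(self, survival_frame):
        p = np.full(len(survival_frame), 0.2)
        with pytest.warns(UserWarning, match="collapsed"):
            table = calibration_table(p,
                                      survival_frame["survival_time_years"],
                                      survival_frame["event"], 2.0)
        assert len(table) == 1
        kmf = KaplanMeierFitter()
        kmf.fit(survival_frame["survival_time_years"],
                survival_frame["event"])
        assert table.loc[0, "observed_km"] == pytest.approx(
            1 - float(kmf.predict(2.0)), abs=1e-9)


class TestReclassificationAnalysis:
    def test_reports_cis_and_valid_c(self, survival_frame):
        res = reclassification_analysis(survival_frame, "sts_score", 2.0,
                                        n_boot=30, seed=1, mode="face_value")
        assert 0.0 <= res.c_base <= 1.0
        assert 0.0 <= res.c_augmented <= 1.0
        assert res.nri_overall_ci[0] <= res.nri_overall_ci[1]
        assert res.n_boot == 30
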