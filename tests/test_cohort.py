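"""Cohort-level statistics: arm comparison, quartiles, KM, Cox, concordance."""

import math

import numpy as np
import pandas as pd
import pytest

import tumorkinetics as tk
from tumorkinetics.cohort import QuartileAssignment

from oracles import cox_brute_force, harrell_c_pairs, km_product_limit


def results_frame(g_values, ids=None, classification=None, d_values=None):
    n = len(g_values)
    ids = ids or [f"s{i}" for i in range(n)]
    if classification is None:
        classification = ["dx" if g == 0 else "gd" for g in g_values]
    return pd.DataFrame({
        "subject_id": ids,
        "classification": classification,
        "g_per_day": g_values,
        "d_per_day": d_values if d_values is not None else [0.01] * n,
        "phi": [None] * n,
        "tdt_days": [None] * n,
        "aic": [0.0] * n,
        "n_points": [5] * n,
        "flags": [""] * n,
    })


def survival_frame(ids, arms=None, os_days=None, os_event=None, **extra):
    n = len(ids)
    df = pd.DataFrame({
        "subject_id": ids,
        "arm": arms if arms is not None else ["A"] * n,
        "os_days": os_days if os_days is not None else [100.0] * n,
        "os_event": os_event if os_event is not None else [1] * n,
        "pfs_days": extra.get("pfs_days", os_days if os_days is not None else [100.0] * n),
        "pfs_event": extra.get("pfs_event", os_event if os_event is not None else [1] * n),
    })
    for k, v in extra.items():
        if k not in df.columns:
            df[k] = v
    return df


class TestCompareArms:
    def test_fully_separated_arms(self):
        g = [0.0] * 10 + [0.001] * 10
        frame = results_frame(g)
        surv = survival_frame(frame["subject_id"], arms=["A"] * 10 + ["B"] * 10)
        cmp = tk.compare_arms_g(frame, surv)
        assert cmp.median["A"] == 0.0
        assert cmp.median["B"] == 0.001
        assert cmp.p_value < 1e-3

    def test_identical_arms_yield_p_one(self):
        g = [0.001] * 8
        frame = results_frame(g)
        surv = survival_frame(frame["subject_id"], arms=["A"] * 4 + ["B"] * 4)
        assert tk.compare_arms_g(frame, surv).p_value == 1.0

    def test_unmodeled_subjects_are_excluded(self):
        frame = results_frame([0.0, 0.001, 0.002, None],
                              classification=["dx", "gd", "gd", "not_fit"])
        surv = survival_frame(frame["subject_id"], arms=["A", "A", "B", "B"])
        # arm B keeps a single modeled subject once not_fit is dropped
        with pytest.raises(ValueError, match="fewer than 2"):
            tk.compare_arms_g(frame, surv)


class TestAssignQuartiles:
    def test_order_statistics_example(self):
        g = np.array([1, 2, 3, 4, 5, 6, 7, 8]) * 1e-4
        qa = tk.assign_quartiles(results_frame(list(g)))
        got = qa.strata.sort_index(key=lambda s: s.str.slice(1).astype(int))
        assert list(got) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_dx_subjects_form_their_own_stratum(self):
        g = [0.0] * 4 + list(np.array([1, 2, 3, 4, 5, 6, 7, 8]) * 1e-4)
        qa = tk.assign_quartiles(results_frame(g))
        counts = qa.counts()
        assert counts["dx"] == 4
        assert all(counts[q] == 2 for q in ("Q1", "Q2", "Q3", "Q4"))

    def test_ties_at_cutpoint_go_to_lower_quartile(self):
        # 25th percentile of these 8 values is exactly 2e-4; both subjects
        # sitting at the cutpoint land in Q1 under the documented rule
        g = np.array([1, 2, 2, 3, 4, 5, 6, 7]) * 1e-4
        qa = tk.assign_quartiles(results_frame(list(g)))
        q1_members = set(qa.strata[qa.strata == "Q1"].index)
        assert {"s0", "s1", "s2"} <= q1_members

    def test_no_growers_is_an_error(self):
        with pytest.raises(ValueError, match="quartiles"):
            tk.assign_quartiles(results_frame([0.0, 0.0, 0.0, 0.0]))

    def test_quartiles_partition_modeled_subjects(self, small_cohort_results):
        qa = tk.assign_quartiles(small_cohort_results)
        modeled = small_cohort_results[
            small_cohort_results["classification"].isin(["dx", "gx", "gd", "gdphi"])]
        assert qa.counts().sum() == len(modeled)


class TestKaplanMeier:
    def test_hand_product_limit_no_censoring(self):
        ids = ["a", "b", "c", "d"]
        g = [1e-4, 2e-4, 3e-4, 4e-4]
        qa = QuartileAssignment((1e-3, 2e-3, 3e-3),
                                pd.Series(["Q1"] * 4, index=ids, name="stratum"))
        surv = survival_frame(ids, os_days=[100, 200, 300, 400], os_event=[1, 1, 1, 1])
        km = tk.km_by_stratum(qa, surv, "os")
        row = km.iloc[0]
        # S = .75, .50, .25, 0; median = first time S <= 0.5; S(365) = 25%
        assert row["median_days"] == 200.0
        assert row["rate_1yr_pct"] == pytest.approx(25.0)

    def test_matches_oracle_with_censoring(self):
        times = [10, 20, 20, 35, 50, 61, 61, 70, 80, 90]
        events = [1, 0, 1, 1, 0, 1, 0, 1, 0, 0]
        ids = [f"s{i}" for i in range(10)]
        qa = QuartileAssignment((1, 2, 3), pd.Series(["Q2"] * 10, index=ids))
        surv = survival_frame(ids, os_days=times, os_event=events)
        km = tk.km_by_stratum(qa, surv, "os")
        _, s_oracle = km_product_limit(times, events)
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(times, events)
        np.testing.assert_allclose(
            kmf.survival_function_.loc[[10, 20, 35, 61, 70], "KM_estimate"].to_numpy(),
            s_oracle, atol=1e-12)
        assert km.iloc[0]["n"] == 10

    def test_all_censored_never_reaches_median(self):
        ids = ["a", "b", "c"]
        qa = QuartileAssignment((1, 2, 3), pd.Series(["Q1"] * 3, index=ids))
        surv = survival_frame(ids, os_days=[100, 400, 500], os_event=[0, 0, 0])
        km = tk.km_by_stratum(qa, surv, "os")
        assert math.isnan(km.iloc[0]["median_days"])
        assert km.iloc[0]["rate_1yr_pct"] == 100.0


class TestCox:
    def test_recovers_known_hazard_ratio(self):
        rng = np.random.default_rng(8)
        n = 1000
        strata = np.array(["Q4"] * (n // 2) + ["Q1"] * (n // 2))
        lam = np.where(strata == "Q4", 0.02, 0.01)  # true HR(Q1 vs Q4) = 0.5
        times = rng.exponential(1 / lam)
        ids = [f"s{i}" for i in range(n)]
        qa = QuartileAssignment((1, 2, 3), pd.Series(strata, index=ids))
        surv = survival_frame(ids, os_days=times, os_event=[1] * n)
        cox = tk.cox_by_stratum(qa, surv, "os")
        hr = cox.set_index("stratum").loc["Q1", "hr"]
        assert 0.9 * 0.5 <= hr <= 1.1 * 0.5

    def test_matches_brute_force_partial_likelihood(self):
        times = [3.0, 5.0, 8.0, 11.0, 14.0, 20.0, 26.0, 33.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        strata = ["Q1", "Q4", "Q1", "Q4", "Q1", "Q4", "Q1", "Q4"]
        ids = [f"s{i}" for i in range(8)]
        qa = QuartileAssignment((1, 2, 3), pd.Series(strata, index=ids))
        surv = survival_frame(ids, os_days=times, os_event=events)
        cox = tk.cox_by_stratum(qa, surv, "os")
        hr = cox.set_index("stratum").loc["Q1", "hr"]
        x = np.array([1.0 if s == "Q1" else 0.0 for s in strata])
        beta_oracle = cox_brute_force(times, events, x)
        assert math.log(hr) == pytest.approx(beta_oracle, abs=1e-6)

    def test_zero_event_stratum_reports_degenerate_hr(self):
        ids = [f"s{i}" for i in range(12)]
        strata = ["Q1"] * 4 + ["Q4"] * 8
        qa = QuartileAssignment((1, 2, 3), pd.Series(strata, index=ids))
        surv = survival_frame(ids, os_days=[300] * 4 + list(range(20, 100, 10)),
                              os_event=[0] * 4 + [1] * 8)
        cox = tk.cox_by_stratum(qa, surv, "os")
        row = cox.set_index("stratum").loc["Q1"]
        assert row["hr"] == 0.0
        assert row["ci_low"] == 0.0
        assert math.isinf(row["ci_high"])

    def test_no_events_anywhere_raises(self):
        ids = ["a", "b", "c", "d"]
        qa = QuartileAssignment((1, 2, 3), pd.Series(["Q1", "Q1", "Q4", "Q4"], index=ids))
        surv = survival_frame(ids, os_days=[10, 20, 30, 40], os_event=[0, 0, 0, 0])
        with pytest.raises(ValueError, match="no events"):
            tk.cox_by_stratum(qa, surv, "os")


class TestConcordance:
    def test_perfect_rank_order_gives_one(self):
        n = 10
        g = np.linspace(1e-4, 1e-3, n)
        times = np.linspace(500, 50, n)  # higher g -> earlier death
        ids = [f"s{i}" for i in range(n)]
        frame = results_frame(list(g), ids=ids,
                              classification=["gd"] * n)
        surv = survival_frame(ids, os_days=list(times), os_event=[1] * n,
                              response_category=["stable"] * n)
        c_g, _ = tk.concordance_comparison(frame, surv)
        assert c_g == pytest.approx(1.0)

    def test_independent_predictor_is_near_half(self):
        rng = np.random.default_rng(4)
        n = 400
        g = np.exp(rng.normal(-7, 1, n))
        times = rng.exponential(300, n)
        ids = [f"s{i}" for i in range(n)]
        frame = results_frame(list(g), ids=ids, classification=["gd"] * n)
        surv = survival_frame(ids, os_days=list(times), os_event=[1] * n,
                              response_category=rng.choice(
                                  ["responder", "stable", "progression"], n).tolist())
        c_g, _ = tk.concordance_comparison(frame, surv)
        assert abs(c_g - 0.5) < 0.06

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(12)
        n = 50
        g = np.exp(rng.normal(-7, 0.8, n))
        lam = 1e-3 * np.exp(800 * g)
        times = np.round(rng.exponential(1 / lam), 3)
        events = (times < 900).astype(int)
        times = np.minimum(times, 900.0)
        ids = [f"s{i}" for i in range(n)]
        frame = results_frame(list(g), ids=ids, classification=["gd"] * n)
        surv = survival_frame(ids, os_days=list(times), os_event=list(events),
                              response_category=["stable"] * n)
        c_g, _ = tk.concordance_comparison(frame, surv)
        c_oracle = harrell_c_pairs(times, events, g)
        assert c_g == pytest.approx(c_oracle, abs=1e-10)

    def test_too_few_subjects_raise(self):
        frame = results_frame([1e-4], ids=["a"], classification=["gd"])
        surv = survival_frame(["a"], os_days=[100], os_event=[1],
                              response_category=["stable"])
        with pytest.raises(ValueError):
            tk.concordance_comparison(frame, surv)


class TestDQuartiles:
    def test_partitions_d_bearing_subjects(self, small_cohort_results, small_cohort):
        qa, km, cox = tk.quartile_analysis_on_d(small_cohort_results,
                                                small_cohort.survival)
        n_d = (small_cohort_results["d_per_day"] > 0).sum()
        assert qa.counts().sum() == n_d
        assert qa.counts()["dx"] == 0

    def test_no_decay_subjects_is_an_error(self):
        frame = results_frame([1e-4, 2e-4], classification=["gx", "gx"],
                              d_values=[None, None])
        surv = survival_frame(frame["subject_id"])
        with pytest.raises(ValueError, match="fitted d"):
            tk.quartile_analysis_on_d(frame, surv)

    def test_d_less_predictive_than_g_when_hazard_depends_on_g(
            self, small_cohort_results, small_cohort):
        """Survival is generated from g only, so d-quartiles are ~noise."""
        g_qa = tk.assign_quartiles(small_cohort_results)
        g_cox = tk.cox_by_stratum(g_qa, small_cohort.survival, "os")
        _, _, d_cox = tk.quartile_analysis_on_d(small_cohort_results,
                                                small_cohort.survival)
        hr_g = g_cox.set_index("stratum").loc["Q1", "hr"]
        hr_d = d_cox.set_index("stratum").loc["Q1", "hr"]
        assert hr_g < hr_d


class TestEarlyLook:
    def test_full_followup_cut_equals_full_analysis(self, small_cohort):
        sim = small_cohort
        n = len(sim.trajectories)
        el = tk.early_look(sim.trajectories, sim.survival, n,
                           followup_floor_days=10_000.0)
        full = tk.results_to_frame(tk.fit_cohort(sim.trajectories))
        merged = el.results.merge(full, on="subject_id", suffixes=("_el", "_full"))
        assert (merged["classification_el"] == merged["classification_full"]).all()

    def test_k_exceeding_cohort_raises(self, small_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            tk.early_look(small_cohort.trajectories, small_cohort.survival, 10_000)

    def test_tiny_interim_runs_without_significance_guarantee(self):
        """Negative control: k=10 at high noise just returns a valid p."""
        scn = tk.db03_like_scenario(seed=21, n_per_arm={"T-DXd": 10, "control": 10},
                                    noise_sd=0.15)
        sim = tk.simulate_cohort(scn)
        el = tk.early_look(sim.trajectories, sim.survival, 10)
        assert 0.0 <= el.comparison.p_value <= 1.0


def test_analyze_cohort_bundles_everything(small_cohort, small_cohort_results):
    an = tk.analyze_cohort(small_cohort_results, small_cohort.survival)
    assert set(an.km_os["stratum"]) <= set(["dx", "Q1", "Q2", "Q3", "Q4"])
    assert (an.cox_os.loc[an.cox_os["reference"], "hr"] == 1.0).all()
    assert set(an.concordance["arm"]) == {"T-DXd", "control"}
    assert (an.km_os["rate_1yr_pct"].between(0, 100)).all()
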