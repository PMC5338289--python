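"""Staining categorization, cohort tables, survival and Cox machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import breslow_partial_loglik
from cdk11net.errors import AnalysisError, InputError
from cdk11net.simulate import CohortSimConfig, generate_tma_cohort
from cdk11net.survival import (
    categorize_staining,
    chi_square,
    cohort_summary,
    cox_fit,
    dichotomize,
    kaplan_meier,
    log_rank,
    low_high_shares,
    round_half_up,
    spearman,
    staining_distribution,
    stepwise_cox,
)


class TestStainingScores:
    @pytest.mark.parametrize(
        "percent,expected",
        [(0.0, 1), (5.0, 1), (9.9, 1), (10.0, 2), (25.0, 2), (25.5, 3), (30.0, 3),
         (50.0, 3), (51.0, 4), (75.0, 4), (80.0, 5), (100.0, 5)],
    )
    def test_percent_bins(self, percent, expected):
        assert categorize_staining(percent) == expected

    def test_no_nuclear_staining_is_category_zero(self):
        assert categorize_staining(0.0, any_nuclear=False) == 0

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(InputError):
            categorize_staining(101.0)

    @pytest.mark.parametrize("cat,expected", [(0, "low"), (2, "low"), (3, "high"), (5, "high")])
    def test_dichotomize_at_category_two(self, cat, expected):
        assert dichotomize(cat) == expected


class TestCohortTables:
    COUNTS = [5, 24, 22, 19, 15, 2]  # published staining categories over 87 cores

    def test_low_high_shares_from_published_counts(self):
        shares = low_high_shares(self.COUNTS)
        assert shares == {"low": 58.6, "high": 41.4}

    def test_category_percentages(self):
        dist = staining_distribution(self.COUNTS)
        assert list(dist["percent"]) == [5.7, 27.6, 25.3, 21.8, 17.2, 2.3]

    def test_age_stratum_column_percent(self):
        # 35 of 67 patients aged <= 24 -> 52.2%
        cohort = pd.DataFrame(
            {
                "ar_category": [3] * 18 + [1] * 17 + [3] * 10 + [1] * 22,
                "age_years": [20] * 35 + [30] * 32,
            }
        )
        summary = cohort_summary(cohort)
        row = summary[(summary["feature"] == "Age") & (summary["stratum"] == "<=24")].iloc[0]
        assert row["n"] == 35
        assert row["percent"] == 52.2
        assert row["ar_high_n"] == 18
        assert row["ar_high_percent"] == 51.4

    def test_single_patient_shares_are_100(self):
        cohort = pd.DataFrame({"ar_category": [4], "age_years": [12]})
        summary = cohort_summary(cohort)
        age = summary[summary["feature"] == "Age"]
        assert list(age["percent"]) == [100.0]
        assert list(age["ar_high_percent"]) == [100.0]

    def test_round_half_up_matches_printed_style(self):
        assert round_half_up(68.75) == 68.8
        assert round_half_up(52.23) == 52.2


class TestChiSquare:
    def test_table_at_expectation_gives_zero(self):
        stat, df, p = chi_square([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chemo_response_table_hand_value(self):
        stat, df, p = chi_square([[6, 3], [10, 27]])
        assert stat == pytest.approx(5.014, abs=1e-3)
        assert df == 1

    def test_doubling_counts_doubles_statistic(self):
        t = np.array([[8, 2], [5, 9]])
        s1, _, _ = chi_square(t)
        s2, _, _ = chi_square(2 * t)
        assert s2 == pytest.approx(2 * s1)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_direct_definition_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, size=(rng.integers(2, 4), rng.integers(2, 4))).astype(float)
        stat, df, _ = chi_square(t)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        assert stat == pytest.approx(((t - expected) ** 2 / expected).sum())
        assert df == (t.shape[0] - 1) * (t.shape[1] - 1)

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            chi_square([[0, 0], [5, 3]])


class TestSpearman:
    def test_perfect_and_reversed(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_pearson(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 3]
        rx = stats.rankdata(x)  # mid-ranks
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        base = spearman(x, y)[0]
        assert spearman(np.exp(x), y)[0] == pytest.approx(base)
        assert spearman(x, y**3)[0] == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            spearman([1, 1, 1], [1, 2, 3])


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=50)
        curve = kaplan_meier(times, np.ones(50, dtype=bool))
        for t in [1.0, 5.0, 12.0]:
            assert curve.at(t) == pytest.approx(np.mean(times > t))

    def test_all_censored_stays_at_one(self):
        curve = kaplan_meier([3.0, 5.0, 9.0], [False, False, False])
        assert np.allclose(curve.survival, 1.0)

    def test_product_limit_hand_computation(self):
        # times (1,2,3), events (1,0,1): S = 2/3 on [1,3); the last
        # subject at risk dies at t=3 so S drops to 0 there
        curve = kaplan_meier([1.0, 2.0, 3.0], [True, False, True])
        assert curve.at(1.5) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(2 / 3)
        assert curve.at(3.5) == pytest.approx(0.0)
        assert list(curve.at_risk) == [3, 2, 1]

    def test_monotone_from_one(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(5, size=80)
        events = rng.random(80) < 0.6
        curve = kaplan_meier(times, events)
        assert curve.survival[0] <= 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_negative_times_rejected(self):
        with pytest.raises(InputError):
            kaplan_meier([-1.0, 2.0], [True, True])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([2.0, 4.0, 6.0, 2.0, 4.0, 6.0])
        events = np.ones(6, dtype=bool)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        stat, df, p = log_rank(groups, times, events)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_power_under_strong_hazard_ratio(self):
        """HR=3 with 500 per arm is detected at p < 0.001 essentially always."""
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(10, 500)
            t1 = rng.exponential(10 / 3, 500)
            times = np.concatenate([t0, t1])
            groups = np.array(["lo"] * 500 + ["hi"] * 500)
            _, _, p = log_rank(groups, times, np.ones(1000, dtype=bool))
            detected += p < 0.001
        assert detected == 20

    def test_permutation_null_is_uniform(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(10, 60)
        events = rng.random(60) < 0.7
        groups = np.array(["a"] * 30 + ["b"] * 30)
        ps = []
        for _ in range(200):
            perm = rng.permutation(groups)
            _, _, p = log_rank(perm, times, events)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            log_rank(["a", "a"], [1.0, 2.0], [True, True])


class TestCoxFit:
    def test_four_subject_fit_matches_grid_search_oracle(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        times = np.array([2.0, 3.0, 5.0, 7.0])
        events = np.array([True, True, True, False])
        model = cox_fit(pd.DataFrame({"x": x}), times, events)
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [breslow_partial_loglik(b, x, times, events) for b in grid]
        assert model.summary.at["x", "coef"] == pytest.approx(grid[int(np.argmax(lls))],
                                                              abs=1e-4)

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        times = rng.exponential(10, n)
        model = cox_fit(pd.DataFrame({"x": x}), times, np.ones(n, dtype=bool))
        assert abs(model.summary.at["x", "coef"]) < 0.1

    def test_recovers_log_hazard_ratio(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 1000).astype(float)
            times = rng.exponential(1.0 / (0.1 * 2.0**x))
            model = cox_fit(pd.DataFrame({"x": x}), times, np.ones(1000, dtype=bool))
            errs.append(model.summary.at["x", "coef"] - np.log(2.0))
        assert np.all(np.abs(errs) < 0.25)
        assert abs(np.mean(errs)) < 0.05

    def test_efron_agrees_with_lifelines_on_tied_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        n = 150
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.integers(0, 2, n).astype(float),
                "t": np.round(rng.exponential(5, n)) + 1,  # heavy ties
                "e": rng.random(n) < 0.8,
            }
        )
        model = cox_fit(df[["x1", "x2"]], df["t"], df["e"], ties="efron")
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.allclose(model.summary["coef"], cph.params_[["x1", "x2"]], atol=1e-4)
        assert np.allclose(model.summary["se"], cph.standard_errors_[["x1", "x2"]],
                           atol=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(InputError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [True, True, True])

    def test_perfect_separation_diagnosed(self):
        # covariate perfectly orders survival: monotone likelihood
        x = np.arange(20, dtype=float)
        times = np.arange(1, 21, dtype=float)
        with pytest.raises(AnalysisError):
            cox_fit(pd.DataFrame({"x": x}), times, np.ones(20, dtype=bool))


class TestStepwiseCox:
    def test_single_strong_candidate_selected(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 400).astype(float)
        times = rng.exponential(1.0 / (0.1 * 3.0**x))
        model = stepwise_cox(pd.DataFrame({"x": x}), times, np.ones(400, dtype=bool))
        assert model.covariates == ["x"]

    def test_strong_covariate_found_among_noise(self):
        """The true predictor always enters; noise covariates rarely do.

        With five null candidates screened at p_enter=0.05, the chance
        that none enters is ~0.95^5 ~ 0.77 per seed, so "signal only"
        is asserted at the conservative binomial bound.
        """
        only_signal = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 1000
            X = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(5)})
            X["signal"] = rng.integers(0, 2, n).astype(float)
            times = rng.exponential(1.0 / (0.1 * 3.0 ** X["signal"]))
            model = stepwise_cox(X, times, np.ones(n, dtype=bool))
            assert "signal" in model.covariates
            only_signal += model.covariates == ["signal"]
        assert only_signal >= 5

    def test_all_noise_yields_empty_model_usually(self):
        empties = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 500
            X = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(4)})
            times = rng.exponential(10, n)
            model = stepwise_cox(X, times, np.ones(n, dtype=bool))
            empties += len(model.covariates) == 0
        # per-seed P(empty) ~ 0.95^4; >= 6 of 10 is the conservative bound
        assert empties >= 6


class TestSimulatedCohortEndToEnd:
    def test_planted_cohort_statistics_recovered(self):
        """n=500, latent rho 0.8, HR 2.5: Spearman > 0.5, log-rank
        p < 0.01 and Cox HR in [1.8, 3.5] in >= 90% of seeds."""
        good = 0
        for seed in range(10):
            cohort, _ = generate_tma_cohort(
                CohortSimConfig(n_patients=500, rho_latent=0.8,
                                hazard_ratio_high=2.5, seed=seed)
            )
            grp = np.where(cohort["ar_category"] > 2, "high", "low")
            rho, _ = spearman(cohort["ar_category"], cohort["cdk11_category"])
            _, _, p = log_rank(grp, cohort["followup_months"], cohort["event"].astype(bool))
            hr = cox_fit(
                pd.DataFrame({"ar_high": (grp == "high").astype(float)}),
                cohort["followup_months"], cohort["event"].astype(bool),
            ).hazard_ratio("ar_high")
            good += (rho > 0.5) and (p < 0.01) and (1.8 <= hr <= 3.5)
        assert good >= 9
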