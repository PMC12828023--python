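"""Development-outcome statistics: rates, survival, log-rank, slope
resampling, wing-length mixed model, group tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from larvadose.devstats import (
    CohortTable,
    asymmetry_test,
    compare_slopes,
    development_rate,
    diet_percent_difference,
    kaplan_meier,
    logrank_test,
    mortality_rate,
    mortality_test,
    ph_check,
    slope_resampling,
    wing_lmm,
)
from larvadose.synthetic import CohortGeneratorSpec, simulate_cohort

warnings.filterwarnings("ignore", module="lifelines")


def records_frame(**cols):
    n = max(len(v) for v in cols.values())
    base = {
        "id": [f"x{i}" for i in range(n)],
        "run": ["r1"] * n,
        "generation": ["G1"] * n,
        "condition": ["LC"] * n,
        "diet": ["T"] * n,
        "pupation_day": [np.nan] * n,
        "emergence_day": [np.nan] * n,
        "death_day": [np.nan] * n,
        "sex": ["F"] * n,
        "wing_left": [np.nan] * n,
        "wing_right": [np.nan] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestElementaryRates:
    def test_reciprocal_values(self):
        assert development_rate(5.0) == pytest.approx(0.2)
        assert development_rate(1.0) == 1.0

    def test_inverse_property(self):
        d = np.random.default_rng(0).uniform(0.5, 30, 50)
        assert np.allclose(development_rate(d) * d, 1.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            development_rate(0.0)

    @pytest.mark.parametrize(
        "deaths,emerg,expected", [(0, 12, 0.0), (3, 47, 0.06), (5, 5, 0.5)]
    )
    def test_mortality_rate(self, deaths, emerg, expected):
        assert mortality_rate(deaths, emerg) == pytest.approx(expected)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            mortality_rate(0, 0)


class TestKaplanMeier:
    def test_no_deaths_survival_is_one(self):
        df = records_frame(emergence_day=[3.0, 4.0, 5.0, 5.0])
        km = kaplan_meier(df)
        assert np.allclose(km.survival, 1.0)

    def test_all_die_same_day_steps_to_zero(self):
        df = records_frame(death_day=[3.0] * 5)
        km = kaplan_meier(df)
        assert km.survival[km.times < 3].size == 0 or np.all(
            km.survival[km.times < 3] == 1.0
        )
        assert km.survival[km.times >= 3][-1] == pytest.approx(0.0)

    def test_hand_worked_six_subject_example(self):
        """Product-limit by hand: death d2 (n=6), censor d3, 2 deaths d4
        (n=4), censor d5, death d6 (n=1)."""
        df = records_frame(
            death_day=[2.0, 4.0, 4.0, 6.0, np.nan, np.nan],
            emergence_day=[np.nan, np.nan, np.nan, np.nan, 3.0, 5.0],
        )
        km = kaplan_meier(df)
        surv = dict(zip(km.times, km.survival))
        assert surv[2.0] == pytest.approx(5 / 6)
        assert surv[4.0] == pytest.approx(5 / 6 * 2 / 4)
        assert surv[6.0] == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(1)
        days = np.ceil(rng.exponential(5, 60)).clip(min=1)
        df = records_frame(death_day=days.astype(float))
        km = kaplan_meier(df)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((days > t).mean(), abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        df = records_frame(pupation_day=[4.0, 5.0, 6.0, 7.0],
                           emergence_day=[6.0, 7.0, 8.0, 9.0])
        res = logrank_test(df, df.copy(), event="pupation")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1.0

    def test_shifted_group_detected(self):
        a = records_frame(pupation_day=[4.0, 5.0, 5.0, 6.0] * 10,
                          emergence_day=[6.0, 7.0, 7.0, 8.0] * 10)
        b = records_frame(pupation_day=[7.0, 8.0, 8.0, 9.0] * 10,
                          emergence_day=[9.0, 10.0, 10.0, 11.0] * 10)
        assert logrank_test(a, b).p_value < 1e-6

    def test_deaths_are_censored_not_events(self):
        a = records_frame(pupation_day=[4.0, 5.0, np.nan, np.nan],
                          death_day=[np.nan, np.nan, 2.0, 3.0])
        b = records_frame(pupation_day=[4.0, 5.0, 6.0, 7.0])
        res = logrank_test(a, b)
        assert np.isfinite(res.statistic)

    def test_no_events_rejected(self):
        df = records_frame(death_day=[2.0, 3.0])
        with pytest.raises(ValueError, match="no observed events"):
            logrank_test(df, df.copy(), event="pupation")


class TestProportionalHazards:
    def test_proportional_hazards_rarely_flagged(self):
        rng = np.random.default_rng(0)
        flags = 0
        reps = 40
        for _ in range(reps):
            a = records_frame(pupation_day=np.ceil(rng.exponential(6, 80)).clip(min=1))
            b = records_frame(pupation_day=np.ceil(rng.exponential(3, 80)).clip(min=1))
            _, reliable = ph_check(a, b)
            flags += not reliable
        assert flags / reps < 0.15

    def test_crossing_hazards_flagged(self):
        rng = np.random.default_rng(1)
        flags = 0
        reps = 15
        for _ in range(reps):
            a = records_frame(pupation_day=np.ceil(rng.uniform(1, 4, 100)))
            b = records_frame(pupation_day=np.concatenate(
                [np.ceil(rng.uniform(1, 2, 50)), np.ceil(rng.uniform(8, 12, 50))]
            ))
            _, reliable = ph_check(a, b)
            flags += not reliable
        assert flags / reps > 0.8

    def test_single_event_groups_error(self):
        a = records_frame(pupation_day=[4.0, np.nan], death_day=[np.nan, 2.0])
        with pytest.raises(ValueError, match="too few"):
            ph_check(a, a.copy())


class TestSlopeResampling:
    def test_constant_rates_give_zero_slopes(self):
        s = slope_resampling([0.2] * 5, [28.0, 28.5], [0.2] * 5, [30.0, 30.5],
                             B=500, seed=0)
        assert np.all(s.slopes == 0.0)

    def test_collinear_rates_recover_exact_slope(self):
        b = 0.0123
        t1 = np.array([28.0, 28.2, 28.4])
        t2 = np.array([30.0, 30.3])
        # rates exactly linear in the drawn temperature is only well-defined
        # when each condition's rate support maps its temperatures
        s = slope_resampling(0.1 + b * t1, t1, 0.1 + b * t2, t2, B=2000, seed=1)
        # every draw pairs some r(T) with some T', so slopes vary, but the
        # degenerate single-temperature-per-condition case is exact:
        s2 = slope_resampling([0.1 + b * 28.0], [28.0], [0.1 + b * 30.0], [30.0],
                              B=500, seed=2)
        assert np.allclose(s2.slopes, b)
        assert np.isfinite(s.slopes).all()

    def test_equal_temperature_draws_redrawn(self):
        s = slope_resampling([0.1, 0.2], [28.0, 29.0], [0.3, 0.4], [29.0, 30.0],
                             B=2000, seed=3)
        assert np.all(s.slopes != np.inf)
        assert s.n_redrawn > 0

    def test_degenerate_identical_single_temperature_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            slope_resampling([0.1], [28.0], [0.2], [28.0], B=10, seed=0)

    def test_known_slope_difference_recovered_with_power(self):
        rng = np.random.default_rng(4)
        rejections = 0
        signs = []
        for seed in range(20):
            c = simulate_cohort(CohortGeneratorSpec(
                seed=seed, runs_per_condition=2, larvae_per_run=80,
                exposure_slope_offset=0.008))
            r = np.random.default_rng(seed)
            def pair(c1, c2):
                rates = development_rate(
                    c.subset(c1, "T")["pupation_day"].dropna().to_numpy())
                rates2 = development_rate(
                    c.subset(c2, "T")["pupation_day"].dropna().to_numpy())
                return slope_resampling(rates, c.temperatures[c1],
                                        rates2, c.temperatures[c2], B=4000, seed=r)
            res = compare_slopes(pair("LC", "HC"), pair("LE", "HE"))
            rejections += res.p_value < 0.05
            signs.append(res.statistic)
        assert rejections / 20 > 0.9
        # exposed pair has the steeper slope -> control - exposed < 0
        assert np.mean(np.array(signs) < 0) > 0.9


class TestCompareSlopes:
    def _sample(self, x, B):
        from larvadose.devstats import SlopeSample

        return SlopeSample(slopes=np.asarray(x, float), B=B, n_redrawn=0)

    def test_identical_samples_give_t_zero(self):
        x = np.random.default_rng(0).normal(size=200)
        res = compare_slopes(self._sample(x, 200), self._sample(x.copy(), 200))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_welch_df_near_2B_minus_2_for_equal_variances(self):
        rng = np.random.default_rng(1)
        B = 5000
        res = compare_slopes(self._sample(rng.normal(size=B), B),
                             self._sample(rng.normal(size=B), B))
        assert res.df == pytest.approx(2 * B - 2, rel=0.01)

    def test_df_magnitude_at_hundred_thousand_replicates(self):
        rng = np.random.default_rng(2)
        B = 100_000
        res = compare_slopes(self._sample(rng.normal(size=B), B),
                             self._sample(rng.normal(size=B), B))
        assert res.df == pytest.approx(1.9e5, rel=0.06)

    def test_mismatched_B_rejected(self):
        with pytest.raises(ValueError, match="same replicate count"):
            compare_slopes(self._sample([1.0, 2.0], 2), self._sample([1.0], 1))


class TestWingLMM:
    def test_noise_free_data_recovered_exactly(self):
        spec = CohortGeneratorSpec(
            seed=5, runs_per_condition=2, larvae_per_run=60, mortality=0.0)
        spec.wing_model = dict(spec.wing_model)
        spec.wing_model["run_sd"] = 0.0
        spec.wing_model["residual_sd"] = 1e-9
        cohort = simulate_cohort(spec)
        fit = wing_lmm(cohort, sex="F")
        assert fit.estimate("(Intercept)") == pytest.approx(2992.23, abs=1e-5)
        assert fit.estimate("Food M") == pytest.approx(-386.16, abs=1e-5)
        assert fit.estimate("type HC") == pytest.approx(-82.14, abs=1e-5)
        assert fit.estimate("type LE:Food M") == pytest.approx(-45.02, abs=1e-5)

    def test_matches_mixedlm_reference_fit(self, default_cohort):
        """Cross-check the closed-form REML fit against statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        from larvadose.devstats import _wing_design

        fit = wing_lmm(default_cohort, sex="F")
        long = _wing_design(default_cohort.records, "F")
        md = smf.mixedlm(
            'wing ~ C(condition, Treatment("LC")) * C(diet, Treatment("T"))',
            long, groups=long["run"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = md.fit(reml=True)
        assert fit.estimate("(Intercept)") == pytest.approx(
            ref.params["Intercept"], rel=1e-6)
        assert fit.estimate("Food M") == pytest.approx(
            ref.params['C(diet, Treatment("T"))[T.M]'], rel=1e-6)
        assert fit.residual_sd**2 == pytest.approx(ref.scale, rel=0.02)

    def test_satterthwaite_df_between_and_within(self, default_cohort):
        """Condition contrasts are between-run (df ~ number of runs); diet
        contrasts are within-run (df ~ number of observations)."""
        fit = wing_lmm(default_cohort, sex="F")
        n_runs = fit.n_groups
        assert fit.terms.loc["type HC", "df"] < 3 * n_runs
        assert fit.terms.loc["Food M", "df"] > 10 * n_runs

    def test_interaction_lrt_null_calibration(self):
        """LRT for the interaction block is ~ chi2(3) on data generated
        without interactions."""
        from scipy import stats as ss

        rejections = 0
        reps = 60
        for seed in range(reps):
            spec = CohortGeneratorSpec(
                seed=seed, runs_per_condition=2, larvae_per_run=60)
            spec.wing_model = dict(spec.wing_model)
            spec.wing_model["interaction"] = {}
            cohort = simulate_cohort(spec)
            fit = wing_lmm(cohort, sex="F")
            rejections += fit.lrt_interaction.p_value < 0.05
        rate = rejections / reps
        # binomial 99% envelope around 0.05 at 60 reps
        assert rate <= ss.binom.ppf(0.995, reps, 0.05) / reps + 1e-9

    def test_single_run_rejected(self, small_cohort):
        records = small_cohort.records
        one_run = records[records["run"] == records["run"].iloc[0]]
        with pytest.raises(ValueError, match="2 runs"):
            wing_lmm(CohortTable(records=one_run, temperatures={}))


class TestDietPercent:
    def _fit_with(self, intercept, diet):
        terms = pd.DataFrame(
            {"estimate": [intercept, diet], "se": [1, 1], "t": [0, 0],
             "df": [1, 1], "p": [1, 1]},
            index=["(Intercept)", "Food M"],
        )
        from larvadose.devstats import WingLengthModelFit

        return WingLengthModelFit(terms=terms, run_sd=0, residual_sd=0,
                                  n_obs=0, n_groups=0, loglik_reml=0)

    def test_published_coefficients_round_to_13_percent(self):
        assert diet_percent_difference(self._fit_with(2992.23, -386.16)) == 13

    def test_zero_effect(self):
        assert diet_percent_difference(self._fit_with(3000.0, 0.0)) == 0

    def test_effect_equal_to_intercept(self):
        assert diet_percent_difference(self._fit_with(3000.0, -3000.0)) == 100


class TestGroupTests:
    def test_asymmetry_df_is_groups_minus_one(self, default_cohort):
        res = asymmetry_test(default_cohort.records)
        assert res.df == 7.0
        assert res.test == "kruskal-wallis"

    def test_all_zero_asymmetries_handled(self):
        df = records_frame(
            condition=["LC"] * 4 + ["HC"] * 4,
            wing_left=[2900.0] * 8,
            wing_right=[2900.0] * 8,
        )
        res = asymmetry_test(df)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        df = records_frame(
            condition=["LC"] * 30 + ["HC"] * 30,
            wing_left=np.r_[rng.normal(2900, 10, 30), rng.normal(2900, 10, 30)],
            wing_right=np.r_[rng.normal(2900, 10, 30), rng.normal(3300, 10, 30)],
        )
        assert asymmetry_test(df).p_value < 1e-4

    def test_mortality_df_structure(self, default_cohort):
        res = mortality_test(default_cohort.records)
        assert res.df == 7.0
        assert 0 <= res.p_value <= 1

    def test_mortality_detection_power_rises_with_effect(self):
        def rate_p(mult, seed):
            spec = CohortGeneratorSpec(seed=seed, runs_per_condition=3,
                                       larvae_per_run=80, mortality=0.05)
            c = simulate_cohort(spec)
            df = c.records.copy()
            # double mortality in HE by converting emergences to deaths
            he = df[(df.condition == "HE") & df.emergence_day.notna()]
            flip = he.sample(frac=min(1.0, 0.05 * (mult - 1)), random_state=seed)
            df.loc[flip.index, "death_day"] = df.loc[flip.index, "pupation_day"]
            df.loc[flip.index, ["pupation_day", "emergence_day"]] = np.nan
            return mortality_test(df).p_value

        null_p = [rate_p(1, s) for s in range(6)]
        alt_p = [rate_p(8, s) for s in range(6)]
        assert np.median(alt_p) < np.median(null_p)
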