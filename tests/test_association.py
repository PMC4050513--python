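"""Association models: WLS and NB2 behaviour, battery shape, sensitivity runs."""

import numpy as np
import pandas as pd
import pytest

from genokrige.association import (
    MAIN_COVARIATES,
    ModelSpec,
    build_design,
    fit_negative_binomial,
    fit_weighted_linear,
    sensitivity_analyses,
    association_battery,
)


def toy_frame(n=200, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return pd.DataFrame({"z_x": z, "w": rng.integers(10, 51, n).astype(float)})


class TestWeightedLinear:
    def test_noiseless_slope_recovered_exactly(self):
        df = toy_frame()
        df["y"] = 1.0 + 2.0 * df["z_x"]
        est = fit_weighted_linear(df, ModelSpec("y", "z_x"))
        assert est.estimate == pytest.approx(2.0, abs=1e-10)
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-8)
        assert est.n == len(df)

    def test_equal_weights_match_unweighted_fit(self):
        df = toy_frame()
        rng = np.random.default_rng(1)
        df["y"] = 0.5 * df["z_x"] + rng.standard_normal(len(df))
        df["ones"] = 1.0
        a = fit_weighted_linear(df, ModelSpec("y", "z_x"))
        b = fit_weighted_linear(df, ModelSpec("y", "z_x", weight_col="ones"))
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-12)

    def test_weighting_changes_estimate_under_heteroscedasticity(self):
        rng = np.random.default_rng(2)
        df = toy_frame(500)
        sd = np.sqrt(50.0 / df["w"])
        df["y"] = 0.3 * df["z_x"] + rng.standard_normal(len(df)) * sd
        wls = fit_weighted_linear(df, ModelSpec("y", "z_x", weight_col="w"))
        ols = fit_weighted_linear(df, ModelSpec("y", "z_x"))
        assert wls.ci_high - wls.ci_low <= ols.ci_high - ols.ci_low

    def test_complete_case_count_reported(self):
        df = toy_frame()
        df["y"] = df["z_x"]
        df.loc[:9, "y"] = np.nan
        est = fit_weighted_linear(df, ModelSpec("y", "z_x"))
        assert est.n == len(df) - 10

    def test_too_few_cases_fail(self):
        df = toy_frame(8)
        df["y"] = df["z_x"]
        with pytest.raises(ValueError, match="complete cases"):
            fit_weighted_linear(df, ModelSpec("y", "z_x"))

    def test_rank_deficiency_names_aliased_column(self, small_cohort):
        df = small_cohort.copy()
        df["dup_cov"] = df["z_no2"]
        spec = ModelSpec("ti", "z_formaldehyde", covariates=("z_no2", "dup_cov"))
        with pytest.raises(ValueError, match="dup_cov"):
            fit_weighted_linear(df, spec)

    def test_constant_covariate_dropped_with_warning(self, small_cohort):
        df = small_cohort.copy()
        df["constant_cov"] = 1.0
        spec = ModelSpec("ti", "z_formaldehyde", covariates=("constant_cov",))
        with pytest.warns(UserWarning, match="constant_cov"):
            est = fit_weighted_linear(df, spec)
        assert np.isfinite(est.estimate)


class TestNegativeBinomial:
    def test_null_poisson_counts_rr_near_one(self):
        rng = np.random.default_rng(3)
        df = toy_frame(400)
        df["y"] = rng.poisson(3.0, size=len(df))
        est = fit_negative_binomial(df, ModelSpec("y", "z_x", family="negative-binomial"))
        assert est.ci_low < 1.0 < est.ci_high
        assert est.estimate == pytest.approx(1.0, abs=0.1)

    def test_recovers_rate_ratio_on_nb_counts(self):
        rng = np.random.default_rng(4)
        df = toy_frame(4000, seed=5)
        mu = 4.6 * np.exp(np.log(1.3) * df["z_x"])
        lam = rng.gamma(shape=1 / 0.7, scale=0.7 * mu)
        df["y"] = rng.poisson(lam)
        est = fit_negative_binomial(df, ModelSpec("y", "z_x", family="negative-binomial"))
        assert est.estimate == pytest.approx(1.3, rel=0.05)
        assert est.dispersion == pytest.approx(0.7, rel=0.3)

    def test_nb_ci_wider_than_poisson_on_overdispersed_data(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        df = toy_frame(600, seed=7)
        lam = rng.gamma(shape=1 / 1.0, scale=1.0 * 4.0 * np.ones(len(df)))
        df["y"] = rng.poisson(lam)
        nb = fit_negative_binomial(df, ModelSpec("y", "z_x", family="negative-binomial"))
        X = build_design(df, "z_x")
        poisson = sm.GLM(df["y"].to_numpy(), X, family=sm.families.Poisson()).fit()
        lo, hi = np.exp(poisson.conf_int().loc["z_x"])
        assert (nb.ci_high - nb.ci_low) > (hi - lo)

    def test_poisson_generated_counts_fall_back_towards_poisson(self):
        """As dispersion -> 0 the NB fit reduces to Poisson estimates."""
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        df = toy_frame(2000, seed=9)
        df["y"] = rng.poisson(5.0 * np.exp(0.2 * df["z_x"]))
        est = fit_negative_binomial(df, ModelSpec("y", "z_x", family="negative-binomial"))
        X = build_design(df, "z_x")
        poisson = sm.GLM(df["y"].to_numpy(), X, family=sm.families.Poisson()).fit()
        assert est.estimate == pytest.approx(float(np.exp(poisson.params["z_x"])), abs=1e-3)

    def test_non_integer_and_all_zero_outcomes_rejected(self):
        df = toy_frame(50)
        df["y"] = 0.5
        with pytest.raises(ValueError, match="integer"):
            fit_negative_binomial(df, ModelSpec("y", "z_x", family="negative-binomial"))
        df["y"] = 0
        with pytest.raises(ValueError, match="zero"):
            fit_negative_binomial(df, ModelSpec("y", "z_x", family="negative-binomial"))


class TestBattery:
    def test_battery_has_24_rows_and_expected_layout(self, small_cohort):
        battery = association_battery(small_cohort)
        assert len(battery) == 24
        assert set(battery["specification"]) == {"crude", "adjusted"}
        counts = battery.groupby(["outcome", "pollutant"]).size()
        assert (counts == 2).all() and len(counts) == 12
        assert set(battery.loc[battery.kind == "rr", "outcome"]) == {"mn_count", "bud_count"}

    def test_crude_differs_from_adjusted_under_confounding(self, district):
        """Make a covariate both outcome- and exposure-associated; crude and
        adjusted estimates must then differ."""
        from genokrige.synthetic import OutcomeSpec, generate_cohort, simulate_outcomes
        cohort = generate_cohort(district, n_per_stratum=150, seed=30)
        rng = np.random.default_rng(31)
        z = rng.standard_normal(len(cohort)) + 1.5 * cohort["smoking_parents"].to_numpy()
        cohort["z_formaldehyde"] = (z - z.mean()) / z.std(ddof=1)
        z2 = rng.standard_normal(len(cohort))
        cohort["z_no2"] = (z2 - z2.mean()) / z2.std(ddof=1)
        out = simulate_outcomes(cohort, OutcomeSpec(), seed=32)
        battery = association_battery(out)
        row = battery[(battery.outcome == "ti") & (battery.pollutant == "formaldehyde")]
        crude = row[row.specification == "crude"]["estimate"].iloc[0]
        adjusted = row[row.specification == "adjusted"]["estimate"].iloc[0]
        assert abs(crude - adjusted) > 1e-4

    def test_individual_failure_recorded_not_raised(self, small_cohort):
        broken = small_cohort.copy()
        broken["mn_count"] = 0
        battery = association_battery(broken)
        failed = battery[battery.outcome == "mn_count"]
        assert failed["estimate"].isna().all()
        assert failed["note"].str.contains("failed").all()
        assert len(battery) == 24


class TestSensitivity:
    def test_indoor_battery_excludes_movers(self, small_cohort, district):
        sens = sensitivity_analyses(small_cohort, district)
        n_non_movers = int((small_cohort["mover"] == 0).sum())
        adj = sens["indoor_adjusted"].query("specification == 'adjusted'")
        assert (adj["n"] <= n_non_movers).all()

    def test_near_industry_subset_size_matches_distance_rule(self, small_cohort, district):
        from genokrige.exposure import factory_distances
        sens = sensitivity_analyses(small_cohort, district)
        d_chip, _ = factory_distances(small_cohort[["x_km", "y_km"]].to_numpy(), district)
        assert sens["near_industry_n"] == int((d_chip < 4.0).sum())

    def test_constant_indoor_indicators_reproduce_main_estimates(self, small_cohort, district):
        frozen = small_cohort.copy()
        frozen["mover"] = 0
        frozen["house_new"] = 0
        frozen["furniture_age"] = pd.Categorical(
            ["ge3y"] * len(frozen), categories=["none", "lt3y", "ge3y"])
        frozen["double_glazing"] = 1
        main = association_battery(frozen).query("specification == 'adjusted' and outcome == 'ti'")
        sens = sensitivity_analyses(frozen, district)["indoor_adjusted"]
        sens_ti = sens.query("specification == 'adjusted' and outcome == 'ti'")
        assert np.allclose(main["estimate"].to_numpy(), sens_ti["estimate"].to_numpy(), atol=1e-8)
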