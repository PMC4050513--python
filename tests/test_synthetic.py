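"""The synthetic district generator: fields, campaigns, cohort, outcomes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from genokrige.exposure import STRATA, distance_strata, factory_distances
from genokrige.synthetic import (
    DistrictSpec,
    GaussianFieldSimulator,
    OutcomeSpec,
    PollutantFieldSpec,
    generate_cohort,
    generate_pollution_field,
    grid_axes,
    industry_kernel,
    simulate_campaign_measurements,
    simulate_outcomes,
)
from genokrige.variogram import VariogramModel, empirical_variogram, fit_variogram


class TestDistrict:
    def test_defaults_are_valid(self, district):
        assert district.extent == (20.0, 30.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            DistrictSpec(extent=(0.0, 30.0))
        with pytest.raises(ValueError):
            DistrictSpec(chipboard_industries=((25.0, 5.0),))
        with pytest.raises(ValueError):
            DistrictSpec(chipboard_industries=())


class TestPollutionField:
    def test_zero_variance_field_is_constant_at_mean(self, district):
        spec = PollutantFieldSpec(
            name="flat", mean=2.5, warm_mean=2.5, cold_mean=2.5,
            variogram=VariogramModel("exponential", nugget=0.0, sill=0.0, range_=1.0),
        )
        surf = generate_pollution_field(spec, district, grid_resolution_km=2.0, seed=0)
        assert np.allclose(surf.values, 2.5)

    def test_fixed_seed_fixes_every_value(self, district):
        spec = PollutantFieldSpec.formaldehyde()
        a = generate_pollution_field(spec, district, grid_resolution_km=1.0, seed=5)
        b = generate_pollution_field(spec, district, grid_resolution_km=1.0, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_all_concentrations_positive(self, district):
        spec = PollutantFieldSpec.no2()
        surf = generate_pollution_field(spec, district, grid_resolution_km=1.0, seed=2)
        assert (surf.values > 0).all()

    def test_hotspot_kernel_peaks_at_southwest_industry(self, district):
        """The deterministic hot-spot component is largest at the stronger
        (south-western) chipboard industry, echoing the district's widest
        observed hot spot; the ensemble-mean surface inherits this peak."""
        spec = dataclasses.replace(PollutantFieldSpec.formaldehyde(),
                                   bump_amplitude=(0.3, 0.0),
                                   small_factory_fraction=0.0)
        x, y = grid_axes(district, 0.5)
        xx, yy = np.meshgrid(x, y)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        k = industry_kernel(spec, district, pts)
        peak = pts[np.argmax(k)]
        sw = np.asarray(district.chipboard_industries[0])
        assert np.hypot(*(peak - sw)) < 2.0
        # ensemble mean over replicates approaches mean + kernel
        sim = GaussianFieldSimulator(spec.variogram, x, y)
        rng = np.random.default_rng(0)
        mean_surf = np.mean([
            generate_pollution_field(spec, district, seed=rng, simulator=sim).values
            for _ in range(80)
        ], axis=0)
        peak_mean = pts[np.argmax(mean_surf.ravel())]
        assert np.hypot(*(peak_mean - sw)) < 2.0

    def test_generated_field_recovers_generator_range(self, district):
        """Fitted exponential range over replicates brackets the truth 3.5 km."""
        spec = dataclasses.replace(PollutantFieldSpec.formaldehyde(), bump_amplitude=0.0)
        x, y = grid_axes(district, 0.5)
        sim = GaussianFieldSimulator(spec.variogram, x, y)
        rng = np.random.default_rng(4)
        sites = np.column_stack([rng.uniform(0, 20, 62), rng.uniform(0, 30, 62)])
        fitted = []
        for _ in range(25):
            surf = generate_pollution_field(spec, district, seed=rng, simulator=sim)
            vals = surf.at(sites)
            emp = empirical_variogram(sites, vals, angle=90.0, ratio=0.5)
            fitted.append(fit_variogram(emp, "exponential", angle=90.0, ratio=0.5).range_)
        assert 2.0 <= np.median(fitted) <= 5.5

    def test_cholesky_node_cap_enforced(self, district):
        spec = PollutantFieldSpec.formaldehyde()
        with pytest.raises(ValueError, match="spectral"):
            GaussianFieldSimulator(spec.variogram, np.arange(0, 20, 0.1),
                                   np.arange(0, 30, 0.1), method="cholesky", node_cap=500)

    def test_spectral_and_cholesky_agree_in_law(self, district):
        """Same covariance target: variances of many draws agree between methods."""
        m = VariogramModel("exponential", nugget=0.0, sill=1.0, range_=3.0)
        x, y = np.arange(0, 10.5, 0.5), np.arange(0, 10.5, 0.5)
        rng = np.random.default_rng(1)
        sim_c = GaussianFieldSimulator(m, x, y, method="cholesky")
        sim_s = GaussianFieldSimulator(m, x, y, method="spectral")
        var_c = np.var([sim_c.draw(rng) for _ in range(60)])
        var_s = np.var([sim_s.draw(rng) for _ in range(60)])
        assert var_c == pytest.approx(1.0, rel=0.15)
        assert var_s == pytest.approx(1.0, rel=0.15)


class TestCampaigns:
    @pytest.fixture(scope="class")
    def surf(self, district):
        return generate_pollution_field(PollutantFieldSpec.formaldehyde(), district,
                                        grid_resolution_km=1.0, seed=9)

    def test_noiseless_zero_offset_measurements_equal_truth(self, district, surf):
        spec = dataclasses.replace(PollutantFieldSpec.formaldehyde(),
                                   warm_mean=2.5, cold_mean=2.5, noise_sd=0.0)
        sites = np.array([[5.0, 5.0], [10.0, 20.0]])
        meas = simulate_campaign_measurements(surf, sites, spec, seed=0)
        wide = meas.pivot_table(index="site_id", columns="campaign", values="conc_ugm3")
        assert np.allclose(wide.to_numpy(), surf.at(sites)[:, None])

    def test_formaldehyde_warm_exceeds_cold_every_replicate(self, district, surf):
        spec = PollutantFieldSpec.formaldehyde()
        sites = np.column_stack([np.linspace(1, 19, 20), np.linspace(1, 29, 20)])
        for seed in range(5):
            meas = simulate_campaign_measurements(surf, sites, spec, seed=seed)
            grp = meas.groupby("season")["conc_ugm3"].mean()
            assert grp["warm"] > grp["cold"]

    def test_no2_cold_exceeds_warm(self, district):
        spec = PollutantFieldSpec.no2()
        surf = generate_pollution_field(spec, district, grid_resolution_km=1.0, seed=3)
        sites = np.column_stack([np.linspace(1, 19, 20), np.linspace(1, 29, 20)])
        meas = simulate_campaign_measurements(surf, sites, spec, seed=1)
        grp = meas.groupby("season")["conc_ugm3"].mean()
        assert grp["cold"] > grp["warm"]

    def test_missingness_never_leaves_no_complete_site(self, district, surf):
        spec = PollutantFieldSpec.formaldehyde()
        sites = np.column_stack([np.linspace(1, 19, 8), np.linspace(1, 29, 8)])
        for seed in range(10):
            meas = simulate_campaign_measurements(surf, sites, spec,
                                                  missing_rate=0.4, seed=seed)
            per_site = meas.groupby("site_id")["campaign"].count()
            assert (per_site == 4).any()          # an anchor site exists
            assert per_site.min() >= 1            # nobody fully lost
        with pytest.raises(ValueError):
            simulate_campaign_measurements(surf, sites, spec, missing_rate=1.0)

    def test_campaign_offsets_are_centred(self):
        for spec in (PollutantFieldSpec.formaldehyde(), PollutantFieldSpec.no2()):
            assert spec.campaign_offsets().sum() == pytest.approx(0.0, abs=1e-12)


class TestCohort:
    def test_one_child_per_stratum_satisfies_distances(self, district):
        cohort = generate_cohort(district, n_per_stratum=1, seed=0)
        assert len(cohort) == 3
        labels = distance_strata(cohort[["x_km", "y_km"]].to_numpy(), district)
        assert list(labels) == list(cohort["stratum"])
        assert set(labels) == set(STRATA)

    def test_near_stratum_children_all_within_2km_of_chipboard(self, district):
        cohort = generate_cohort(district, n_per_stratum=150, seed=1)
        near = cohort[cohort["stratum"] == "chipboard_lt2km"]
        d_chip, _ = factory_distances(near[["x_km", "y_km"]].to_numpy(), district)
        assert (d_chip < 2.0).all()

    def test_female_fraction_within_binomial_bounds(self, district):
        cohort = generate_cohort(district, n_per_stratum=250, seed=3)
        n = len(cohort)
        p_hat = cohort["female"].mean()
        half_width = 2.576 * np.sqrt(0.44 * 0.56 / n)   # binomial 99% band
        assert abs(p_hat - 0.44) < half_width + 1e-12

    def test_reproducible_to_the_byte(self, district):
        a = generate_cohort(district, n_per_stratum=40, seed=5)
        b = generate_cohort(district, n_per_stratum=40, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_stratum_geometry_diagnosed(self):
        # a district too small for any point to be >= 4 km from the factories
        district = DistrictSpec(extent=(4.0, 4.0),
                                chipboard_industries=((2.0, 2.0),),
                                small_factories=((2.0, 2.0),))
        with pytest.raises(ValueError, match="region appears empty"):
            generate_cohort(district, n_per_stratum=5, seed=0)

    def test_bad_category_frequencies_rejected(self, district):
        freqs = {"collector": {"parents": 0.5, "parents_assisted": 0.2,
                               "health_personnel": 0.1}}
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(district, n_per_stratum=5, covariate_freqs=freqs, seed=0)


class TestOutcomes:
    @pytest.fixture(scope="class")
    def exposed(self, district):
        cohort = generate_cohort(district, n_per_stratum=400, seed=21)
        rng = np.random.default_rng(22)
        for col in ("z_formaldehyde", "z_no2"):
            z = rng.standard_normal(len(cohort))
            cohort[col] = (z - z.mean()) / z.std(ddof=1)
        return cohort

    def test_no_effects_no_residual_gives_constant_ti(self, exposed):
        spec = OutcomeSpec(ti_sd=1e-6, slopes={}, rate_ratios={}, covariate_effects={})
        out = simulate_outcomes(exposed, spec, seed=0)
        assert out["ti"].std() < 1e-5
        assert out["ti"].mean() == pytest.approx(3.25, abs=1e-5)

    def test_marginal_moments_match_spec(self, exposed):
        out = simulate_outcomes(exposed, OutcomeSpec(), seed=1)
        n = len(out)
        assert out["ti"].mean() == pytest.approx(3.25, abs=4 * 0.88 / np.sqrt(n))
        assert out["ti"].std() == pytest.approx(0.88, rel=0.1)
        assert out["bn_pct"].mean() == pytest.approx(1.83, abs=4 * 0.64 / np.sqrt(n))
        assert out["tm"].std() == pytest.approx(0.05, rel=0.1)
        # count markers: means at 0.12% and 0.23% of 2,000 cells
        assert out["mn_count"].mean() == pytest.approx(2.4, rel=0.2)
        assert out["bud_count"].mean() == pytest.approx(4.6, rel=0.2)

    def test_bud_counts_are_overdispersed_with_cv_near_one(self, exposed):
        out = simulate_outcomes(exposed, OutcomeSpec(), seed=2)
        cv = out["bud_pct"].std() / out["bud_pct"].mean()
        assert 0.75 < cv < 1.3
        assert out["bud_count"].var() > 1.5 * out["bud_count"].mean()

    def test_counts_integer_in_range_and_percentages_valid(self, exposed):
        out = simulate_outcomes(exposed, OutcomeSpec(), seed=3)
        for col in ("mn_count", "bud_count"):
            assert np.issubdtype(out[col].dtype, np.integer)
            assert out[col].between(0, 2000).all()
        assert out["cells_examined"].between(10, 50).all()
        assert out["ti"].between(0, 100).all()
        assert out["bn_pct"].between(0, 100).all()

    def test_inconsistent_spec_rejected(self, exposed):
        spec = OutcomeSpec(ti_sd=0.01, slopes={("ti", "formaldehyde"): 5.0})
        with pytest.raises(ValueError, match="inconsistent OutcomeSpec"):
            simulate_outcomes(exposed, spec, seed=0)

    def test_missing_exposures_rejected(self, district):
        cohort = generate_cohort(district, n_per_stratum=3, seed=0)
        with pytest.raises(ValueError, match="z_formaldehyde"):
            simulate_outcomes(cohort, OutcomeSpec(), seed=0)
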