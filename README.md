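# genokrige

Semi-ecological analysis of industrial air pollution and early genotoxic
damage: passive-sampler exposure surfaces by ordinary kriging, and per-1-SD
associations with comet-assay and micronucleus biomarkers in children.

The package is aimed at environmental-epidemiology analysts who need the full
chain from a handful of short monitoring campaigns to adjusted biomarker
effect estimates — and at methodologists who want to stress-test that chain on
synthetic districts where the truth is known.  It models a wood-industry
district in which two large chipboard plants (plus a scatter of small wood
factories) emit formaldehyde and NO₂; children's residential exposure is
interpolated from 62 passive-sampler sites and related to DNA strand breaks
(comet assay: tail intensity TI, tail length TL, tail moment TM) and fixed
chromosomal damage (micronucleus assay: binucleated cells BN, micronuclei MN,
nuclear buds, per 2,000 buccal cells).

## What it computes

1. **Monitoring-network design** — sites at the medoids of equal-sized
   clusters of residences (balanced partitioning around medoids; the balanced
   assignment is solved exactly as a transportation problem), with half the
   sites constrained to a 3-km radius of the chipboard industries.
2. **Temporal adjustment** — four one-week campaigns (2 warm, 2 cold) are
   converted to annual site means by the difference method: over complete
   sites, campaign means `A_c` and their grand mean `Ā` give corrections
   `Δ_c = A_c − Ā` subtracted from every measurement.
3. **Geostatistics** — Matheron empirical variograms; exponential, spherical,
   Gaussian and nugget models `γ(h) = c₀ + c·g(h′/a)` with geometric
   anisotropy `h′ = ‖R(θ)S(ρ)h‖`; weighted-least-squares fitting with Cressie
   weights `N(h)/γ(h)²`; ordinary kriging
   `[Γ 1; 1ᵀ 0][w; μ] = [γ₀; 1]`, prediction `wᵀz`, variance `wᵀγ₀ + μ`;
   model selection by leave-one-out cross-validated RMSE.
4. **Exposure assignment** — direct point kriging at each residence,
   standardised to per-1-SD units (sample SD), plus the <2 km / <4 km / ≥4 km
   distance strata.
5. **Association models** — weighted linear regression for TI/TL/TM (weights ∝
   cells examined) and BN, NB2 negative-binomial regression (`Var = μ + αμ²`,
   log link, `RR = e^β`) for MN and bud counts, each crude and adjusted for
   eleven questionnaire covariates; a 6 × 2 × 2 "battery" report and two
   sensitivity analyses (extra indoor-air covariates without movers; the
   subset living <4 km from a chipboard industry).
6. **Synthetic district generator** — Gaussian random fields with the target
   variogram (dense Cholesky or circulant embedding), deterministic hot-spot
   kernels at the industries, seasonal campaign offsets with missingness, a
   three-stratum cohort with survey-like covariate frequencies, and outcome
   models whose per-1-SD effects are configurable generative truth.

## Worked example

```python
from genokrige import (DistrictSpec, PollutantFieldSpec, generate_pollution_field,
                       generate_cohort, stratified_site_split, simulate_campaign_measurements,
                       campaign_corrections, annual_site_means, select_model,
                       OrdinaryKriging, assign_exposure, simulate_outcomes, association_battery)

district = DistrictSpec()                      # 20 x 30 km, 2 chipboard industries
cohort = generate_cohort(district, n_per_stratum=150, seed=1)
plan = stratified_site_split(cohort[["x_km", "y_km"]].to_numpy(),
                             district.chipboard_industries, k=62)

for spec in (PollutantFieldSpec.formaldehyde(), PollutantFieldSpec.no2()):
    surface = generate_pollution_field(spec, district, grid_resolution_km=0.5, seed=2)
    meas = simulate_campaign_measurements(surface, plan.medoids, spec,
                                          missing_rate=0.15, seed=3)
    annual = annual_site_means(meas, campaign_corrections(meas)).annual
    model, board = select_model(plan.medoids, annual.annual_ugm3.to_numpy(),
                                angles=(90.0, 135.0), ratios=(1.0, 0.5))
    ok = OrdinaryKriging(model).fit(plan.medoids, annual.annual_ugm3.to_numpy())
    cohort, assignment = assign_exposure(ok, cohort, spec.name)
    print(f"{spec.name}: annual {annual.annual_ugm3.mean():.1f} ug/m3 at 62 sites; "
          f"{model.family} variogram (range {model.range_:.1f} km, "
          f"LOOCV-RMSE {board.loc[0, 'loocv_rmse']:.3g}); cohort 1-SD {assignment.sd:.2f}")

analysis = simulate_outcomes(cohort, seed=4)
battery = association_battery(analysis)
row = battery.query("outcome == 'bud_count' and pollutant == 'no2' "
                    "and specification == 'adjusted'").iloc[0]
print(f"nuclear buds, adjusted RR per 1-SD NO2: "
      f"{row.estimate:.2f} ({row.ci_low:.2f}, {row.ci_high:.2f})")
```

Output:

```
formaldehyde: annual 2.4 ug/m3 at 62 sites; exponential variogram (range 3.1 km, LOOCV-RMSE 0.238); cohort 1-SD 0.20
no2: annual 15.3 ug/m3 at 62 sites; exponential variogram (range 16.2 km, LOOCV-RMSE 2.14); cohort 1-SD 2.14
nuclear buds, adjusted RR per 1-SD NO2: 1.22 (1.11, 1.34)
```

Reading it: the temporally adjusted annual means sit near the generator's
district means (2.5 and 16.0 µg/m³); LOOCV selects the exponential family for
both pollutants; the standard deviations of the assigned exposures (0.20 and
2.14 µg/m³) define the "per 1-SD" unit of every effect; and in this single
replicate the adjusted negative-binomial model estimates a 22% (11%, 34%)
relative increase in nuclear-bud counts per 1-SD NO₂ against a generative
truth of 16%.

The same chain runs from the shell (`genokrige run --config config.yaml --out
rundir`, or stage by stage via `genokrige design | adjust | krige | assign |
associate`); each run writes CSV artefacts, a markdown report and a manifest
with per-stage digests that reproduce exactly under a fixed seed.

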