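# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Study design being modelled

A semi-ecological design: individual outcomes and questionnaire covariates,
with exposure assigned from a modelled surface rather than personal
measurements.  Children are sampled from three residence strata — within 2 km
of a chipboard industry, within 4 km of a small wood factory (but ≥ 2 km from
the chipboard plants), and ≥ 4 km from any factory — and each child receives
the kriged annual mean formaldehyde and NO₂ concentration at their home
address.  Effects are reported per 1 SD of the assigned exposure
distribution, which makes the two pollutants comparable despite very
different concentration scales.

A child 2–4 km from a chipboard industry but far from any small factory is
classified "far" under the strict reading of the three labels; a flag
(`treat_chipboard_as_small`) moves such children to the middle stratum
instead.  The default keeps the strict reading because the middle stratum is
defined by small-factory proximity.

## Monitoring-network design

Sites are medoids of equal-sized clusters of candidate residences, so sampler
density follows population density.  The balanced variant of partitioning
around medoids alternates (i) an **exact** balanced assignment — cluster sizes
constrained to ⌊n/k⌋ or ⌈n/k⌉, solved as one linear-sum-assignment problem on
an expanded slot matrix with dummy rows absorbing the unused "extra" slots —
and (ii) a medoid update (the in-cluster point minimising summed distance).
Both steps are non-increasing in the total point-to-medoid distance, so the
objective is monotone and the loop terminates.

Two determinism decisions:

* **Initialisation is deterministic**, a farthest-point spread anchored at
  coordinate-ranked points, with all ties broken by lexicographic coordinate
  order.  A randomised (seeded) init cannot make the medoid set invariant to
  the input row order, and row-order invariance is the more valuable
  property for a reproducible design tool; `random_state` is accepted for
  scikit-learn compatibility but does not affect the result.
* Alternating schemes stop at local optima, so the fit restarts from up to
  `n_restarts` (default 10) anchors and keeps the best objective.  When
  C(n, k) ≤ 1000 the solver instead enumerates all medoid sets; the best
  optimal balanced assignment followed by one medoid update provably attains
  the balanced-partition optimum, which is what the enumeration tests check.

The stratified design runs the solver separately inside and outside a 3-km
radius of the chipboard industries, by default placing ⌈k/2⌉ of the 62 sites
inside.

## Temporal adjustment (difference method)

Week-long campaigns are biased by season.  Over the sites with all four
campaigns measured, the campaign means `A_c` and their grand mean `Ā` give
corrections `Δ_c = A_c − Ā`; each measurement is adjusted by `y − Δ_c` and
averaged per site.  Computing `A_c` **over complete sites only** keeps `A_c`
and `Ā` on the same site set, which guarantees `Σ_c Δ_c = 0` and hence the
identity that a complete site's adjusted annual mean equals its raw
four-campaign mean (tested to 1e-12).  Negative adjusted concentrations are
clipped to zero and counted — physically impossible values can arise when a
correction exceeds a small measurement.

## Variograms and kriging

The semivariogram is parameterised by nugget c₀ (micro-scale plus measurement
variance), partial sill c, and range a, with the **range taken as the
exponential distance parameter** in `γ(h) = c₀ + c(1 − e^(−h/a))` — the
convention of the geostatistical software family this workflow mirrors — not
the practical range (~3a).  This matters: the reported formaldehyde range of
3.5 km implies correlation decaying to 5% only at ~10.5 km.

Geometric anisotropy rotates the lag into (major, minor) axes (angle in
degrees clockwise from north, so 90° = east) and divides the minor component
by the ratio ρ ∈ (0, 1].  Only the angle of maximum continuity is ever
reported for the district surfaces; ρ is therefore profiled over a small grid
{1, 0.7, 0.5} during model selection rather than optimised continuously.

Empirical variograms use the Matheron estimator in equal-width bins up to
half the maximum pairwise site separation (default 12 bins, bins with < 5
pairs flagged); each bin is represented by its **mean pair separation**, not
the bin centre, which removes a first-bin bias when short-range pairs are
scarce.  Fitting is bounded multi-start least squares on (c₀, c, a) with
Cressie weights `N(h)/γ_model(h)²`; fixed short- and mid-range starting
values are included because the objective is multimodal in the range.

Ordinary kriging is global (all sites; n is a few dozen, so no moving
neighbourhood), solved from the augmented system with an LU factorisation
shared across query points.  Duplicate-coordinate sites are averaged first.
Predictions at data sites are exact when c₀ = 0.  LOOCV-RMSE is computed with
the algebraic shortcut `e_i = b_i / (A⁻¹)_ii`, `b = A⁻¹[z; 0]`, which is
identical to refitting each fold (the refit implementation is retained as the
test oracle).  Model selection fits every (family, θ, ρ) candidate, ranks by
LOOCV-RMSE, and breaks ties by fewer parameters then smaller range.

NO₂'s nugget is not reported anywhere and is taken as 0.

## Exposure assignment

Exposure is the kriged prediction **at the residence coordinates** (point
kriging), not an interpolation of an exported grid.  Standardisation uses the
sample (n−1) SD — the convention of mainstream statistical software — and the
cohort mean/SD are recorded so `z·SD + mean` round-trips exactly.  Residences
outside the bounding box of the monitoring sites (plus a 1-km margin) are
flagged as extrapolations.

## Association models

* **Gaussian markers** (TI, TL, TM, BN): weighted least squares.  Comet
  markers are weighted by the number of cells examined, normalised to mean 1
  so the weighted n equals the nominal n; BN uses unit weights.  Wald 95% CIs
  with the t reference.
* **Count markers** (MN, nuclear buds per 2,000 cells): NB2 negative binomial
  (`Var = μ + αμ²`, log link), dispersion estimated by ML, effects reported
  as `RR = e^β` with the Wald CI exponentiated from the log scale.  When the
  dispersion estimate collapses to the zero boundary or the NB likelihood
  fails, the fit falls back to Poisson with a recorded note — for MN-like
  rates (α ≈ 0.08 at mean count 2.4) this is expected behaviour, not an
  error.

Covariates: sex, age (continuous), nationality, parents' education (4
levels), parental smoking, smoking at home, air-refreshing time (3 levels),
traffic, orthodontic appliance, DMFT ≥ 1, and sample collector (3 levels);
categorical covariates are reference-coded against their first level.
Complete-case deletion with the analysis n reported per model.  Covariate
columns that are constant in the analysis sample are dropped with a warning
(they carry no information); genuine collinearity raises an error naming the
aliased columns.  No multiple-testing adjustment is applied, matching the
5%-level convention of the reporting format; the battery therefore expects
~5% false-positive flags under a null generator, and that is tested.  No
offset term is used in the count models (all subjects are scored on 2,000
cells); an offset hook exists via the covariate list.

Sensitivity analyses: (a) adding house age, bedroom-furniture age and double
glazing, after excluding movers (those indicators describe the earlier home);
(b) restricting to children within 4 km of a chipboard industry.

## The synthetic district generator

The generator's purpose is closure testing: every quantity the pipeline
estimates exists in the generator as a known parameter.

* **True surfaces**: district mean + deterministic hot-spot kernels
  (exponential decay, e-folding 1.5 km) at the industries + a zero-mean
  stationary Gaussian field with the target variogram.  The south-western
  chipboard plant carries the larger kernel amplitude (0.3 vs 0.2 µg/m³
  formaldehyde; 2.5 vs 1.8 µg/m³ NO₂), reproducing the qualitative pattern
  of the widest hot spot sitting in the south-west.  Fields are drawn by
  dense Cholesky factorisation (factor cached for replicate studies) up to a
  configurable node cap, and by circulant embedding (FFT) beyond it; the
  embedding clips negative spectral mass and warns if it exceeds 0.1%.
  Nugget variance enters as independent micro-scale noise.  Nonpositive
  concentrations trigger a bounded redraw.
* **Variogram truths**: formaldehyde exponential c₀ = 0.01, c = 0.12,
  a = 3.5 km, θ = 90°; NO₂ exponential c₀ = 0, c = 10, a = 4 km, θ = 135°.
  The anisotropy ratio of the real surfaces is unknown; full-district
  simulation defaults to ρ = 0.5 so that anisotropy handling is exercised.
* **Campaigns**: seasonal means (formaldehyde 2.8 warm / 2.1 cold µg/m³; NO₂
  12.9 / 18.8) enter as zero-centred offsets, so a complete site's raw
  4-campaign mean is unbiased for its annual value; measurement noise SDs
  are 0.05 and 0.8 µg/m³; missingness is site-by-campaign Bernoulli,
  redrawn (bounded) until at least one complete site remains and no site
  loses all campaigns.
* **Cohort**: residences uniform within each stratum (rejection sampling,
  with a geometry diagnostic if a stratum region is empty); age uniform on
  6–12 years; covariates independent with survey-like frequencies (female
  0.44, smoking parents 0.29, DMFT ≥ 1 0.45, high traffic 0.60, ...).
* **Outcomes**: Gaussian markers are mean + Σ(slope × z-exposure) +
  mean-centred covariate terms + residual, with the residual variance chosen
  so the *marginal* SD matches the target (TI 3.25 ± 0.88%, TL 11.69 ± 2.11
  µm, TM 0.20 ± 0.05, BN 1.83 ± 0.64%); comet residuals are scaled by
  √(50/cells examined), which is exactly what justifies the cells-examined
  weighting at analysis time.  Counts are Gamma–Poisson (NB2) with log-link
  effects; baselines 0.12% (MN) and 0.23% (buds) of 2,000 cells, with
  dispersions α = 0.08 and 0.70 — the bud value chosen so the marginal CV of
  the bud frequency lands near 1.0.  Default effect truths: TI +0.13%/SD
  and TM +0.007/SD formaldehyde, BN +0.13%/SD NO₂, bud RR 1.12/SD
  formaldehyde and 1.16/SD NO₂.  Covariate coefficients are not identified
  by any reported analysis, so defaults are small fixed values (e.g. +0.10
  outcome-SD for parental smoking) — mild, adjustable confounding.
* **What it does not emulate**: real geography (coordinates are an abstract
  plane; distances Euclidean), spatially varying covariates beyond the
  strata, exposure measurement error in the outcome model (outcomes are
  generated from the *assigned* standardised exposures, so recovery studies
  test estimation bias, not attenuation from kriging error), nonresponse,
  within-child repeated measures, and correlation between the two
  pollutants' exposures in the recovery harness (drawn independent, which
  keeps single-pollutant models unbiased).  Passing closure tests therefore
  demonstrates correctness of the estimation machinery under the generator's
  assumptions, not robustness to violations of them.

## Calibration studies (problem sizes and protocols)

* **Effect recovery**: 500 replicates per headline effect at n = 310 (comet)
  or n = 374 (micronucleus) — the complete-case sizes of the adjusted
  analyses — with exposures drawn as independent standard normals and
  re-standardised.  Slopes are summarised by the mean, rate ratios by the
  geometric mean; acceptance requires < 10% bias.
* **Variogram recovery**: 200 fields from the reported formaldehyde model
  taken as a self-contained *isotropic* truth (a direction is printed but no
  ratio, so the calibration does not invent one), on a 0.25-km grid via
  circulant embedding, sampled at 62 designed sites with 0.05 µg/m³ noise.
  The fit uses a lag cutoff of one third of the maximum pairwise separation —
  the classic geostatistical cutoff — because beyond that the variogram is
  flat and carries no shape information; the median fitted range and the
  LOOCV family-selection tally are reported.  Variogram estimation from 62
  regularised (medoid-spread) sites is intrinsically noisy; individual fitted
  ranges spread widely even though the median is stable, and the tests bound
  the median, not single fits.
* **Type-I error**: 200 replicates of the full 24-model battery under a null
  generator (all exposure effects zero, covariate effects retained); the
  flagged fraction at p < 0.05 is required to lie in [0.03, 0.07] — the band
  is wider than binomial because the 24 tests per replicate are correlated.

## Pipeline and reproducibility

One YAML config (seed mandatory, schema-validated before any stage runs)
drives generate → design → adjust → krige → assign → associate → report.  The
global seed expands into fixed per-stage substreams keyed by stage name, so
inserting a stage does not shift the randomness of the others.  Every stage
writes plain-text artefacts (CSV/JSON/markdown) and the manifest records
config hash, per-file SHA-256 digests and wall times; a rerun with the same
config and seed reproduces identical digests, and that is tested end to end.

## Known limitations

* The balanced k-medoids heuristic is exact only below the enumeration
  threshold; above it, multi-restart alternation gives good but not certified
  optima.
* Kriging variance is the model-based variance; it ignores variogram
  estimation uncertainty.
* The association models treat assigned exposure as fixed; no
  measurement-error correction for kriging uncertainty is attempted.
* The difference-method adjustment assumes campaign effects are additive and
  shared across sites; multiplicative seasonal structure would call for the
  ratio variant, which is out of scope.
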