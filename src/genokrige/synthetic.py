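"""Synthetic district generator: pollutant fields, campaigns, cohort, outcomes.

This module builds a district with the statistical structure the downstream
analysis assumes, so every stage can be exercised without any external data:

* a rectangular planar district with two chipboard industries in the south and
  a scatter of small wood factories;
* per pollutant, a latent annual-mean surface = overall mean + deterministic
  exponential-decay hot-spot kernels around the industries + a stationary
  (anisotropic) Gaussian random field whose variogram matches the target model;
* four one-week monitoring campaigns (two warm, two cold) with zero-centred
  seasonal offsets, measurement noise and site-by-campaign missingness;
* a three-stratum cohort of children with questionnaire covariates drawn at
  survey-like frequencies;
* genotoxicity outcomes: Gaussian comet markers (tail intensity/length/moment,
  heteroscedastic in the number of cells examined) and binucleated-cell
  frequency, plus negative-binomial micronucleus and nuclear-bud counts per
  2,000 cells, with per-1-SD exposure effects as generative truth.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.distance import cdist

from .exposure import STRATA, distance_strata
from .variogram import VariogramModel

__all__ = [
    "DistrictSpec",
    "PollutantFieldSpec",
    "OutcomeSpec",
    "ExposureSurface",
    "GaussianFieldSimulator",
    "generate_pollution_field",
    "simulate_campaign_measurements",
    "generate_cohort",
    "simulate_outcomes",
    "default_covariate_freqs",
    "write_truth_json",
]

SEASONS = ("warm", "warm", "cold", "cold")   # campaigns 1-4


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# district geometry
# ---------------------------------------------------------------------------

@dataclass
class DistrictSpec:
    """Abstract rectangular district in planar km (origin at the SW corner)."""

    extent: tuple[float, float] = (20.0, 30.0)
    chipboard_industries: tuple = ((5.5, 6.0), (14.0, 7.0))
    small_factories: tuple = (
        (3.0, 10.0), (7.5, 9.0), (10.5, 12.0), (15.0, 11.5),
        (6.0, 14.5), (11.0, 16.0), (16.5, 5.0), (9.0, 3.5),
    )
    chipboard_radius_km: float = 2.0
    small_radius_km: float = 4.0

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("district extent must have strictly positive area")
        for pt in list(self.chipboard_industries) + list(self.small_factories):
            if not (0 <= pt[0] <= w and 0 <= pt[1] <= h):
                raise ValueError(f"industry point {pt} lies outside the extent {self.extent}")
        if not self.chipboard_industries:
            raise ValueError("at least one chipboard industry is required")

    @property
    def all_factories(self) -> np.ndarray:
        return np.asarray(list(self.chipboard_industries) + list(self.small_factories), dtype=float)


# ---------------------------------------------------------------------------
# pollutant fields
# ---------------------------------------------------------------------------

@dataclass
class PollutantFieldSpec:
    """Generative description of one pollutant's annual surface and campaigns."""

    name: str
    variogram: VariogramModel
    mean: float                       # annual district mean, ug/m3
    warm_mean: float                  # warm-season campaign mean
    cold_mean: float                  # cold-season campaign mean
    bump_amplitude: float | tuple = 0.0   # hot-spot kernel height at each chipboard
                                          # industry (scalar = same for all)
    bump_decay_km: float = 1.5        # e-folding distance of the kernel
    small_factory_fraction: float = 0.25   # kernel height at small factories, as a fraction
    noise_sd: float = 0.0             # measurement noise SD, ug/m3

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.bump_decay_km <= 0:
            raise ValueError("noise_sd must be >= 0 and bump_decay_km > 0")

    def campaign_offsets(self) -> np.ndarray:
        """Zero-centred seasonal offsets for campaigns 1-4 (warm, warm, cold, cold)."""
        raw = np.array([self.warm_mean if s == "warm" else self.cold_mean for s in SEASONS])
        return raw - raw.mean()

    @classmethod
    def formaldehyde(cls, anisotropy_ratio: float = 0.5) -> "PollutantFieldSpec":
        return cls(
            name="formaldehyde",
            variogram=VariogramModel("exponential", nugget=0.01, sill=0.12, range_=3.5,
                                     angle=90.0, ratio=anisotropy_ratio),
            mean=2.5, warm_mean=2.8, cold_mean=2.1,
            bump_amplitude=(0.3, 0.2), bump_decay_km=1.5, noise_sd=0.05,
        )

    @classmethod
    def no2(cls, anisotropy_ratio: float = 0.5) -> "PollutantFieldSpec":
        # nugget not reported for NO2; taken as 0
        return cls(
            name="no2",
            variogram=VariogramModel("exponential", nugget=0.0, sill=10.0, range_=4.0,
                                     angle=135.0, ratio=anisotropy_ratio),
            mean=16.0, warm_mean=12.9, cold_mean=18.8,
            bump_amplitude=(2.5, 1.8), bump_decay_km=1.5, noise_sd=0.8,
        )


@dataclass
class ExposureSurface:
    """A gridded annual-mean surface for one pollutant, with point queries."""

    x: np.ndarray        # (nx,) grid east coordinates, km
    y: np.ndarray        # (ny,) grid north coordinates, km
    values: np.ndarray   # (ny, nx)
    pollutant: str = ""

    def at(self, points, method: str = "linear") -> np.ndarray:
        """Surface values at (m, 2) points.

        ``method='linear'`` interpolates bilinearly; ``'nearest'`` returns the
        nearest grid node (no smoothing — preferred when the point values must
        have exactly the field's covariance, e.g. in variogram calibration).
        """
        interp = RegularGridInterpolator((self.y, self.x), self.values,
                                         method=method, bounds_error=False, fill_value=None)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return interp(pts[:, ::-1])   # (y, x) order

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x_km": xx.ravel(), "y_km": yy.ravel(),
                             "value": self.values.ravel()})


class GaussianFieldSimulator:
    """Zero-mean stationary Gaussian random field on a regular grid.

    The structured (partial-sill) part of the variogram is simulated by dense
    Cholesky factorisation of the grid covariance (factor cached, so repeated
    draws are cheap) or, for grids above ``node_cap`` nodes, by circulant
    embedding with FFTs ("spectral").  The nugget is added as independent
    white noise in either case.
    """

    def __init__(self, model: VariogramModel, x, y, method: str = "auto",
                 node_cap: int = 8000, jitter: float = 1e-9):
        self.model = model
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        n = len(self.x) * len(self.y)
        if method == "auto":
            method = "cholesky" if n <= node_cap else "spectral"
        if method == "cholesky" and n > node_cap:
            raise ValueError(
                f"grid has {n} nodes > node_cap={node_cap}; dense Cholesky would be "
                "too large — use method='spectral' (circulant embedding)"
            )
        self.method = method
        if model.sill == 0.0:
            self._chol = None
        elif method == "cholesky":
            xx, yy = np.meshgrid(self.x, self.y)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            lag = pts[:, None, :] - pts[None, :, :]
            d = model.anisotropic_distance(lag)
            cov = model.sill * (1.0 - model._structure(d))
            cov[np.diag_indices_from(cov)] = model.sill + jitter
            self._chol = np.linalg.cholesky(cov)
        elif method == "spectral":
            self._setup_spectral()
        else:
            raise ValueError(f"unknown method {method!r}")

    def _setup_spectral(self) -> None:
        dx = float(self.x[1] - self.x[0]) if len(self.x) > 1 else 1.0
        dy = float(self.y[1] - self.y[0]) if len(self.y) > 1 else 1.0
        mx = 1 << int(np.ceil(np.log2(2 * len(self.x))))
        my = 1 << int(np.ceil(np.log2(2 * len(self.y))))
        kx = np.fft.fftfreq(mx, d=1.0 / mx)          # signed integer lags
        ky = np.fft.fftfreq(my, d=1.0 / my)
        lag_x, lag_y = np.meshgrid(kx * dx, ky * dy)
        d = self.model.anisotropic_distance(np.stack([lag_x, lag_y], axis=-1))
        cov = self.model.sill * (1.0 - self.model._structure(d))
        lam = np.fft.fft2(cov).real
        neg = lam < 0
        if neg.any():
            frac = -lam[neg].sum() / max(lam[~neg].sum(), 1e-30)
            if frac > 1e-3:
                warnings.warn(f"circulant embedding clipped {frac:.2%} negative spectral mass",
                              stacklevel=2)
            lam = np.maximum(lam, 0.0)
        self._lam = lam
        self._mx, self._my = mx, my

    def draw(self, rng) -> np.ndarray:
        """One field realisation, shape (ny, nx)."""
        rng = _rng(rng)
        ny, nx = len(self.y), len(self.x)
        if self.model.sill == 0.0:
            z = np.zeros((ny, nx))
        elif self.method == "cholesky":
            z = (self._chol @ rng.standard_normal(self._chol.shape[0])).reshape(ny, nx)
        else:
            eps = rng.standard_normal((self._my, self._mx)) \
                + 1j * rng.standard_normal((self._my, self._mx))
            spec = np.sqrt(self._lam / (self._mx * self._my)) * eps
            z = np.fft.fft2(spec).real[:ny, :nx]
        if self.model.nugget > 0:
            z = z + np.sqrt(self.model.nugget) * rng.standard_normal((ny, nx))
        return z


def industry_kernel(spec: PollutantFieldSpec, district: DistrictSpec, points) -> np.ndarray:
    """Deterministic hot-spot component: exponential-decay bumps at the factories."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(pts))
    chip = np.atleast_2d(np.asarray(district.chipboard_industries, dtype=float))
    amp = np.broadcast_to(np.asarray(spec.bump_amplitude, dtype=float), (len(chip),))
    if not amp.any():
        return out
    out += (amp * np.exp(-cdist(pts, chip) / spec.bump_decay_km)).sum(axis=1)
    small = np.asarray(district.small_factories, dtype=float)
    if small.size:
        out += (spec.small_factory_fraction * float(amp.max())
                * np.exp(-cdist(pts, np.atleast_2d(small)) / spec.bump_decay_km).sum(axis=1))
    return out


def grid_axes(district: DistrictSpec, resolution_km: float):
    w, h = district.extent
    x = np.arange(0.0, w + 1e-9, resolution_km)
    y = np.arange(0.0, h + 1e-9, resolution_km)
    return x, y


def generate_pollution_field(
    spec: PollutantFieldSpec,
    district: DistrictSpec,
    grid_resolution_km: float = 0.5,
    seed=None,
    method: str = "auto",
    node_cap: int = 8000,
    simulator: GaussianFieldSimulator | None = None,
    max_redraws: int = 10,
) -> ExposureSurface:
    """Draw the latent annual-mean surface: mean + industry kernel + Gaussian field.

    Concentrations must be positive; a draw with any nonpositive grid value is
    redrawn (bounded retries).  Pass a prebuilt ``simulator`` to amortise the
    covariance factorisation over many replicates.
    """
    rng = _rng(seed)
    if simulator is None:
        x, y = grid_axes(district, grid_resolution_km)
        simulator = GaussianFieldSimulator(spec.variogram, x, y, method=method, node_cap=node_cap)
    x, y = simulator.x, simulator.y
    xx, yy = np.meshgrid(x, y)
    base = spec.mean + industry_kernel(spec, district,
                                       np.column_stack([xx.ravel(), yy.ravel()])).reshape(yy.shape)
    for _ in range(max_redraws):
        values = base + simulator.draw(rng)
        if (values > 0).all():
            return ExposureSurface(x=x, y=y, values=values, pollutant=spec.name)
    raise RuntimeError(
        f"could not draw an all-positive {spec.name} field in {max_redraws} attempts; "
        "check mean vs field variance in the PollutantFieldSpec"
    )


# ---------------------------------------------------------------------------
# monitoring campaigns
# ---------------------------------------------------------------------------

def simulate_campaign_measurements(
    true_field: ExposureSurface,
    sites,
    spec: PollutantFieldSpec,
    missing_rate: float = 0.0,
    seed=None,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Four campaigns of passive-sampler measurements at the monitoring sites.

    measurement = true annual value at the site + zero-centred seasonal offset
    of the campaign + Gaussian noise.  Site-by-campaign missingness is applied
    at random but never removes all four campaigns of a site, and at least one
    site always stays complete (the temporal adjustment needs an anchor).
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed)
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    n = len(sites)
    truth = np.asarray(true_field.at(sites), dtype=float)
    offsets = spec.campaign_offsets()

    mask = np.zeros((n, 4), dtype=bool)   # True = missing
    if missing_rate > 0:
        for _ in range(max_retries):
            mask = rng.random((n, 4)) < missing_rate
            complete = ~mask.any(axis=1)
            if complete.any() and not mask.all(axis=1).any():
                break
        else:
            raise RuntimeError("could not draw an admissible missingness pattern "
                               f"in {max_retries} tries (missing_rate={missing_rate})")

    rows = []
    for c in range(4):
        conc = truth + offsets[c]
        if spec.noise_sd > 0:
            noise = rng.normal(0.0, spec.noise_sd, size=n)
            conc = conc + noise
            for _ in range(max_retries):          # truncate-and-redraw negatives
                bad = conc <= 0
                if not bad.any():
                    break
                conc[bad] = truth[bad] + offsets[c] + rng.normal(0.0, spec.noise_sd, size=bad.sum())
            else:
                raise RuntimeError("could not draw positive concentrations")
        for i in range(n):
            if mask[i, c]:
                continue
            rows.append({
                "site_id": i, "x_km": sites[i, 0], "y_km": sites[i, 1],
                "campaign": c + 1, "season": SEASONS[c],
                "pollutant": spec.name, "conc_ugm3": float(conc[i]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def default_covariate_freqs() -> dict:
    """Survey-like covariate category frequencies (aggregated over strata)."""
    return {
        "female": 0.44,
        "foreign": 0.09,
        "parents_education": {"primary": 0.03, "secondary": 0.27,
                              "high_school": 0.53, "university": 0.17},
        "smoking_parents": 0.29,
        "smoke_home": 0.11,
        "air_refreshing": {"lt15min": 0.25, "about30min": 0.30, "ge1hr": 0.45},
        "high_traffic": 0.60,
        "orthodontic": 0.20,
        "dmft_ge1": 0.45,
        "collector": {"parents": 0.14, "parents_assisted": 0.63, "health_personnel": 0.23},
        "house_new": 0.15,
        "furniture_age": {"none": 0.22, "lt3y": 0.32, "ge3y": 0.46},
        "double_glazing": 0.66,
        "mover": 0.14,
    }

CATEGORICAL_LEVELS = {
    "parents_education": ["primary", "secondary", "high_school", "university"],
    "air_refreshing": ["lt15min", "about30min", "ge1hr"],
    "collector": ["parents", "parents_assisted", "health_personnel"],
    "furniture_age": ["none", "lt3y", "ge3y"],
}


def _sample_stratum_points(district, stratum, n, rng, max_batches=2000):
    """Rejection-sample n uniform residences inside one distance stratum."""
    w, h = district.extent
    got = []
    for _ in range(max_batches):
        batch = rng.random((max(4 * n, 256), 2)) * np.array([w, h])
        labels = distance_strata(batch, district)
        hit = batch[labels == stratum]
        if len(hit):
            got.append(hit)
        if sum(len(g) for g in got) >= n:
            return np.concatenate(got)[:n]
    raise ValueError(
        f"stratum {stratum!r} region appears empty: distance thresholds "
        f"(chipboard {district.chipboard_radius_km} km, small {district.small_radius_km} km) "
        f"are inconsistent with the extent {district.extent} and factory layout"
    )


def generate_cohort(
    district: DistrictSpec,
    n_per_stratum: int = 250,
    covariate_freqs: dict | None = None,
    seed=None,
) -> pd.DataFrame:
    """Children with residences (uniform within stratum) and questionnaire covariates.

    Covariates are drawn independently at the configured frequencies; age is
    uniform on 6-12 years.  Sensitivity-analysis covariates (house age,
    furniture age, double glazing) and a mover flag are included.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    rng = _rng(seed)
    freqs = default_covariate_freqs()
    if covariate_freqs:
        freqs.update(covariate_freqs)
    for name, levels in CATEGORICAL_LEVELS.items():
        p = freqs[name]
        if abs(sum(p.values()) - 1.0) > 1e-6:
            raise ValueError(f"category frequencies for {name!r} must sum to 1")

    frames = []
    for stratum in STRATA:
        xy = _sample_stratum_points(district, stratum, n_per_stratum, rng)
        frames.append(pd.DataFrame({"x_km": xy[:, 0], "y_km": xy[:, 1], "stratum": stratum}))
    cohort = pd.concat(frames, ignore_index=True)
    n = len(cohort)
    cohort.insert(0, "child_id", np.arange(n))
    cohort["age"] = rng.uniform(6.0, 12.0, size=n)
    for name in ("female", "foreign", "smoking_parents", "smoke_home", "high_traffic",
                 "orthodontic", "dmft_ge1", "house_new", "double_glazing", "mover"):
        cohort[name] = (rng.random(n) < freqs[name]).astype(int)
    for name, levels in CATEGORICAL_LEVELS.items():
        p = np.array([freqs[name][lev] for lev in levels], dtype=float)
        draw = rng.choice(len(levels), size=n, p=p / p.sum())
        cohort[name] = pd.Categorical.from_codes(draw, categories=levels)
    cohort["stratum"] = pd.Categorical(cohort["stratum"], categories=list(STRATA))
    return cohort


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def _default_gaussian_cov_effects(sd: float) -> dict:
    # mild, fixed confounders: effects expressed on the outcome scale
    return {"smoking_parents": 0.10 * sd, "age_c": 0.02 * sd, "female": -0.05 * sd}


def _default_count_cov_effects() -> dict:
    # log-rate scale
    return {"smoking_parents": 0.08, "age_c": 0.01, "female": -0.03}


@dataclass
class OutcomeSpec:
    """Generative parameters of the six genotoxicity markers.

    Gaussian markers (per-subject medians / frequencies): tail intensity (%),
    tail length (um), tail moment, binucleated cells (%).  Count markers per
    ``n_cells_scored`` = 2,000 cells: micronuclei and nuclear buds, negative
    binomial with NB2 dispersion ``alpha`` (variance mu + alpha mu^2).
    ``slopes`` holds additive effects per 1-SD exposure, ``rate_ratios``
    multiplicative RRs per 1-SD.
    """

    ti_mean: float = 3.25
    ti_sd: float = 0.88
    tl_mean: float = 11.69
    tl_sd: float = 2.11
    tm_mean: float = 0.20
    tm_sd: float = 0.05
    bn_mean: float = 1.83
    bn_sd: float = 0.64
    mn_pct: float = 0.12          # mean frequency, % of scored cells
    bud_pct: float = 0.23
    n_cells_scored: int = 2000
    alpha_mn: float = 0.08
    alpha_buds: float = 0.70
    cells_full_prob: float = 0.8  # P(all 50 comet cells scorable)
    cells_min: int = 10
    slopes: dict = field(default_factory=lambda: {
        ("ti", "formaldehyde"): 0.13,
        ("tm", "formaldehyde"): 0.007,
        ("bn_pct", "no2"): 0.13,
    })
    rate_ratios: dict = field(default_factory=lambda: {
        ("bud_count", "formaldehyde"): 1.12,
        ("bud_count", "no2"): 1.16,
    })
    covariate_effects: dict | None = None   # outcome -> {covariate: coef}; None = defaults

    def __post_init__(self) -> None:
        for sd in (self.ti_sd, self.tl_sd, self.tm_sd, self.bn_sd):
            if sd <= 0:
                raise ValueError("outcome SDs must be positive")
        if any(rr <= 0 for rr in self.rate_ratios.values()):
            raise ValueError("rate ratios must be positive")
        if not (10 <= self.cells_min <= 50):
            raise ValueError("cells_min must be in [10, 50]")

    def cov_effects(self, outcome: str, sd: float | None = None) -> dict:
        if self.covariate_effects is not None:
            return dict(self.covariate_effects.get(outcome, {}))
        if outcome in ("mn_count", "bud_count"):
            return _default_count_cov_effects()
        return _default_gaussian_cov_effects(sd if sd is not None else 1.0)


_GAUSSIAN = {
    "ti": ("ti_mean", "ti_sd", True),
    "tl": ("tl_mean", "tl_sd", True),
    "tm": ("tm_mean", "tm_sd", True),
    "bn_pct": ("bn_mean", "bn_sd", False),
}
_COUNTS = {"mn_count": ("mn_pct", "alpha_mn"), "bud_count": ("bud_pct", "alpha_buds")}
EXPOSURE_COLS = {"formaldehyde": "z_formaldehyde", "no2": "z_no2"}


def _covariate_values(cohort: pd.DataFrame, name: str) -> np.ndarray:
    if name == "age_c":
        return cohort["age"].to_numpy(dtype=float) - 9.0
    col = cohort[name]
    if isinstance(col.dtype, pd.CategoricalDtype):
        return col.cat.codes.to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def simulate_outcomes(cohort: pd.DataFrame, spec: OutcomeSpec | None = None, seed=None) -> pd.DataFrame:
    """Attach the six outcome columns (and cells_examined) to an exposed cohort.

    The cohort must carry standardised exposure columns ``z_formaldehyde`` and
    ``z_no2``.  Gaussian outcomes: linear predictor = marginal mean + per-SD
    slopes x z + mean-centred covariate terms; the residual SD is chosen so
    the marginal SD matches the spec, and for the comet markers it is scaled
    by sqrt(50 / cells examined), which is what motivates the cells-examined
    weighting in the analysis.  Counts are NB2 via a Gamma-Poisson mixture
    with log link.
    """
    spec = spec or OutcomeSpec()
    rng = _rng(seed)
    out = cohort.copy()
    n = len(out)
    for col in EXPOSURE_COLS.values():
        if col not in out.columns:
            raise ValueError(f"cohort lacks standardised exposure column {col!r}")

    # comet cells examined: 50 when available, occasionally fewer
    full = rng.random(n) < spec.cells_full_prob
    cells = np.where(full, 50, rng.integers(spec.cells_min, 50, size=n))
    out["cells_examined"] = cells.astype(int)

    def systematic(outcome: str, mean: float, sd: float | None) -> np.ndarray:
        lp = np.full(n, 0.0)
        for (oc, poll), eff in spec.slopes.items():
            if oc == outcome:
                lp += eff * out[EXPOSURE_COLS[poll]].to_numpy()
        for cov, coef in spec.cov_effects(outcome, sd).items():
            v = _covariate_values(out, cov)
            lp += coef * (v - v.mean())
        return mean + lp

    for outcome, (mean_attr, sd_attr, comet) in _GAUSSIAN.items():
        mean = getattr(spec, mean_attr)
        sd = getattr(spec, sd_attr)
        sys = systematic(outcome, mean, sd)
        var_sys = float(np.var(sys))
        resid_var = sd**2 - var_sys
        if resid_var <= 0:
            raise ValueError(
                f"inconsistent OutcomeSpec: systematic SD {np.sqrt(var_sys):.4g} of "
                f"{outcome!r} exceeds its marginal SD {sd:.4g}"
            )
        if comet:
            f = 50.0 / cells
            base_var = resid_var / float(f.mean())
            eps = rng.normal(0.0, np.sqrt(base_var * f))
        else:
            eps = rng.normal(0.0, np.sqrt(resid_var), size=n)
        values = sys + eps
        if outcome in ("ti", "bn_pct"):
            values = np.clip(values, 0.0, 100.0)
        else:
            values = np.clip(values, 0.0, None)
        out[outcome] = values

    for outcome, (pct_attr, alpha_attr) in _COUNTS.items():
        base_count = getattr(spec, pct_attr) / 100.0 * spec.n_cells_scored
        alpha = getattr(spec, alpha_attr)
        log_mu = np.log(base_count) * np.ones(n)
        for (oc, poll), rr in spec.rate_ratios.items():
            if oc == outcome:
                log_mu += np.log(rr) * out[EXPOSURE_COLS[poll]].to_numpy()
        for cov, coef in spec.cov_effects(outcome).items():
            v = _covariate_values(out, cov)
            log_mu += coef * (v - v.mean())
        mu = np.exp(log_mu)
        if alpha > 0:
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        else:
            lam = mu
        counts = rng.poisson(lam)
        out[outcome] = np.minimum(counts, spec.n_cells_scored).astype(int)

    out["mn_pct"] = out["mn_count"] / spec.n_cells_scored * 100.0
    out["bud_pct"] = out["bud_count"] / spec.n_cells_scored * 100.0
    return out


# ---------------------------------------------------------------------------
# truth export
# ---------------------------------------------------------------------------

def write_truth_json(path, district: DistrictSpec, field_specs, outcome_spec: OutcomeSpec,
                     seed=None) -> None:
    """All generative parameters, for parameter-recovery tests and audits."""
    def encode(obj):
        if isinstance(obj, VariogramModel):
            return asdict(obj)
        if isinstance(obj, (DistrictSpec, PollutantFieldSpec)):
            return asdict(obj)
        if isinstance(obj, OutcomeSpec):
            d = asdict(obj)
            d["slopes"] = {f"{k[0]}|{k[1]}": v for k, v in obj.slopes.items()}
            d["rate_ratios"] = {f"{k[0]}|{k[1]}": v for k, v in obj.rate_ratios.items()}
            return d
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot encode {type(obj)}")

    payload = {
        "seed": seed,
        "district": district,
        "fields": {s.name: s for s in field_specs},
        "outcomes": outcome_spec,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, default=encode, indent=2)
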