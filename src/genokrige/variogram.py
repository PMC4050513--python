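"""Variogram models, empirical (Matheron) estimation, and weighted least-squares fitting.

The semivariogram :math:`\\gamma(h)` is half the expected squared difference of a
spatial field at lag ``h``.  Models here are parameterised by a nugget
:math:`c_0` (micro-scale plus measurement variance), a partial sill :math:`c`
(structured variance) and a range ``a`` — the *distance parameter* of the
model, so for the exponential family

.. math:: \\gamma(h) = c_0 + c\\,(1 - e^{-h/a}), \\qquad \\gamma(0) = 0,

and the practical range (95 % of the sill) is about :math:`3a`.  Geometric
anisotropy is handled by rotating the lag vector into the major/minor axes and
stretching the minor axis by ``1/ratio`` before evaluating the isotropic form.
Angles are degrees clockwise from north (90° = east).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

FAMILIES = ("exponential", "spherical", "gaussian", "nugget")

__all__ = [
    "FAMILIES",
    "VariogramModel",
    "EmpiricalVariogram",
    "empirical_variogram",
    "fit_variogram",
]


@dataclass(frozen=True)
class VariogramModel:
    """A parametric semivariogram with optional geometric anisotropy.

    Parameters
    ----------
    family : {"exponential", "spherical", "gaussian", "nugget"}
    nugget : float
        Nugget variance :math:`c_0 \\ge 0`.
    sill : float
        Partial sill :math:`c \\ge 0` (structured variance on top of the nugget).
    range_ : float
        Distance parameter ``a`` in km, > 0.  For the exponential family this
        is the e-folding distance, not the practical range (~3a).
    angle : float
        Direction of maximum spatial continuity, degrees clockwise from north.
    ratio : float
        Anisotropy ratio (minor/major axis) in (0, 1]; 1 = isotropic.
    """

    family: str
    nugget: float = 0.0
    sill: float = 1.0
    range_: float = 1.0
    angle: float = 0.0
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}; choose from {FAMILIES}")
        if self.nugget < 0 or self.sill < 0:
            raise ValueError("nugget and partial sill must be nonnegative")
        if self.family != "nugget" and self.range_ <= 0:
            raise ValueError("range must be strictly positive")
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError("anisotropy ratio must lie in (0, 1]")

    # -- geometry -----------------------------------------------------------

    def anisotropic_distance(self, h: np.ndarray) -> np.ndarray:
        """Effective (major-axis-equivalent) distance of lag vectors ``h``.

        ``h`` has shape (..., 2) in (x=east, y=north) km.  The lag is rotated
        into the (major, minor) axes and the minor component divided by the
        anisotropy ratio, so correlation decays ``1/ratio`` times faster
        across the minor axis.
        """
        h = np.asarray(h, dtype=float)
        theta = np.deg2rad(self.angle)
        # clockwise-from-north major axis unit vector is (sin t, cos t)
        major = h[..., 0] * np.sin(theta) + h[..., 1] * np.cos(theta)
        minor = h[..., 0] * np.cos(theta) - h[..., 1] * np.sin(theta)
        return np.hypot(major, minor / self.ratio)

    # -- evaluation ---------------------------------------------------------

    def _structure(self, d: np.ndarray) -> np.ndarray:
        """Normalised structured part g(d) in [0, 1] (no nugget, no sill)."""
        a = self.range_
        if self.family == "exponential":
            return 1.0 - np.exp(-d / a)
        if self.family == "gaussian":
            return 1.0 - np.exp(-((d / a) ** 2))
        if self.family == "spherical":
            u = np.clip(d / a, 0.0, 1.0)
            return 1.5 * u - 0.5 * u**3
        # pure nugget
        return np.zeros_like(d)

    def semivariance(self, h) -> np.ndarray:
        """Evaluate gamma at scalar separation distance(s) ``h``.

        Distances are taken on the anisotropy-corrected (major-axis) scale;
        use :meth:`semivariance_lag` for raw 2-D lag vectors.
        """
        d = np.abs(np.asarray(h, dtype=float))
        gamma = self.nugget + self.sill * self._structure(d)
        return np.where(d > 0, gamma, 0.0)

    __call__ = semivariance

    def semivariance_lag(self, h) -> np.ndarray:
        """Evaluate gamma at 2-D lag vector(s) ``h`` (last axis = (east, north) km)."""
        return self.semivariance(self.anisotropic_distance(h))

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = c0 + c - gamma(h) at scalar distance(s).

        The nugget contributes only exactly at h = 0.
        """
        d = np.abs(np.asarray(h, dtype=float))
        cov = self.sill * (1.0 - self._structure(d))
        return np.where(d > 0, cov, self.sill + self.nugget)

    def covariance_lag(self, h) -> np.ndarray:
        return self.covariance(self.anisotropic_distance(h))

    @property
    def total_sill(self) -> float:
        return self.nugget + self.sill

    @property
    def n_params(self) -> int:
        """Free structural parameters (used for model-selection tie-breaks)."""
        return 1 if self.family == "nugget" else 3

    def with_anisotropy(self, angle: float, ratio: float) -> "VariogramModel":
        return replace(self, angle=angle, ratio=ratio)


@dataclass
class EmpiricalVariogram:
    """Binned Matheron estimates: gamma_hat(h) = sum (z_i - z_j)^2 / (2 N(h))."""

    lags: np.ndarray          # bin centres, km (anisotropy-corrected scale)
    gamma: np.ndarray         # semivariance estimates
    counts: np.ndarray        # pair counts N(h)
    max_lag: float
    min_pairs: int = 5

    @property
    def reliable(self) -> np.ndarray:
        """Mask of bins with at least ``min_pairs`` pairs."""
        return self.counts >= self.min_pairs


def empirical_variogram(
    coords,
    values,
    n_bins: int = 12,
    max_lag: float | None = None,
    angle: float = 0.0,
    ratio: float = 1.0,
    direction: float | None = None,
    direction_tol: float = 22.5,
    min_pairs: int = 5,
) -> EmpiricalVariogram:
    """Method-of-moments (Matheron) variogram of point data.

    Parameters
    ----------
    coords : (n, 2) array of site coordinates in km.
    values : (n,) array of the variable (e.g. adjusted annual means).
    n_bins, max_lag : equal-width lag bins up to ``max_lag`` (default: half the
        maximum pairwise separation).
    angle, ratio : geometric-anisotropy transform applied to pair separations
        before binning, so a model fitted to the result uses its major-axis
        range.  Defaults are isotropic.
    direction, direction_tol : optional directional filtering — keep only
        pairs whose azimuth (degrees clockwise from north, mod 180) is within
        ``direction_tol`` of ``direction``.  Used for anisotropy exploration.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two sites for an empirical variogram")

    i, j = np.triu_indices(n, k=1)
    dxy = coords[j] - coords[i]

    if direction is not None:
        az = np.rad2deg(np.arctan2(dxy[:, 0], dxy[:, 1])) % 180.0
        delta = np.abs(az - direction % 180.0)
        delta = np.minimum(delta, 180.0 - delta)
        keep = delta <= direction_tol
        dxy = dxy[keep]
        i, j = i[keep], j[keep]

    transform = VariogramModel("exponential", angle=angle, ratio=ratio)
    dist = transform.anisotropic_distance(dxy)
    if max_lag is None:
        # half the maximum pairwise separation (site geometry, untransformed)
        max_lag = 0.5 * float(np.hypot(dxy[:, 0], dxy[:, 1]).max())
    inside = dist <= max_lag
    if not inside.any():
        raise ValueError("all point pairs lie beyond max_lag")
    sq = 0.5 * (values[j[inside]] - values[i[inside]]) ** 2
    dist = dist[inside]

    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sq, minlength=n_bins)
    dsums = np.bincount(which, weights=dist, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # represent each bin by the mean pair separation, not the bin centre
    centres = 0.5 * (edges[:-1] + edges[1:])
    lags = np.where(counts > 0, dsums / np.maximum(counts, 1), centres)
    return EmpiricalVariogram(lags, gamma, counts, max_lag, min_pairs=min_pairs)


def _start_points(emp: EmpiricalVariogram, rng: np.random.Generator, n_starts: int):
    ok = emp.reliable & np.isfinite(emp.gamma)
    g = emp.gamma[ok]
    lag = emp.lags[ok]
    sill0 = max(float(np.mean(g[-max(1, len(g) // 3):])), 1e-8)
    nug0 = max(float(g[0]) if len(g) else 0.0, 0.0)
    nug0 = min(nug0, 0.5 * sill0)
    reach = np.nonzero(g >= 0.95 * sill0)[0]
    a0 = max(float(lag[reach[0]]) if len(reach) else float(lag[-1]) / 3.0, 1e-3)
    c0 = max(sill0 - nug0, 1e-8)
    # one moment-based start plus fixed short- and mid-range starts (the
    # objective is multimodal in the range; short-range optima are easy to miss)
    starts = [(nug0, c0, a0 / 3.0), (nug0, c0, float(lag[0])), (nug0, c0, float(lag[-1]) / 6.0)]
    for _ in range(max(n_starts - 3, 0)):
        f = rng.uniform(0.3, 3.0, size=3)
        starts.append((nug0 * f[0], c0 * f[1], a0 / 3.0 * f[2]))
    return starts


def fit_variogram(
    emp: EmpiricalVariogram,
    family: str = "exponential",
    angle: float = 0.0,
    ratio: float = 1.0,
    n_starts: int = 3,
    random_state: int = 0,
) -> VariogramModel:
    """Fit (nugget, partial sill, range) to an empirical variogram.

    Weighted least squares with Cressie weights N(h)/gamma_model(h)^2, solved
    by bounded multi-start Levenberg–Marquardt (trust-region reflective); the
    anisotropy (``angle``, ``ratio``) is held fixed and stamped on the
    returned model — it is profiled over a grid by model selection, not
    optimised continuously here.
    """
    ok = emp.reliable & np.isfinite(emp.gamma)
    if ok.sum() < 3:
        raise ValueError("need at least 3 populated lag bins to fit a variogram")
    lags = emp.lags[ok]
    gam = emp.gamma[ok]
    cnt = emp.counts[ok].astype(float)

    if family == "nugget":
        c0 = float(np.average(gam, weights=cnt))
        return VariogramModel("nugget", nugget=c0, sill=0.0, range_=1.0, angle=angle, ratio=ratio)

    lo = np.array([0.0, 0.0, 0.1 * float(lags.min())])
    hi = np.array([np.inf, np.inf, 2.0 * float(emp.max_lag)])
    rng = np.random.default_rng(random_state)

    def residuals(p):
        model = VariogramModel(family, nugget=p[0], sill=p[1], range_=max(p[2], 1e-9))
        g = model.semivariance(lags)
        g = np.maximum(g, 1e-12)
        return np.sqrt(cnt) * (gam - g) / g

    best = None
    for x0 in _start_points(emp, rng, n_starts):
        x0 = np.clip(np.asarray(x0, dtype=float), lo, np.where(np.isfinite(hi), hi, np.inf))
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), max_nfev=2000)
        except Exception:  # pragma: no cover - numerical edge
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"variogram fit failed to converge for family {family!r} at all starts")
    c0, c, a = best.x
    return VariogramModel(family, nugget=float(c0), sill=float(c), range_=float(a), angle=angle, ratio=ratio)
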