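"""Ordinary kriging, leave-one-out cross-validation, and variogram model selection.

Ordinary kriging is the best linear unbiased predictor of a stationary field
with unknown constant mean.  For sites :math:`x_1..x_n` with values ``z`` and a
semivariogram :math:`\\gamma`, the weights at a query point :math:`x_0` solve
the augmented system

.. math::

    \\begin{pmatrix} \\Gamma & \\mathbf{1} \\\\ \\mathbf{1}^T & 0 \\end{pmatrix}
    \\begin{pmatrix} w \\\\ \\mu \\end{pmatrix}
    = \\begin{pmatrix} \\gamma_0 \\\\ 1 \\end{pmatrix},

with :math:`\\Gamma_{ij} = \\gamma(x_i - x_j)` and
:math:`\\gamma_{0,i} = \\gamma(x_i - x_0)`; the prediction is :math:`w^T z` and
the kriging variance :math:`w^T \\gamma_0 + \\mu`.  The constraint
:math:`\\sum w_i = 1` enforces unbiasedness.  The neighbourhood is global (all
sites), appropriate for the few dozen passive-sampler sites this package
targets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .variogram import VariogramModel, empirical_variogram, fit_variogram

__all__ = [
    "OrdinaryKriging",
    "KrigingResult",
    "krige",
    "loocv_rmse",
    "select_model",
]


@dataclass
class KrigingResult:
    """Predictions (and diagnostics) of one kriging run."""

    predictions: np.ndarray
    variance: np.ndarray
    model: VariogramModel
    weights: np.ndarray | None = None   # (n_query, n_sites), optional
    loocv_rmse: float | None = None


class OrdinaryKriging(RegressorMixin, BaseEstimator):
    """Global ordinary kriging interpolator.

    Parameters
    ----------
    model : VariogramModel
        The (possibly anisotropic) semivariogram to krige with.
    average_duplicates : bool, default True
        Sites sharing coordinates are replaced by their mean value before the
        system is built (and a warning emitted); otherwise the system is
        singular.

    Attributes
    ----------
    X_ : (n, 2) ndarray — site coordinates actually used (deduplicated).
    z_ : (n,) ndarray — site values.
    n_features_in_ : int
    """

    def __init__(self, model: VariogramModel | None = None, average_duplicates: bool = True):
        self.model = model
        self.average_duplicates = average_duplicates

    def fit(self, X, y):
        if self.model is None:
            raise ValueError("OrdinaryKriging requires a VariogramModel")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of planar km coordinates")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) < 2:
            raise ValueError("ordinary kriging needs at least 2 sites")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("X and y must be finite")

        uniq, inverse = np.unique(X, axis=0, return_inverse=True)
        if len(uniq) < len(X):
            if not self.average_duplicates:
                raise ValueError("duplicate site coordinates present")
            warnings.warn(
                f"averaged {len(X) - len(uniq)} duplicate-coordinate site(s) before kriging",
                stacklevel=2,
            )
            y = np.bincount(inverse, weights=y) / np.bincount(inverse)
            X = uniq
        if len(X) < 2:
            raise ValueError("fewer than 2 distinct sites after averaging duplicates")

        n = len(X)
        lag = X[:, None, :] - X[None, :, :]
        gamma = self.model.semivariance_lag(lag)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = gamma
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        A[n, n] = 0.0
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"kriging system is numerically singular (condition number {cond:.3g}); "
                "are all sites coincident or the variogram degenerate?"
            )
        self.X_ = X
        self.z_ = y
        self._lu = linalg.lu_factor(A)
        self.n_features_in_ = 2
        return self

    def predict(self, X, return_std: bool = False, return_weights: bool = False):
        """Krige at query points ``X`` (shape (m, 2)).

        Returns predictions; with ``return_std`` also the kriging standard
        deviation, and with ``return_weights`` the (m, n) weight matrix.
        """
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 2:
            raise ValueError("query points must be (m, 2)")
        n = len(self.X_)
        lag = self.X_[None, :, :] - X[:, None, :]
        gamma0 = self.model.semivariance_lag(lag)          # (m, n)
        rhs = np.empty((n + 1, len(X)))
        rhs[:n] = gamma0.T
        rhs[n] = 1.0
        sol = linalg.lu_solve(self._lu, rhs)                # (n+1, m)
        w = sol[:n].T                                       # (m, n)
        mu = sol[n]
        pred = w @ self.z_
        out = [pred]
        if return_std:
            var = np.einsum("mn,mn->m", w, gamma0) + mu
            out.append(np.sqrt(np.maximum(var, 0.0)))
        if return_weights:
            out.append(w)
        return out[0] if len(out) == 1 else tuple(out)

    def kriging_variance(self, X) -> np.ndarray:
        pred, std = self.predict(X, return_std=True)
        return std**2

    def __call__(self, X) -> np.ndarray:
        return self.predict(X)


def krige(coords, values, model: VariogramModel, query, return_weights: bool = False) -> KrigingResult:
    """One-shot ordinary kriging of ``values`` at ``coords`` onto ``query`` points."""
    ok = OrdinaryKriging(model).fit(coords, values)
    if return_weights:
        pred, std, w = ok.predict(query, return_std=True, return_weights=True)
    else:
        pred, std = ok.predict(query, return_std=True)
        w = None
    return KrigingResult(predictions=pred, variance=std**2, model=model, weights=w)


def loocv_rmse(coords, values, model: VariogramModel, max_fail_frac: float = 0.1) -> float:
    """Leave-one-out cross-validated RMSE of ordinary kriging with a fixed model.

    Each site is predicted from the other n-1 with the same variogram.  The
    per-fold systems share structure with the full one, so the errors are
    computed in one shot from the inverse of the full augmented matrix
    (e_i = b_i / (A^-1)_ii with b = A^-1 [z; 0]) — algebraically identical to
    refitting every fold.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(coords)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 sites")
    try:
        ok = OrdinaryKriging(model).fit(coords, values)
    except np.linalg.LinAlgError:
        # duplicate averaging changed n, or the full system is singular:
        # fall back to explicit refits so partial failures can be counted
        return _loocv_rmse_refit(coords, values, model, max_fail_frac)
    if len(ok.X_) != n:   # duplicates were averaged; refit folds explicitly
        return _loocv_rmse_refit(coords, values, model, max_fail_frac)
    A_inv = linalg.lu_solve(ok._lu, np.eye(n + 1))
    b = A_inv @ np.append(values, 0.0)
    diag = np.diag(A_inv)[:n]
    if np.any(np.abs(diag) < 1e-14):
        return _loocv_rmse_refit(coords, values, model, max_fail_frac)
    errs = b[:n] / diag
    return float(np.sqrt(np.mean(errs**2)))


def _loocv_rmse_refit(coords, values, model: VariogramModel, max_fail_frac: float = 0.1) -> float:
    n = len(coords)
    mask = np.ones(n, dtype=bool)
    errs = []
    failures = 0
    for i in range(n):
        mask[i] = False
        try:
            ok = OrdinaryKriging(model).fit(coords[mask], values[mask])
            pred = ok.predict(coords[i][None, :])[0]
            errs.append(pred - values[i])
        except np.linalg.LinAlgError:
            failures += 1
        finally:
            mask[i] = True
    if failures > max_fail_frac * n:
        raise RuntimeError(f"{failures}/{n} LOOCV folds failed")
    return float(np.sqrt(np.mean(np.square(errs))))


def select_model(
    coords,
    values,
    families=("exponential", "gaussian", "spherical"),
    angles=(0.0,),
    ratios=(1.0,),
    n_bins: int = 12,
    max_lag: float | None = None,
    min_pairs: int = 5,
    random_state: int = 0,
):
    """Fit every (family, angle, ratio) candidate and pick the LOOCV-RMSE argmin.

    The anisotropy angle and ratio are profiled over the supplied grids (the
    variogram fit itself only optimises nugget/sill/range).  Ties are broken
    by fewer model parameters, then smaller range.  Returns
    ``(best_model, leaderboard)`` where the leaderboard is a DataFrame sorted
    by RMSE ascending (winner first).
    """
    if not families:
        raise ValueError("candidate family set is empty")
    rows = []
    failures = []
    for family, angle, ratio in itertools.product(families, angles, ratios):
        try:
            emp = empirical_variogram(
                coords, values, n_bins=n_bins, max_lag=max_lag,
                angle=angle, ratio=ratio, min_pairs=min_pairs,
            )
            model = fit_variogram(emp, family=family, angle=angle, ratio=ratio,
                                  random_state=random_state)
            rmse = loocv_rmse(coords, values, model)
        except Exception as exc:
            failures.append((family, angle, ratio, str(exc)))
            continue
        rows.append({
            "family": family, "angle": angle, "ratio": ratio,
            "nugget": model.nugget, "sill": model.sill, "range_km": model.range_,
            "loocv_rmse": rmse, "n_params": model.n_params, "_model": model,
        })
    if not rows:
        raise RuntimeError(f"all variogram candidates failed: {failures}")
    board = pd.DataFrame(rows).sort_values(
        ["loocv_rmse", "n_params", "range_km"], kind="mergesort"
    ).reset_index(drop=True)
    best = board.loc[0, "_model"]
    board = board.drop(columns="_model")
    return best, board
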