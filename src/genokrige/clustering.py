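"""Balanced k-medoids monitoring-network design.

Passive-sampler sites are placed at the medoids of equal-sized clusters of the
candidate residences, so the network tracks population density.  The balanced
variant of partitioning-around-medoids alternates

1. an *exact* balanced assignment of points to the current medoids (cluster
   sizes constrained to ``floor(n/k)`` or ``ceil(n/k)``), solved as a
   transportation problem on an expanded slot matrix with the Hungarian
   algorithm, and
2. a medoid update: each cluster's new medoid is the member point minimising
   the summed distance to the other members.

Both steps are nonincreasing in the total point-to-medoid distance, so the
objective is monotone and the loop terminates.  Initial medoids use a
deterministic farthest-point spread anchored at the lexicographically smallest
coordinate, which makes the medoid set invariant to the input point order
(ties broken by coordinate order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["SitePlan", "BalancedKMedoids", "balanced_kmedoids", "stratified_site_split"]

_PENALTY = 1e9  # keeps dummy rows in the "extra" slots; never paid at optimum


@dataclass
class SitePlan:
    """Result of a monitoring-network design."""

    k: int
    medoid_indices: np.ndarray   # indices into the input points
    medoids: np.ndarray          # (k, 2) coordinates
    labels: np.ndarray           # cluster label per input point
    objective: float             # total within-cluster point-to-medoid distance, km

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _lex_order(points: np.ndarray) -> np.ndarray:
    """Indices sorting points by (x, y) then original index — the global tie-break."""
    return np.lexsort((np.arange(len(points)), points[:, 1], points[:, 0]))


def _farthest_point_init(D: np.ndarray, k: int, rank: np.ndarray, anchor: int) -> list[int]:
    """Deterministic k-means++-style spread: start at ``anchor``, then
    repeatedly add the point farthest from the chosen set (ties broken by
    coordinate order)."""
    chosen = [anchor]
    while len(chosen) < k:
        dmin = D[:, chosen].min(axis=1)
        best = np.flatnonzero(dmin == dmin.max())
        chosen.append(int(best[np.argmin(rank[best])]))
    return chosen


def _balanced_assignment(D_to_medoids: np.ndarray, k: int) -> np.ndarray:
    """Optimal assignment of n points to k medoids with sizes in {q, q+1}.

    Each cluster gets q base slots plus one optional extra slot; ``k - r``
    dummy rows (zero cost to extra slots only) absorb the unused extras, so
    exactly r clusters end up with q+1 points.  Solved as one square
    linear-sum-assignment problem.
    """
    n, kk = D_to_medoids.shape
    assert kk == k
    q, r = divmod(n, k)
    n_dummy = k - r
    size = n + n_dummy                       # = k*q + k = columns (k*q base + k extra)
    cost = np.empty((size, size))
    base_cols = np.repeat(np.arange(k), q)   # k*q base slots
    cost[:n, :k * q] = D_to_medoids[:, base_cols]
    cost[:n, k * q:] = D_to_medoids          # one extra slot per cluster
    cost[n:, :k * q] = _PENALTY
    cost[n:, k * q:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    labels = np.empty(n, dtype=int)
    for row, col in zip(rows, cols):
        if row < n:
            labels[row] = base_cols[col] if col < k * q else col - k * q
    return labels


class BalancedKMedoids(ClusterMixin, BaseEstimator):
    """Partitioning around medoids with exactly balanced cluster sizes.

    Parameters
    ----------
    n_clusters : int
    max_iter : int, default 50
    n_restarts : int, default 10
        Alternating assignment/update converges to a local optimum, so the
        search restarts from up to ``n_restarts`` farthest-point spreads
        anchored at coordinate-ranked points (all deterministic) and keeps the
        best objective.
    random_state : int or None
        Accepted for scikit-learn API compatibility; the initialisation is a
        deterministic farthest-point spread, so results do not depend on it.

    Attributes
    ----------
    labels_ : (n,) cluster label per point.
    medoid_indices_ : (k,) indices of the medoids in the input.
    cluster_centers_ : (k, 2) medoid coordinates.
    inertia_ : total within-cluster point-to-medoid distance (km).
    n_iter_ : iterations run.
    """

    def __init__(self, n_clusters: int = 8, max_iter: int = 50, n_restarts: int = 10,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    @staticmethod
    def _alternate(D, medoids, rank, k, max_iter):
        """Alternating balanced assignment / medoid update from given medoids."""
        n = len(D)
        labels = None
        objective = np.inf
        for it in range(1, max_iter + 1):
            new_labels = _balanced_assignment(D[:, medoids], k)
            new_medoids = []
            for c in range(k):
                members = np.flatnonzero(new_labels == c)
                intra = D[np.ix_(members, members)].sum(axis=1)
                best = members[intra == intra.min()]
                new_medoids.append(int(best[np.argmin(rank[best])]))
            new_objective = float(D[np.arange(n), np.asarray(new_medoids)[new_labels]].sum())
            converged = labels is not None and np.array_equal(new_labels, labels) \
                and new_medoids == medoids
            labels, medoids, objective = new_labels, new_medoids, new_objective
            if converged:
                break
        return labels, medoids, objective, it

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of planar coordinates")
        n, k = len(X), self.n_clusters
        if k <= 0 or k > n:
            raise ValueError(f"n_clusters must be in [1, n]; got k={k}, n={n}")
        if len(np.unique(X, axis=0)) < n:
            import warnings
            warnings.warn("duplicate points supplied to BalancedKMedoids", stacklevel=2)

        D = cdist(X, X)
        order = _lex_order(X)
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)

        from math import comb
        if comb(n, k) <= 1000:
            # exact: the best optimal balanced assignment over all medoid sets,
            # followed by one medoid update, attains the partition optimum
            import itertools as _it
            best = None
            total_iter = 0
            for combo in _it.combinations(order.tolist(), k):
                medoids0 = sorted(combo, key=lambda i: rank[i])
                labels, medoids, objective, it = self._alternate(D, medoids0, rank, k, 2)
                total_iter += it
                key = (objective, tuple(sorted(rank[m] for m in medoids)))
                if best is None or key < best[0]:
                    best = (key, labels, medoids, objective)
        else:
            # anchors at evenly spaced coordinate ranks -> permutation-invariant restarts
            n_restarts = max(1, min(self.n_restarts, n))
            anchors = [int(order[round(i * n / n_restarts)]) for i in range(n_restarts)]
            best = None
            total_iter = 0
            for anchor in dict.fromkeys(anchors):
                medoids0 = _farthest_point_init(D, k, rank, anchor)
                medoids0 = sorted(medoids0, key=lambda i: rank[i])
                labels, medoids, objective, it = self._alternate(D, medoids0, rank, k,
                                                                 self.max_iter)
                total_iter += it
                key = (objective, tuple(sorted(rank[m] for m in medoids)))
                if best is None or key < best[0]:
                    best = (key, labels, medoids, objective)
        _, labels, medoids, objective = best

        # final relabel so cluster ids follow medoid coordinate order
        perm = np.argsort([rank[m] for m in medoids], kind="mergesort")
        medoids = [medoids[c] for c in perm]
        remap = np.empty(k, dtype=int)
        remap[perm] = np.arange(k)
        labels = remap[labels]

        self.labels_ = labels
        self.medoid_indices_ = np.asarray(medoids)
        self.cluster_centers_ = X[self.medoid_indices_]
        self.inertia_ = objective
        self.n_iter_ = total_iter
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "cluster_centers_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.argmin(cdist(X, self.cluster_centers_), axis=1)


def balanced_kmedoids(points, k: int, seed: int | None = None, max_iter: int = 50) -> SitePlan:
    """Functional wrapper around :class:`BalancedKMedoids`."""
    est = BalancedKMedoids(n_clusters=k, max_iter=max_iter, random_state=seed).fit(points)
    return SitePlan(
        k=k,
        medoid_indices=est.medoid_indices_,
        medoids=est.cluster_centers_,
        labels=est.labels_,
        objective=est.inertia_,
    )


def stratified_site_split(
    points,
    industry_points,
    k: int = 62,
    inner_fraction: float = 0.5,
    radius_km: float = 3.0,
    seed: int | None = None,
    max_iter: int = 50,
) -> SitePlan:
    """Site design with a quota of sites near the main industries.

    ``ceil(inner_fraction * k)`` sites are chosen by balanced k-medoids among
    the points within ``radius_km`` of any industry point, the remainder among
    the points outside; the union is returned (default: half of 62 sites
    within 3 km).
    """
    points = np.asarray(points, dtype=float)
    if not (0.0 <= inner_fraction <= 1.0):
        raise ValueError("inner_fraction must be in [0, 1]")
    if inner_fraction == 0.0:
        return balanced_kmedoids(points, k, seed=seed, max_iter=max_iter)
    industry_points = np.atleast_2d(np.asarray(industry_points, dtype=float))
    d = cdist(points, industry_points).min(axis=1)
    inner = d <= radius_km
    k_inner = int(np.ceil(inner_fraction * k))
    k_outer = k - k_inner
    if inner.all() or k_outer == 0:
        if k_outer > 0 and not (~inner).any():
            raise ValueError(f"outer partition empty but {k_outer} site(s) allocated to it")
        return balanced_kmedoids(points, k, seed=seed, max_iter=max_iter)
    for name, mask, kk in (("inner", inner, k_inner), ("outer", ~inner, k_outer)):
        if kk > 0 and mask.sum() == 0:
            raise ValueError(f"{name} partition is empty but {kk} site(s) allocated "
                             f"(inner={int(inner.sum())}, outer={int((~inner).sum())})")
        if kk > mask.sum():
            raise ValueError(f"{name} partition has {int(mask.sum())} points < {kk} sites")

    idx_in = np.flatnonzero(inner)
    idx_out = np.flatnonzero(~inner)
    plan_in = balanced_kmedoids(points[idx_in], k_inner, seed=seed, max_iter=max_iter)
    plan_out = balanced_kmedoids(points[idx_out], k_outer, seed=seed, max_iter=max_iter)

    labels = np.empty(len(points), dtype=int)
    labels[idx_in] = plan_in.labels
    labels[idx_out] = plan_out.labels + k_inner
    medoid_idx = np.concatenate([idx_in[plan_in.medoid_indices], idx_out[plan_out.medoid_indices]])
    return SitePlan(
        k=k,
        medoid_indices=medoid_idx,
        medoids=points[medoid_idx],
        labels=labels,
        objective=plan_in.objective + plan_out.objective,
    )
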