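"""PAM (k-medoids) clustering of temporal profiles, k by best silhouette.

The classic Kaufman-Rousseeuw algorithm: a greedy BUILD phase chooses
initial medoids one at a time to maximally reduce total dissimilarity,
then the SWAP phase repeatedly performs the single (medoid, non-medoid)
exchange that most lowers the objective until no exchange improves it.
The objective — the sum over points of the dissimilarity to their
nearest medoid — never increases during SWAP.  Ties are broken toward
the lowest index so results are reproducible.

The number of clusters is selected by scanning a k range and keeping
the model with the best mean silhouette width, per-point
``(b - a) / max(a, b)`` where ``a`` is the mean dissimilarity to the
point's own cluster and ``b`` the smallest mean dissimilarity to
another cluster.

Profiles are per-feature vectors of per-ZT means (days and replicates
collapsed), z-scored per row by default so distances reflect the shape
(phase) of the daily profile rather than its amplitude or baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances, silhouette_samples

from .errors import ConfigurationError, InsufficientDataError
from .timecourse import TimeCourse

_OBJECTIVE_TOL = 1e-10


@dataclass
class ClusterModel:
    """A fitted k-medoids model (optionally the winner of a k scan)."""

    k: int
    medoids: list            # feature ids of the medoids
    medoid_indices: np.ndarray
    labels: np.ndarray       # cluster index per feature (0..k-1)
    feature_ids: list
    objective: float         # total dissimilarity to nearest medoids
    metric: str = "euclidean"
    silhouette: np.ndarray | None = None
    mean_silhouette: float | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def assignments(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"cluster": self.labels}, index=pd.Index(self.feature_ids, name="feature_id")
        )
        if self.silhouette is not None:
            out["silhouette"] = self.silhouette
        return out


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigurationError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ConfigurationError("dissimilarity matrix must be symmetric")
    if (D < 0).any() or not np.allclose(np.diag(D), 0.0):
        raise ConfigurationError("dissimilarities must be >= 0 with a zero diagonal")
    return D


def _build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        reduction[medoids] = -np.inf
        nxt = int(np.argmax(reduction))  # argmax keeps the lowest index on ties
        medoids.append(nxt)
        nearest = np.minimum(nearest, D[:, nxt])
    return medoids


def _nearest(D: np.ndarray, medoids: list[int]):
    n = D.shape[0]
    Dm = D[:, medoids]
    order = np.argsort(Dm, axis=1, kind="stable")
    nearest_pos = order[:, 0]
    d1 = Dm[np.arange(n), nearest_pos]
    d2 = Dm[np.arange(n), order[:, 1]]
    return nearest_pos, d1, d2


def _swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Best-improvement SWAP iterations from the given start, to convergence."""
    medoids = list(medoids)
    nearest_pos, d1, d2 = _nearest(D, medoids)
    cost = d1.sum()
    while True:
        best = (0.0, None, None)
        for j in range(len(medoids)):
            # distance to nearest medoid once medoid j is removed
            d_no_m = np.where(nearest_pos == j, d2, d1)
            cand_cost = np.minimum(d_no_m[:, None], D).sum(axis=0)
            cand_cost[medoids] = np.inf
            x = int(np.argmin(cand_cost))
            delta = cand_cost[x] - cost
            if delta < best[0] - _OBJECTIVE_TOL:
                best = (delta, j, x)
        if best[1] is None:
            return medoids, float(cost)
        _, j, x = best
        medoids[j] = x
        nearest_pos, d1, d2 = _nearest(D, medoids)
        new_cost = d1.sum()
        assert new_cost <= cost + _OBJECTIVE_TOL, "SWAP must not increase the objective"
        cost = new_cost


def pam(
    D,
    k: int,
    feature_ids=None,
    metric: str = "precomputed",
    seed: int = 0,
    n_starts: int = 10,
) -> ClusterModel:
    """PAM on a precomputed dissimilarity matrix.

    Runs BUILD initialisation followed by best-improvement SWAP
    iterations to convergence, then repeats SWAP from ``n_starts - 1``
    seeded random medoid sets and keeps the lowest objective (SWAP is a
    local search; the extra starts guard against its local optima).
    Deterministic given ``seed`` (ties toward the lowest index /
    earliest start).
    """
    D = _check_dissimilarity(D)
    n = D.shape[0]
    if not 2 <= k < n:
        raise ConfigurationError(f"k must satisfy 2 <= k < n={n}, got {k}")
    if n_starts < 1:
        raise ConfigurationError(f"n_starts must be >= 1, got {n_starts}")
    if feature_ids is None:
        feature_ids = list(range(n))
    feature_ids = list(feature_ids)

    starts = [_build(D, k)]
    rng = np.random.default_rng(seed)
    starts += [sorted(rng.choice(n, size=k, replace=False)) for _ in range(n_starts - 1)]

    medoids, cost = None, np.inf
    for start in starts:
        cand_medoids, cand_cost = _swap(D, start)
        if cand_cost < cost - _OBJECTIVE_TOL:
            medoids, cost = cand_medoids, cand_cost

    nearest_pos, _, _ = _nearest(D, medoids)
    labels = nearest_pos.copy()
    labels[medoids] = np.arange(k)  # each medoid belongs to its own cluster
    return ClusterModel(
        k=k,
        medoids=[feature_ids[m] for m in medoids],
        medoid_indices=np.asarray(medoids),
        labels=labels,
        feature_ids=feature_ids,
        objective=float(cost),
        metric=metric,
    )


def select_k(
    profiles: pd.DataFrame,
    k_range=range(2, 11),
    metric: str = "euclidean",
    seed: int = 0,
) -> ClusterModel:
    """Scan k, fit PAM for each, keep the best mean silhouette (ties: smallest k)."""
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 3:
        raise InsufficientDataError("need at least 3 profiles to scan k")
    if (X == X[0]).all():
        raise ConfigurationError("all profiles identical: silhouette undefined")
    feature_ids = (
        list(profiles.index) if isinstance(profiles, pd.DataFrame) else list(range(len(X)))
    )
    D = pairwise_distances(X, metric=metric)
    np.fill_diagonal(D, 0.0)

    best_model, by_k = None, {}
    for k in k_range:
        if k >= X.shape[0]:
            break
        model = pam(D, k, feature_ids=feature_ids, metric=metric, seed=seed)
        sil = silhouette_samples(D, model.labels, metric="precomputed")
        model.silhouette = sil
        model.mean_silhouette = float(sil.mean())
        by_k[k] = model.mean_silhouette
        if best_model is None or model.mean_silhouette > best_model.mean_silhouette:
            best_model = model
    if best_model is None:
        raise ConfigurationError("k_range contained no feasible k")
    best_model.silhouette_by_k = by_k
    return best_model


def profile_matrix(
    tc: TimeCourse,
    feature_ids=None,
    condition: str | None = None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature ZT-mean profiles, optionally z-scored per row.

    Days and replicates at the same ZT are averaged.  Returns the
    profile matrix (features x sorted ZT) and a flag series marking
    constant features, which cannot be standardised (their rows are
    left at zero when ``standardize`` is on).
    """
    if condition is not None:
        tc = tc.subset_condition(condition)
    if feature_ids is not None:
        tc = tc.subset_features(feature_ids)
    zts = np.unique(tc.times)
    means = pd.DataFrame(
        {f"ZT{zt:g}": tc.values.loc[:, tc.times == zt].mean(axis=1) for zt in zts}
    )
    if means.isna().any().any():
        raise ConfigurationError("a timepoint has no samples for some feature")
    mat = means.to_numpy()
    sd = mat.std(axis=1)
    constant = sd == 0
    if standardize:
        sd_safe = np.where(constant, 1.0, sd)
        mat = (mat - mat.mean(axis=1, keepdims=True)) / sd_safe[:, None]
        mat[constant] = 0.0
        means = pd.DataFrame(mat, index=means.index, columns=means.columns)
    return means, pd.Series(constant, index=means.index, name="constant")
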