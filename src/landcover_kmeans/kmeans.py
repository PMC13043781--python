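"""From-scratch Lloyd's K-means with Euclidean distance.

This is the clustering core of the toolkit, written out in full rather than
delegated to a library, because its exact behaviour (Forgy initialization
seeded for reproducibility, lowest-index tie-breaking, deterministic
empty-cluster repair, explicit convergence tolerance) is part of the
method's contract. The estimator follows the scikit-learn API (``fit``,
``predict``, ``fit_predict``, trailing-underscore fitted attributes) and
composes with sklearn pipelines and model selection.

Algorithm (Lloyd's iteration):

1. choose K;
2. initialize the K centroids from randomly chosen data points;
3. assign each point to the nearest centroid by Euclidean distance;
4. recompute each centroid as the mean of its assigned points;
5. repeat 3-4 until the centroids no longer change (maximum per-coordinate
   displacement <= ``tol``) or ``max_iter`` is reached.

Distances are compared on their squares internally (a monotone transform),
but :func:`euclidean_distance` returns the true root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import ValidationError


def euclidean_distance(x, c) -> float:
    """Euclidean distance between two equal-length vectors.

    d(x, c) = sqrt(sum_k (x_k - c_k)^2); symmetric, zero iff x == c.
    """
    x = np.asarray(x, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    if x.shape != c.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {c.shape}")
    return float(np.sqrt(np.sum((x - c) ** 2)))


def _sq_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(n, K) matrix of squared Euclidean distances."""
    diff = points[:, None, :] - centroids[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def assign(points, centroids) -> np.ndarray:
    """Map each point to its nearest centroid (ties -> lowest index)."""
    points = np.asarray(points, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    if points.ndim != 2 or centroids.ndim != 2:
        raise ValidationError("points and centroids must be 2-D arrays")
    if points.shape[1] != centroids.shape[1]:
        raise ValidationError(
            f"dimension mismatch: points have d={points.shape[1]}, "
            f"centroids d={centroids.shape[1]}"
        )
    # np.argmin returns the first (lowest-index) minimiser, our tie rule
    return np.argmin(_sq_distances(points, centroids), axis=1)


@dataclass
class ClusterModel:
    """Frozen result of a K-means fit."""

    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    n_iter: int
    seed: int | None
    converged: bool
    inertia_history: list


class KMeans(ClusterMixin, BaseEstimator):
    """Lloyd's K-means clusterer.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K (3 for the land-cover use case: background,
        soil, crops).
    max_iter : int
        Iteration cap for the assign/update loop.
    tol : float
        Convergence threshold on the maximum absolute per-coordinate
        centroid displacement between iterations.
    random_state : int or None
        Seed for Forgy initialization (K distinct input points sampled
        without replacement). Same seed, same data => bit-identical model.
    n_init : int
        Number of restarts with seeds random_state, random_state + 1, ...;
        the run with the lowest final inertia wins. Lloyd's iteration only
        finds a local optimum, so restarts are the standard safeguard —
        with a dominant class (say 70% of pixels) a single random init
        often places two centroids inside it and splits it.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (K, d)
    labels_ : ndarray of shape (n,)
        Assignment of each training point (ties -> lowest centroid index).
    inertia_ : float
        Sum of squared distances of points to their assigned centroid.
    n_iter_ : int
    converged_ : bool
    inertia_history_ : list of float
        Objective value after each assignment step; non-increasing.
    """

    def __init__(self, n_clusters: int = 3, max_iter: int = 300,
                 tol: float = 1e-4, random_state: int | None = 0,
                 n_init: int = 1, init=None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.n_init = n_init
        self.init = init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D (n_samples, n_features) array")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        n, _ = X.shape
        k = self.n_clusters
        if k < 1:
            raise ValidationError("n_clusters must be >= 1")
        if k > n:
            raise ValidationError(f"n_clusters={k} exceeds n_samples={n}")
        if self.tol < 0:
            raise ValidationError("tol must be non-negative")
        if self.n_init < 1:
            raise ValidationError("n_init must be >= 1")

        if self.init is not None:
            # explicit starting centroids: one deterministic run, no restarts
            centroids = np.array(self.init, dtype=np.float64)
            if centroids.shape != (k, X.shape[1]):
                raise ValidationError(
                    f"init must have shape ({k}, {X.shape[1]}), got {centroids.shape}")
        elif self.n_init > 1:
            base = 0 if self.random_state is None else self.random_state
            best = None
            for r in range(self.n_init):
                run = KMeans(n_clusters=k, max_iter=self.max_iter, tol=self.tol,
                             random_state=base + r, n_init=1).fit(X)
                if best is None or run.inertia_ < best.inertia_:
                    best = run
            for attr in ("cluster_centers_", "labels_", "inertia_", "n_iter_",
                         "converged_", "inertia_history_"):
                setattr(self, attr, getattr(best, attr))
            return self
        else:
            rng = np.random.default_rng(self.random_state)
            centroids = X[rng.choice(n, size=k, replace=False)].copy()

        history: list[float] = []
        labels = np.zeros(n, dtype=np.intp)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            sq = _sq_distances(X, centroids)
            labels = np.argmin(sq, axis=1)
            history.append(float(sq[np.arange(n), labels].sum()))

            new_centroids = centroids.copy()
            counts = np.bincount(labels, minlength=k)
            for j in range(k):
                if counts[j] > 0:
                    new_centroids[j] = X[labels == j].mean(axis=0)
            # deterministic empty-cluster repair: move each empty centroid to
            # the point currently farthest from its assigned centroid
            empties = np.flatnonzero(counts == 0)
            if empties.size:
                point_sq = sq[np.arange(n), labels].copy()
                for j in empties:
                    far = int(np.argmax(point_sq))
                    new_centroids[j] = X[far]
                    point_sq[far] = -1.0  # each repair takes a distinct point

            shift = float(np.max(np.abs(new_centroids - centroids)))
            centroids = new_centroids
            if shift <= self.tol:
                converged = True
                break

        # make labels and inertia consistent with the final centroids
        sq = _sq_distances(X, centroids)
        labels = np.argmin(sq, axis=1)
        inertia = float(sq[np.arange(n), labels].sum())
        history.append(inertia)

        self.cluster_centers_ = centroids
        self.labels_ = labels
        self.inertia_ = inertia
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.inertia_history_ = history
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise ValidationError("KMeans instance is not fitted yet")
        return assign(X, self.cluster_centers_)

    def to_model(self) -> ClusterModel:
        """Snapshot the fitted state as an immutable :class:`ClusterModel`."""
        if not hasattr(self, "cluster_centers_"):
            raise ValidationError("KMeans instance is not fitted yet")
        return ClusterModel(
            centroids=self.cluster_centers_.copy(),
            assignments=self.labels_.copy(),
            inertia=self.inertia_,
            n_iter=self.n_iter_,
            seed=self.random_state,
            converged=self.converged_,
            inertia_history=list(self.inertia_history_),
        )


def kmeans_fit(points, k: int, seed: int | None = 0, max_iter: int = 300,
               tol: float = 1e-4) -> ClusterModel:
    """Functional wrapper: fit Lloyd's K-means and return a ClusterModel."""
    est = KMeans(n_clusters=k, max_iter=max_iter, tol=tol, random_state=seed)
    return est.fit(points).to_model()


def kmeans_best_of(points, k: int, n_restarts: int, seed: int = 0,
                   max_iter: int = 300, tol: float = 1e-4) -> ClusterModel:
    """Run seeded restarts seed, seed+1, ... and keep the lowest inertia."""
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    best = None
    for r in range(n_restarts):
        model = kmeans_fit(points, k, seed=seed + r, max_iter=max_iter, tol=tol)
        if best is None or model.inertia < best.inertia:
            best = model
    return best
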