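"""Clustering backends with a uniform partition contract.

Every backend is a callable ``backend(X, n_clusters, rng) -> labels`` that
partitions the rows of ``X`` into exactly ``n_clusters`` non-empty clusters,
labelled 0..K-1. Backends are looked up by name in :data:`BACKENDS`;
registering a new one requires nothing beyond this contract — the scoring
code never inspects backend internals.

Shipped backends:

``kmeans``
    Lloyd's algorithm (squared-Euclidean distance) with k-means++
    initialisation, best within-cluster sum of squares over 10 restarts.
    All restarts are run batched in vectorised numpy, which keeps the
    per-call cost low on the small progeny sets the algorithm
    re-clusters thousands of times; a test cross-checks it against
    scikit-learn's KMeans.
``ward``
    Agglomerative hierarchical clustering with Ward linkage on Euclidean
    distance, dendrogram cut at ``n_clusters`` groups.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.cluster import AgglomerativeClustering

__all__ = ["BACKENDS", "BackendError", "cluster", "register_backend"]

# empty clusters or non-convergence trigger a fresh initialisation
_MAX_RETRIES = 10

_KMEANS_RESTARTS = 10
_KMEANS_MAX_ITER = 300
_KMEANS_TOL = 1e-4


class BackendError(RuntimeError):
    """A clustering backend failed to produce a valid partition."""


def _kmeanspp_init(
    X: np.ndarray, n_clusters: int, n_restarts: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding for all restarts at once; returns (R, K, d)."""
    n, d = X.shape
    centers = np.empty((n_restarts, n_clusters, d))
    first = rng.integers(0, n, size=n_restarts)
    centers[:, 0] = X[first]
    # closest squared distance of each point to the chosen centers, per restart
    d2 = ((X[None, :, :] - centers[:, 0, None, :]) ** 2).sum(-1)
    for c in range(1, n_clusters):
        total = d2.sum(axis=1)
        # degenerate restart (all points coincide with centers): fall back
        # to a uniform draw
        probs = np.where(total[:, None] > 0, d2 / np.maximum(total, 1e-300)[:, None], 1.0 / n)
        cum = probs.cumsum(axis=1)
        u = rng.random(n_restarts)
        idx = np.minimum((cum < u[:, None]).sum(axis=1), n - 1)
        centers[:, c] = X[idx]
        new_d2 = ((X[None, :, :] - centers[:, c, None, :]) ** 2).sum(-1)
        np.minimum(d2, new_d2, out=d2)
    return centers


def _kmeans_backend(
    X: np.ndarray, n_clusters: int, rng: np.random.Generator
) -> np.ndarray:
    """Lloyd's algorithm, best WCSS over restarts run batched.

    All restarts iterate simultaneously as stacked numpy operations;
    a restart whose centers move less than ``_KMEANS_TOL`` (relative to
    the data scale) is converged, and iteration stops when all are.
    Restarts left with an empty cluster are discarded at selection time.
    """
    n, d = X.shape
    centers = _kmeanspp_init(X, n_clusters, _KMEANS_RESTARTS, rng)
    x2 = (X**2).sum(axis=1)
    tol = _KMEANS_TOL * float(X.var(axis=0).sum())
    labels = None
    for _ in range(_KMEANS_MAX_ITER):
        # squared distances (R, n, K) via ||x||^2 - 2 x.c + ||c||^2
        d2 = (
            x2[None, :, None]
            - 2.0 * np.einsum("nd,rkd->rnk", X, centers)
            + (centers**2).sum(-1)[:, None, :]
        )
        labels = d2.argmin(axis=2)  # (R, n)
        onehot = labels[:, :, None] == np.arange(n_clusters)  # (R, n, K)
        counts = onehot.sum(axis=1).astype(np.float64)  # (R, K)
        sums = np.einsum("rnk,nd->rkd", onehot, X)
        new_centers = np.where(
            counts[:, :, None] > 0,
            sums / np.maximum(counts, 1.0)[:, :, None],
            centers,
        )
        shift = ((new_centers - centers) ** 2).sum(-1).max()
        centers = new_centers
        if shift <= tol:
            break
    # WCSS per restart; drop restarts with empty clusters
    d2 = (
        x2[None, :, None]
        - 2.0 * np.einsum("nd,rkd->rnk", X, centers)
        + (centers**2).sum(-1)[:, None, :]
    )
    labels = d2.argmin(axis=2)
    inertia = np.take_along_axis(d2, labels[:, :, None], axis=2).sum(axis=(1, 2))
    valid = np.array(
        [len(np.unique(labels[r])) == n_clusters for r in range(_KMEANS_RESTARTS)]
    )
    if not valid.any():
        raise BackendError("k-means produced an empty cluster in every restart")
    inertia[~valid] = np.inf
    best = int(inertia.argmin())
    return labels[best].astype(np.int64)


def _ward_backend(X: np.ndarray, n_clusters: int, rng: np.random.Generator) -> np.ndarray:
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(X).astype(np.int64)


BACKENDS: dict[str, Callable[[np.ndarray, int, np.random.Generator], np.ndarray]] = {
    "kmeans": _kmeans_backend,
    "ward": _ward_backend,
}


def register_backend(name: str, fn: Callable) -> None:
    """Register a clustering backend under ``name``.

    ``fn(X, n_clusters, rng)`` must return integer labels 0..n_clusters-1
    with every cluster non-empty (or raise :class:`BackendError`).
    """
    BACKENDS[name] = fn


def cluster(
    X: np.ndarray,
    n_clusters: int,
    method: str = "kmeans",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Partition the rows of ``X`` into exactly ``n_clusters`` groups.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
    n_clusters : int
        Number of clusters K, with 2 <= K <= n_samples.
    method : str
        Backend name registered in :data:`BACKENDS`.
    rng : numpy Generator, int seed, or None
        Source of randomness for stochastic backends. Ward is
        deterministic and ignores it.

    Returns
    -------
    labels : ndarray of shape (n_samples,)
        Integer labels in ``[0, n_clusters)``; every cluster non-empty.

    Raises
    ------
    ValueError
        If ``n_clusters`` is out of range or the method is unknown.
    BackendError
        If the backend still returns an invalid partition after retries.
    """
    X = np.asarray(X, dtype=np.float64)
    if n_clusters < 1 or n_clusters > X.shape[0]:
        raise ValueError(
            f"n_clusters must be in [1, {X.shape[0]}], got {n_clusters}"
        )
    try:
        backend = BACKENDS[method]
    except KeyError:
        raise ValueError(
            f"unknown clustering method {method!r}; "
            f"available: {sorted(BACKENDS)}"
        ) from None
    rng = np.random.default_rng(rng)

    last_error: Exception | None = None
    for _ in range(_MAX_RETRIES):
        try:
            labels = np.asarray(backend(X, n_clusters, rng))
        except BackendError as exc:  # degenerate run; retry with fresh init
            last_error = exc
            continue
        if len(np.unique(labels)) == n_clusters:
            return labels.astype(np.int64)
        last_error = BackendError(
            f"backend {method!r} returned fewer than {n_clusters} clusters"
        )
    raise BackendError(
        f"backend {method!r} failed to produce {n_clusters} non-empty "
        f"clusters after {_MAX_RETRIES} retries"
    ) from last_error
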