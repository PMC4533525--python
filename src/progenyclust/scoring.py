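"""Core stability scoring: progeny sampling, co-occurrence, stability score.

The inner loop of progeny clustering. For a candidate cluster number K the
data are clustered once, then R times a set of "progenies" — imaginary
samples built by drawing each feature independently from the members of one
cluster — is generated, pooled and re-clustered. How reproducibly progenies
return to their cluster of origin is summarised in a co-occurrence
probability matrix P and condensed into a stability score S: the ratio of
true-classification to false-classification probability.

Progenies from cluster k occupy the contiguous row block
``[k*n, (k+1)*n)`` of the progeny matrix, so P splits into K diagonal
"true" blocks and (K-1)*K off-diagonal "false" blocks.
"""

from __future__ import annotations

import numpy as np

from .backends import cluster
from .config import RunConfig

__all__ = [
    "sample_progenies",
    "cooccurrence_matrix",
    "aggregate_cooccurrence",
    "stability_score",
    "stability_curve",
]


def _check_partition(labels: np.ndarray, n_samples: int) -> int:
    labels = np.asarray(labels)
    if labels.shape != (n_samples,):
        raise ValueError(
            f"labels have shape {labels.shape}, expected ({n_samples},)"
        )
    k = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any() or labels.min() < 0:
        raise ValueError(
            "invalid assignment: labels must cover 0..K-1 with every "
            "cluster non-empty"
        )
    return k


def sample_progenies(
    X: np.ndarray,
    labels: np.ndarray,
    n_progenies: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_progenies`` feature-independent resamples per cluster.

    For each progeny of cluster k, every feature value is drawn uniformly
    with replacement from that feature's values among the members of
    cluster k; features are drawn independently of one another.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
    labels : ndarray of shape (n_samples,)
        Cluster labels 0..K-1; every cluster must be non-empty.
    n_progenies : int
        Progenies per cluster (n >= 1).
    rng : numpy Generator

    Returns
    -------
    progenies : ndarray of shape (K * n_progenies, n_features)
        Block-contiguous: rows ``[k*n, (k+1)*n)`` stem from cluster k.
    block_of : ndarray of shape (K * n_progenies,)
        Source cluster of each progeny row.
    """
    X = np.asarray(X, dtype=np.float64)
    if n_progenies < 1:
        raise ValueError(f"n_progenies must be >= 1, got {n_progenies}")
    n_clusters = _check_partition(labels, X.shape[0])
    n_features = X.shape[1]

    blocks = []
    for k in range(n_clusters):
        members = X[labels == k]
        # independent row index per (progeny, feature) cell
        idx = rng.integers(0, members.shape[0], size=(n_progenies, n_features))
        blocks.append(members[idx, np.arange(n_features)])
    progenies = np.vstack(blocks)
    block_of = np.repeat(np.arange(n_clusters), n_progenies)
    return progenies, block_of


def cooccurrence_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary co-occurrence matrix Q of one re-clustering.

    ``Q[i, j] = 1`` iff progenies i and j received the same label.
    Symmetric with unit diagonal by construction.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    return (labels[:, None] == labels[None, :]).astype(np.uint8)


def aggregate_cooccurrence(qs: list[np.ndarray]) -> np.ndarray:
    """Entrywise mean of R co-occurrence matrices: the probability matrix P."""
    if len(qs) == 0:
        raise ValueError("need at least one co-occurrence matrix")
    shape = qs[0].shape
    for q in qs:
        if q.shape != shape:
            raise ValueError(
                f"co-occurrence matrices differ in shape: {q.shape} vs {shape}"
            )
    p = np.mean([np.asarray(q, dtype=np.float64) for q in qs], axis=0)
    return p


def _block_masks(n_clusters: int, n_progenies: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the true region (diagonal blocks minus the diagonal
    itself) and the false region (everything outside the diagonal blocks)."""
    block = np.repeat(np.arange(n_clusters), n_progenies)
    same_block = block[:, None] == block[None, :]
    eye = np.eye(len(block), dtype=bool)
    return same_block & ~eye, ~same_block


def stability_score(
    P: np.ndarray,
    n_clusters: int,
    n_progenies: int,
    n_repeats: int,
) -> float:
    """Stability score S of a co-occurrence probability matrix.

    S = (mean of true-block entries, diagonal self-pairs excluded)
        / (mean of false-block entries).

    Diagonal entries are identically 1 and carry no information, so they
    are excluded; means rather than sums make S invariant to block size.
    A perfectly reproducible clustering has true mean 1 and false mean 0.
    To keep S finite the denominator is floored at
    ``eps = 1 / (n_repeats * n_false)`` where ``n_false`` is the number of
    false-region entries — one chance co-occurrence in R rounds, the
    smallest resolvable probability.

    Parameters
    ----------
    P : ndarray of shape (K*n, K*n)
        Co-occurrence probability matrix, block-contiguous.
    n_clusters, n_progenies : int
        Block structure K and n. ``n_progenies`` must be >= 2.
    n_repeats : int
        Number of repetitions R that produced P (sets the floor eps).

    Returns
    -------
    float
        S >= 0, finite.
    """
    P = np.asarray(P, dtype=np.float64)
    if n_progenies < 2:
        raise ValueError(
            "n_progenies must be >= 2: the true blocks are empty after "
            "excluding the diagonal when n == 1"
        )
    m = n_clusters * n_progenies
    if P.shape != (m, m):
        raise ValueError(f"P has shape {P.shape}, expected ({m}, {m})")
    true_mask, false_mask = _block_masks(n_clusters, n_progenies)
    n_false = int(false_mask.sum())  # (K-1) * K * n^2
    eps = 1.0 / (n_repeats * n_false)
    true_mean = float(P[true_mask].mean())
    false_mean = max(float(P[false_mask].mean()), eps)
    return true_mean / false_mean


def _score_one_k(
    X: np.ndarray,
    k: int,
    config: RunConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[float, np.ndarray]:
    """Stability score for one candidate K; returns (S, initial labels).

    The full dataset is clustered once; each of the R repetitions then
    samples fresh progenies and re-clusters the pooled set into the same K
    with the same method. Q matrices are accumulated into a running sum
    (equivalent to, but cheaper than, storing all R of them).
    """
    ss_init, ss_rep = seed_seq.spawn(2)
    rng_init = np.random.default_rng(ss_init)
    labels = cluster(X, k, method=config.method, rng=rng_init)

    m = k * config.n_progenies
    q_sum = np.zeros((m, m), dtype=np.float64)
    rng_rep = np.random.default_rng(ss_rep)
    for _ in range(config.n_repeats):
        progenies, _ = sample_progenies(X, labels, config.n_progenies, rng_rep)
        prog_labels = cluster(progenies, k, method=config.method, rng=rng_rep)
        np.add(q_sum, prog_labels[:, None] == prog_labels[None, :], out=q_sum)
    p = q_sum / config.n_repeats
    s = stability_score(p, k, config.n_progenies, config.n_repeats)
    return s, labels


def stability_curve(
    X: np.ndarray,
    config: RunConfig,
    seed_seq: np.random.SeedSequence | int | None = None,
    return_assignments: bool = False,
):
    """Stability score S_K for every candidate K in ``[k_min, k_max]``.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
    config : RunConfig
    seed_seq : numpy SeedSequence, int, or None
        Master entropy for this curve. One child sequence is spawned per
        candidate K; within each, separate streams drive the initial
        clustering and the repetition loop, so the curve is reproducible.
    return_assignments : bool
        If True also return the per-K initial cluster assignment of the
        full dataset.

    Returns
    -------
    scores : dict mapping K -> S_K
    assignments : dict mapping K -> labels (only if ``return_assignments``)
    """
    X = np.asarray(X, dtype=np.float64)
    config.validate(n_samples=X.shape[0])
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    scores: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k, child in zip(config.k_values, seed_seq.spawn(len(config.k_values))):
        scores[k], assignments[k] = _score_one_k(X, k, config, child)
    if return_assignments:
        return scores, assignments
    return scores
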