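"""Reference datasets, score correction, and the two selection criteria.

Stability scores have an inherent bias: even structureless data scores
higher at some cluster numbers than others (on uniform noise the score
grows roughly linearly with K, since more clusters build stronger
identities by splitting the data into smaller pieces). Monte-Carlo
reference datasets — uniform resamples of the feature ranges — estimate
this bias so it can be subtracted out.

Two criteria pick the optimal K:

* greatest score: argmax of the reference-corrected difference
  ``D_K = S_K - mean_t S_ref[t, K]``;
* greatest gap: argmax of the discrete second difference
  ``2*S_K - S_{K-1} - S_{K+1}`` over interior K. Because reference scores
  are near-linear in K, their gaps cancel, so this criterion needs no
  reference datasets at all and is much cheaper.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .scoring import stability_curve

logger = logging.getLogger(__name__)

__all__ = [
    "generate_reference",
    "reference_curves",
    "score_difference",
    "gap_curve",
    "select_greatest_score",
    "select_greatest_gap",
    "score_stability_sd",
]


def generate_reference(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one reference dataset from the data's bounding box.

    Each column j is drawn i.i.d. uniform on ``[min_j, max_j]`` of the
    original column. A constant column yields a constant reference column.
    """
    X = np.asarray(X, dtype=np.float64)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    constant = lo == hi
    if constant.any():
        logger.info(
            "reference generation: %d constant column(s) replicated as-is",
            int(constant.sum()),
        )
    return rng.uniform(lo, hi, size=X.shape)


def reference_curves(
    X: np.ndarray,
    config: RunConfig,
    seed_seq: np.random.SeedSequence | int | None = None,
) -> tuple[np.ndarray, dict[int, float]]:
    """Score T reference datasets with the same core algorithm.

    Returns
    -------
    curves : ndarray of shape (T, n_k)
        Stability score of each reference dataset at each candidate K
        (columns ordered k_min..k_max).
    mean_curve : dict mapping K -> mean reference score
    """
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    k_values = config.k_values
    curves = np.empty((config.n_references, len(k_values)))
    for t, child in enumerate(seed_seq.spawn(config.n_references)):
        ss_data, ss_curve = child.spawn(2)
        ref = generate_reference(X, np.random.default_rng(ss_data))
        scores = stability_curve(ref, config, ss_curve)
        curves[t] = [scores[k] for k in k_values]
    mean_curve = dict(zip(k_values, curves.mean(axis=0)))
    return curves, mean_curve


def score_difference(
    scores: dict[int, float],
    reference_mean: dict[int, float],
    log_ratio: bool = False,
) -> dict[int, float]:
    """Reference-corrected score curve ``D_K = S_K - mean reference S_K``.

    With ``log_ratio=True`` the comparison is made on the log scale,
    ``log(S_K) - log(ref_K)``, i.e. the log of the score ratio.
    """
    if set(scores) != set(reference_mean):
        raise ValueError(
            "score curve and reference mean curve cover different K ranges"
        )
    if log_ratio:
        return {
            k: float(np.log(scores[k]) - np.log(reference_mean[k]))
            for k in sorted(scores)
        }
    return {k: scores[k] - reference_mean[k] for k in sorted(scores)}


def gap_curve(scores: dict[int, float]) -> dict[int, float]:
    """Discrete second difference ``2*S_K - S_{K-1} - S_{K+1}``.

    Defined only at interior K; a curve of fewer than three points has no
    interior. Exactly zero everywhere on an affine score curve.
    """
    ks = sorted(scores)
    if len(ks) < 3:
        raise ValueError("gap curve requires at least three K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("score curve must cover consecutive K values")
    return {
        k: 2.0 * scores[k] - scores[k - 1] - scores[k + 1] for k in ks[1:-1]
    }


def _argmax_smallest_k(curve: dict[int, float]) -> int:
    if not curve:
        raise ValueError("empty curve")
    best_k = min(curve)
    for k in sorted(curve):
        if curve[k] > curve[best_k]:
            best_k = k
    return best_k


def select_greatest_score(diff: dict[int, float]) -> int:
    """K maximising the score difference; ties go to the smallest K."""
    return _argmax_smallest_k(diff)


def select_greatest_gap(gap: dict[int, float]) -> int:
    """K maximising the gap; ties go to the smallest K.

    Only interior cluster numbers are assessable — this criterion cannot
    evaluate the quality of the smallest or largest candidate K.
    """
    return _argmax_smallest_k(gap)


def score_stability_sd(
    X: np.ndarray,
    config: RunConfig,
    iterations: int = 25,
    seed_seq: np.random.SeedSequence | int | None = None,
) -> dict[int, float]:
    """Per-K standard deviation of S over independent full runs.

    A diagnostic of algorithmic (Monte-Carlo) variability, not needed in
    routine use.
    """
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    runs = [
        stability_curve(X, config, child) for child in seed_seq.spawn(iterations)
    ]
    return {
        k: float(np.std([r[k] for r in runs], ddof=1)) for k in config.k_values
    }
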