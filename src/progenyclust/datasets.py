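"""Synthetic Gaussian benchmarks with known cluster structure.

Two standard test beds for cluster-number estimation:

* a 2-D dataset of three bivariate-normal clusters (50 samples each,
  identity covariance) centred at (-1, 2), (2, 0) and (-1, -2);
* a 10-D dataset of four clusters (50 samples each) whose first two
  dimensions are bivariate normal around (±4, ±4) while the remaining
  eight dimensions are pure standard-normal noise.

Both emit ground-truth labels and are deterministic given a seed.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .config import RunConfig

__all__ = [
    "make_gauss_2d",
    "make_gauss_10d",
    "add_feature_noise",
    "run_repeat_experiment",
]

_CENTERS_2D = np.array([[-1.0, 2.0], [2.0, 0.0], [-1.0, -2.0]])
_CENTERS_10D = np.array([[4.0, 4.0], [4.0, -4.0], [-4.0, 4.0], [-4.0, -4.0]])
_SAMPLES_PER_CLUSTER = 50


def make_gauss_2d(seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Three-cluster 2-D benchmark: 150 x 2 data plus true labels."""
    rng = np.random.default_rng(seed)
    blocks = [
        rng.multivariate_normal(c, np.eye(2), size=_SAMPLES_PER_CLUSTER)
        for c in _CENTERS_2D
    ]
    X = np.vstack(blocks)
    labels = np.repeat(np.arange(len(_CENTERS_2D)), _SAMPLES_PER_CLUSTER)
    return X, labels


def make_gauss_10d(seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Four-cluster 10-D benchmark with eight pure-noise dimensions.

    Returns a 200 x 10 matrix: dimensions 0-1 carry the cluster signal,
    dimensions 2-9 are i.i.d. standard normal, plus true labels.
    """
    rng = np.random.default_rng(seed)
    signal = np.vstack(
        [
            rng.multivariate_normal(c, np.eye(2), size=_SAMPLES_PER_CLUSTER)
            for c in _CENTERS_10D
        ]
    )
    n = signal.shape[0]
    noise = rng.standard_normal(size=(n, 8))
    X = np.hstack([signal, noise])
    labels = np.repeat(np.arange(len(_CENTERS_10D)), _SAMPLES_PER_CLUSTER)
    return X, labels


def add_feature_noise(
    X: np.ndarray, sigma: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Perturb every entry with i.i.d. N(0, sigma^2) noise.

    ``sigma=0`` returns the input unchanged. Used to probe how much
    measurement noise on the informative features the cluster-number
    estimate tolerates (typical sweep: sigma from 0.1 to 1.5).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    X = np.asarray(X, dtype=np.float64)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(rng)
    return X + rng.normal(0.0, sigma, size=X.shape)


def run_repeat_experiment(
    generator: Callable[[int], tuple[np.ndarray, np.ndarray]],
    reps: int,
    config: RunConfig | None = None,
    criterion: str = "both",
    seed: int | None = None,
) -> tuple[float, list[int]]:
    """Regenerate a benchmark ``reps`` times and score recovery of K.

    Each repetition draws a fresh dataset from ``generator(seed_i)``,
    runs the full selection with independent randomness, and records the
    selected cluster number; the true K is taken from the generator's
    labels.

    Returns
    -------
    fraction_correct : float
        Share of repetitions selecting the generative K.
    selections : list of int
        The per-repetition selected K.
    """
    from .estimator import ProgenyClustering

    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    config = config or RunConfig()
    master = np.random.SeedSequence(seed)
    selections: list[int] = []
    true_k = None
    for child in master.spawn(reps):
        data_seed, run_seed = (int(s.generate_state(1)[0] % 2**31) for s in child.spawn(2))
        X, labels = generator(data_seed)
        true_k = len(np.unique(labels))
        model = ProgenyClustering(
            criterion=criterion, random_state=run_seed, **config.to_dict()
        )
        selections.append(model.fit_select(X))
    fraction = float(np.mean([k == true_k for k in selections]))
    return fraction, selections
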