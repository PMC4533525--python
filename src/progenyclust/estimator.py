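"""Scikit-learn style estimator for progeny clustering."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted

from .backends import cluster
from .config import RunConfig
from .reference import (
    gap_curve,
    reference_curves,
    score_difference,
    select_greatest_gap,
    select_greatest_score,
)
from .scoring import stability_curve

__all__ = ["ProgenyClustering"]


class ProgenyClustering(ClusterMixin, BaseEstimator):
    """Estimate the optimal number of clusters by progeny stability.

    For each candidate K the data are clustered, then R times per-cluster
    "progenies" (imaginary samples drawn feature-wise from the cluster
    members) are pooled and re-clustered; a co-occurrence probability
    matrix over the progenies yields a stability score S_K — the ratio of
    within-cluster to between-cluster co-occurrence probability. The bias
    of S on structureless data is removed by subtracting the mean score of
    T uniform reference datasets, and K is selected by either the greatest
    corrected score or the greatest local gap in the score curve.

    Parameters
    ----------
    k_min, k_max : int, default 2 and 10
        Inclusive range of candidate cluster numbers.
    n_progenies : int, default 10
        Progenies sampled per cluster (minimum 2).
    n_repeats : int, default 100
        Sampling / re-clustering repetitions R per candidate K.
    n_references : int, default 10
        Monte-Carlo reference datasets T (only used by the greatest-score
        criterion, or by greatest-gap with ``gap_on_difference=True``).
    method : {"kmeans", "ward"}, default "kmeans"
        Clustering backend, used both for the initial clustering and for
        re-clustering the progenies.
    criterion : {"score", "gap", "both"}, default "both"
        Which selection criterion drives ``best_k_`` (and ``labels_``).
        With ``"gap"`` the reference datasets are skipped entirely — the
        fast path. ``"both"`` computes both and reports the greatest-score
        choice as ``best_k_``.
    gap_on_difference : bool, default False
        Apply the gap criterion to the reference-corrected difference
        curve instead of the raw score curve.
    log_ratio : bool, default False
        Compare scores to the reference on the log scale.
    standardize : bool, default False
        Z-score each feature before the analysis.
    pca_components : int or None, default None
        Project onto this many leading principal components before the
        analysis. Recommended for data with strongly dependent features,
        since progeny sampling draws features independently.
    random_state : int or None
        Seed of the master random stream.

    Attributes
    ----------
    k_values_ : ndarray
        Candidate cluster numbers, ``k_min..k_max``.
    scores_ : dict
        K -> stability score of the data.
    reference_scores_ : ndarray of shape (T, n_k) or None
        Stability score of each reference dataset (None on the fast path).
    reference_mean_ : dict or None
        K -> mean reference score.
    score_difference_ : dict or None
        K -> reference-corrected score difference.
    gap_ : dict or None
        Interior K -> score gap (None if fewer than three candidates).
    k_score_, k_gap_ : int or None
        Selection under each criterion.
    best_k_ : int
        Selection under the configured ``criterion``.
    labels_ : ndarray
        Cluster assignment of the training data at ``best_k_``.
    warnings_ : list of str
        Advisories, e.g. when the greatest score lands on ``k_max`` and
        the score curve is near-linear (a signature of structureless
        data).

    Examples
    --------
    >>> from progenyclust import ProgenyClustering
    >>> from progenyclust.datasets import make_gauss_2d
    >>> X, _ = make_gauss_2d(seed=0)
    >>> model = ProgenyClustering(random_state=0).fit(X)
    >>> model.best_k_
    3
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 10,
        n_progenies: int = 10,
        n_repeats: int = 100,
        n_references: int = 10,
        method: str = "kmeans",
        criterion: str = "both",
        gap_on_difference: bool = False,
        log_ratio: bool = False,
        standardize: bool = False,
        pca_components: int | None = None,
        random_state: int | None = None,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_progenies = n_progenies
        self.n_repeats = n_repeats
        self.n_references = n_references
        self.method = method
        self.criterion = criterion
        self.gap_on_difference = gap_on_difference
        self.log_ratio = log_ratio
        self.standardize = standardize
        self.pca_components = pca_components
        self.random_state = random_state

    def _make_config(self) -> RunConfig:
        return RunConfig(
            k_min=self.k_min,
            k_max=self.k_max,
            n_progenies=self.n_progenies,
            n_repeats=self.n_repeats,
            n_references=self.n_references,
            method=self.method,
            gap_on_difference=self.gap_on_difference,
            log_ratio=self.log_ratio,
        )

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        self.scaler_ = None
        self.pca_ = None
        if self.standardize:
            self.scaler_ = StandardScaler()
            X = self.scaler_.fit_transform(X)
        if self.pca_components is not None:
            if self.pca_components > X.shape[1]:
                raise ValueError(
                    f"pca_components ({self.pca_components}) exceeds the "
                    f"number of features ({X.shape[1]})"
                )
            self.pca_ = PCA(n_components=self.pca_components)
            X = self.pca_.fit_transform(X)
        return X

    def fit(self, X, y=None):
        """Run the full analysis and select the optimal cluster number."""
        if self.criterion not in ("score", "gap", "both"):
            raise ValueError(
                f"criterion must be 'score', 'gap' or 'both', "
                f"got {self.criterion!r}"
            )
        X = check_array(X, ensure_min_samples=2, ensure_all_finite=True)
        self.n_features_in_ = X.shape[1]
        config = self._make_config()
        config.validate(n_samples=X.shape[0])

        Xp = self._preprocess(X)
        master = np.random.SeedSequence(self.random_state)
        ss_orig, ss_ref = master.spawn(2)

        self.k_values_ = np.array(config.k_values)
        self.scores_, assignments = stability_curve(
            Xp, config, ss_orig, return_assignments=True
        )
        self.warnings_: list[str] = []

        need_refs = self.criterion in ("score", "both") or (
            self.criterion == "gap" and self.gap_on_difference
        )
        if need_refs:
            self.reference_scores_, self.reference_mean_ = reference_curves(
                Xp, config, ss_ref
            )
            self.score_difference_ = score_difference(
                self.scores_, self.reference_mean_, log_ratio=self.log_ratio
            )
            self.k_score_ = select_greatest_score(self.score_difference_)
            if self.k_score_ == self.k_max:
                msg = (
                    "greatest score falls on k_max; the optimum may lie "
                    "beyond the tested range"
                )
                if self._score_curve_near_linear():
                    msg += (
                        " (the score curve is near-linear in K, as on "
                        "structureless reference data — consult the gap "
                        "curve or extend k_max)"
                    )
                self.warnings_.append(msg)
        else:
            self.reference_scores_ = None
            self.reference_mean_ = None
            self.score_difference_ = None
            self.k_score_ = None

        gap_basis = (
            self.score_difference_ if self.gap_on_difference else self.scores_
        )
        if len(self.k_values_) >= 3:
            self.gap_ = gap_curve(gap_basis)
            self.k_gap_ = select_greatest_gap(self.gap_)
        elif self.criterion == "gap":
            raise ValueError(
                "the gap criterion needs at least three candidate K values"
            )
        else:
            self.gap_ = None
            self.k_gap_ = None

        self.best_k_ = (
            self.k_gap_ if self.criterion == "gap" else self.k_score_
        )
        self.labels_ = assignments[self.best_k_]
        return self

    def _score_curve_near_linear(self) -> bool:
        s = np.array([self.scores_[k] for k in self.k_values_])
        if np.allclose(s, s[0]):
            return True
        r = np.corrcoef(self.k_values_, s)[0, 1]
        return r > 0.99

    def fit_select(self, X) -> int:
        """Fit and return the selected number of clusters."""
        return self.fit(X).best_k_

    def transform_labels(self, X) -> np.ndarray:
        """Cluster new data into ``best_k_`` groups with the same backend.

        Note: this re-clusters ``X`` from scratch; progeny clustering
        itself selects K and does not learn a partition model.
        """
        check_is_fitted(self, "best_k_")
        X = check_array(X)
        rng = np.random.default_rng(
            np.random.SeedSequence(self.random_state).spawn(3)[2]
        )
        return cluster(X, self.best_k_, method=self.method, rng=rng)


def select_n_clusters(X, **params) -> int:
    """Functional one-shot wrapper: fit :class:`ProgenyClustering`, return K."""
    return ProgenyClustering(**params).fit_select(X)
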