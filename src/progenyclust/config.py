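"""Run configuration shared by the clustering pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """Parameters of a progeny-clustering run.

    Attributes
    ----------
    k_min, k_max : int
        Range of candidate cluster numbers, inclusive. Defaults 2 and 10.
    n_progenies : int
        Progenies sampled per cluster (default 10). Must be at least 2:
        with a single progeny per cluster the true-classification blocks
        contain only diagonal entries, which the score excludes.
    n_repeats : int
        Number of progeny sampling / re-clustering repetitions R aggregated
        into the co-occurrence probability matrix (default 100).
    n_references : int
        Number of Monte-Carlo reference datasets T (default 10).
    method : str
        Clustering backend name; ``"kmeans"`` or ``"ward"``.
    gap_on_difference : bool
        If True, the greatest-gap criterion operates on the
        reference-corrected score difference instead of the raw score
        curve (the fast, reference-free path is the default).
    log_ratio : bool
        If True, scores are compared on the log scale, so the score
        "difference" becomes the log of the score ratio.
    """

    k_min: int = 2
    k_max: int = 10
    n_progenies: int = 10
    n_repeats: int = 100
    n_references: int = 10
    method: str = "kmeans"
    gap_on_difference: bool = False
    log_ratio: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, n_samples: int | None = None) -> None:
        if self.k_min < 2:
            raise ValueError(f"k_min must be >= 2, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError(
                f"k_max ({self.k_max}) must be >= k_min ({self.k_min})"
            )
        if self.n_progenies < 2:
            raise ValueError(
                "n_progenies must be >= 2: with one progeny per cluster the "
                "true blocks are empty once the diagonal is excluded"
            )
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.n_references < 1:
            raise ValueError(
                f"n_references must be >= 1, got {self.n_references}"
            )
        if n_samples is not None and self.k_max > n_samples:
            raise ValueError(
                f"k_max ({self.k_max}) exceeds the number of observations "
                f"({n_samples})"
            )

    @property
    def k_values(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1))

    def to_dict(self) -> dict:
        return asdict(self)
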