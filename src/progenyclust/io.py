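"""CSV/TSV input, preprocessing helpers, and result serialization."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "preprocess", "build_report", "write_report", "read_report"]


def read_matrix(
    path: str | Path,
    delimiter: str = ",",
    has_ids: bool = False,
    transpose: bool = False,
) -> pd.DataFrame:
    """Load an observations-by-features table.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row of feature names.
    delimiter : str
        Field separator ("," or "\\t" typically).
    has_ids : bool
        Treat the first column as sample identifiers.
    transpose : bool
        Transpose after loading, for features-by-observations files
        (e.g. the genes x conditions convention of expression tables).

    Returns
    -------
    DataFrame of float64 values; index holds sample ids, columns hold
    feature names.

    Raises
    ------
    ValueError
        On any non-numeric or missing cell, naming its location.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0 if has_ids else None)
    if transpose:
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing value at row {df.index[row]!r}, "
            f"column {df.columns[col]!r}"
        )
    numeric = numeric.astype(np.float64)
    if numeric.shape[0] < 2 or numeric.shape[1] < 1:
        raise ValueError(
            f"need at least 2 observations and 1 feature, got shape "
            f"{numeric.shape}"
        )
    return numeric


def preprocess(
    X, standardize: bool = False, pca_components: int | None = None
) -> np.ndarray:
    """Optional z-scoring then optional PCA projection.

    A convenience mirror of the estimator's built-in preprocessing for
    users who want the transformed matrix itself.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(X, dtype=np.float64)
    if standardize:
        X = StandardScaler().fit_transform(X)
    if pca_components is not None:
        if pca_components > X.shape[1]:
            raise ValueError(
                f"pca_components ({pca_components}) exceeds the number of "
                f"features ({X.shape[1]})"
            )
        X = PCA(n_components=pca_components).fit_transform(X)
    return X


def _round_sig(x: float, digits: int = 12) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def _curve_to_json(curve: dict[int, float] | None) -> dict[str, float] | None:
    if curve is None:
        return None
    return {str(k): _round_sig(float(v)) for k, v in sorted(curve.items())}


def build_report(model, elapsed: float | None = None) -> dict:
    """Serializable summary of a fitted :class:`ProgenyClustering`."""
    ref = model.reference_scores_
    report = {
        "config": model.get_params(),
        "k_values": [int(k) for k in model.k_values_],
        "scores": _curve_to_json(model.scores_),
        "reference_scores": None
        if ref is None
        else [[_round_sig(float(v)) for v in row] for row in ref],
        "reference_mean": _curve_to_json(model.reference_mean_),
        "score_difference": _curve_to_json(model.score_difference_),
        "gap": _curve_to_json(model.gap_),
        "k_score": model.k_score_,
        "k_gap": model.k_gap_,
        "best_k": int(model.best_k_),
        "warnings": list(model.warnings_),
        "elapsed_seconds": elapsed,
    }
    return report


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``report.json`` and ``curves.csv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")

    rows = {"K": report["k_values"], "score": [report["scores"][str(k)] for k in report["k_values"]]}
    for name in ("reference_mean", "score_difference", "gap"):
        curve = report[name]
        if curve is not None:
            rows[name] = [curve.get(str(k)) for k in report["k_values"]]
    csv_path = out_dir / "curves.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return json_path, csv_path


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
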