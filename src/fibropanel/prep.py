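"""Biomarker-scale handling, z-standardization and kNN imputation.

Plasma biomarker concentrations are analysed on the log10 scale and
reported back-transformed: ``10**mean(log10 x)`` is the geometric mean and
``10**sd(log10 x)`` the multiplicative (geometric) SD.  Analysis matrices
are z-standardized column-wise (subtract mean, divide by sample SD) before
any distance-based step; missing cells are then filled by k-nearest-
neighbour imputation over the standardized rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def log10_transform(values):
    """Elementwise log base 10; NaN propagates, nonpositive values raise.

    Accepts scalars, arrays, Series or DataFrames and returns the same kind.
    The error message names the offending row/column where available.
    """
    if np.isscalar(values):
        if values <= 0:
            raise ValueError(f"log10 of nonpositive value {values}")
        return float(np.log10(values))
    if isinstance(values, pd.DataFrame):
        bad = (values <= 0).any()
        if bad.any():
            col = bad[bad].index[0]
            row = (values[col] <= 0).idxmax()
            raise ValueError(
                f"log10 of nonpositive value at row {row!r}, column {col!r}"
            )
        return np.log10(values)
    if isinstance(values, pd.Series):
        bad = values <= 0
        if bad.any():
            raise ValueError(f"log10 of nonpositive value at index {bad.idxmax()!r}")
        return np.log10(values)
    arr = np.asarray(values, dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        idx = np.argwhere(np.nan_to_num(arr, nan=1.0) <= 0)[0]
        raise ValueError(f"log10 of nonpositive value at position {tuple(idx)}")
    return np.log10(arr)


def back_transform(log10_mean: float, log10_sd: float) -> Tuple[float, float]:
    """(geometric mean, geometric SD) = (10**mean, 10**sd) of log10 summaries."""
    return float(10.0 ** log10_mean), float(10.0 ** log10_sd)


@dataclass
class StandardizationModel:
    """Per-column location/scale fitted on one matrix and reusable on others.

    Columns with zero variance (or fewer than two observed values) cannot be
    z-scored; they are recorded in ``dropped`` and excluded from output
    rather than silently divided by zero.
    """

    columns: List[str]
    means: pd.Series
    sds: pd.Series
    dropped: List[str] = field(default_factory=list)


def fit_standardizer(matrix: pd.DataFrame) -> StandardizationModel:
    """Column means and sample (n-1) SDs, ignoring missing entries."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    means = matrix.mean(skipna=True)
    sds = matrix.std(skipna=True, ddof=1)
    counts = matrix.notna().sum()
    keep = [c for c in matrix.columns if counts[c] >= 2 and sds[c] > 0]
    dropped = [c for c in matrix.columns if c not in keep]
    return StandardizationModel(
        columns=keep, means=means[keep], sds=sds[keep], dropped=dropped
    )


def apply_standardizer(model: StandardizationModel, matrix: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in model.columns if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks fitted columns: {missing}")
    return (matrix[model.columns] - model.means) / model.sds


def standardize(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, StandardizationModel]:
    """Fit on ``matrix`` and apply to it; convenience for the common case."""
    model = fit_standardizer(matrix)
    return apply_standardizer(model, matrix), model


@dataclass
class ImputationReport:
    """Record of what kNN imputation did: positions, donors, fallbacks."""

    k: int
    metric: str
    imputed: List[dict] = field(default_factory=list)  # {row, column, neighbors, value}
    fallback_count: int = 0
    fully_missing_rows: List[int] = field(default_factory=list)

    @property
    def n_imputed(self) -> int:
        return len(self.imputed)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "metric": self.metric,
            "n_imputed": self.n_imputed,
            "fallback_count": self.fallback_count,
            "fully_missing_rows": self.fully_missing_rows,
            "imputed": self.imputed,
        }


def _row_distances(X: np.ndarray, i: int) -> np.ndarray:
    """Mean squared difference over columns observed in both rows.

    Averaging over the shared-column count keeps rows with different
    missingness patterns comparable; a pair with no shared observed column
    gets infinite distance.
    """
    n = X.shape[0]
    obs_i = ~np.isnan(X[i])
    d = np.full(n, np.inf)
    for j in range(n):
        if j == i:
            continue
        shared = obs_i & ~np.isnan(X[j])
        m = int(shared.sum())
        if m == 0:
            continue
        diff = X[i, shared] - X[j, shared]
        d[j] = float(diff @ diff) / m
    return d


def knn_impute(
    matrix: pd.DataFrame, k: int = 5, weighted: bool = False
) -> Tuple[pd.DataFrame, ImputationReport]:
    """Fill missing cells with the mean of the k nearest rows' values.

    Distance between rows is the mean squared difference over columns both
    rows observe.  Donor rows must have the target column observed; if fewer
    than k eligible donors exist all of them are used, and with none the
    column mean is substituted and counted as a fallback.  Equidistant
    donors are broken by lowest row index (stable sort).  Observed entries
    are never altered.  Expects a scale-homogeneous (standardized) matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.to_numpy(dtype=float, copy=True)
    n, p = X.shape
    col_obs = ~np.isnan(X)
    fully_missing_cols = [matrix.columns[j] for j in range(p) if not col_obs[:, j].any()]
    if fully_missing_cols:
        raise ValueError(f"fully-missing columns cannot be imputed: {fully_missing_cols}")
    col_means = np.nanmean(X, axis=0)

    report = ImputationReport(k=k, metric="mean_squared_difference")
    out = X.copy()
    for i in range(n):
        miss = np.where(np.isnan(X[i]))[0]
        if miss.size == 0:
            continue
        if miss.size == p:
            out[i] = col_means
            report.fully_missing_rows.append(i)
            report.fallback_count += int(p)
            for j in range(p):
                report.imputed.append(
                    {
                        "row": int(i),
                        "column": str(matrix.columns[j]),
                        "neighbors": [],
                        "value": float(col_means[j]),
                    }
                )
            continue
        d = _row_distances(X, i)
        order = np.argsort(d, kind="stable")  # ties -> lowest row index first
        for j in miss:
            eligible = [r for r in order if np.isfinite(d[r]) and col_obs[r, j]]
            donors = eligible[:k]
            if not donors:
                value = float(col_means[j])
                report.fallback_count += 1
            elif weighted:
                w = 1.0 / (np.array([d[r] for r in donors]) + 1e-12)
                value = float(np.average(X[donors, j], weights=w))
            else:
                value = float(np.mean(X[donors, j]))
            out[i, j] = value
            report.imputed.append(
                {
                    "row": int(i),
                    "column": str(matrix.columns[j]),
                    "neighbors": [int(r) for r in donors],
                    "value": value,
                }
            )

    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), report


def column_mean_impute(matrix: pd.DataFrame) -> pd.DataFrame:
    """Baseline imputation: every missing cell gets its column mean."""
    return matrix.fillna(matrix.mean(skipna=True))
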