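"""Quantile normalization of expression columns (robustness variants).

Two approaches used to check that clustering is not driven by the shape of
per-experiment fold-change distributions: a rank-based method that replaces
each column's values by the cross-column mean quantile curve, and a
spline-based method that maps each column onto that reference curve through
a fitted monotone smooth.  Missing cells stay missing in both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["quantile_normalize", "reference_quantile_curve", "QuantileNormalizer"]


def reference_quantile_curve(matrix: pd.DataFrame, n_grid: int | None = None):
    """Mean quantile function across columns.

    Returns ``(probs, ref)`` where ``ref[i]`` is the mean over columns of
    each column's quantile function evaluated at probability ``probs[i]``.
    Columns with unequal non-missing counts are mapped via interpolated
    quantiles; the grid has ``max(n_j)`` points by default so that for
    complete equal-length columns the curve is exactly the mean of the
    order statistics.
    """
    counts = matrix.notna().sum(axis=0)
    if (counts < 1).any():
        raise ValueError("every column needs at least one non-missing value")
    n = int(counts.max()) if n_grid is None else int(n_grid)
    probs = (np.arange(n) + 0.5) / n
    curves = []
    for col in matrix.columns:
        v = np.sort(matrix[col].dropna().to_numpy(dtype=float))
        p = (np.arange(v.size) + 0.5) / v.size
        curves.append(np.interp(probs, p, v))
    return probs, np.mean(curves, axis=0)


def quantile_normalize(matrix: pd.DataFrame, method: str = "rank") -> pd.DataFrame:
    """Normalize every column onto a common reference distribution.

    Parameters
    ----------
    matrix : DataFrame
        Expression matrix (rows RNAs, columns experiments), NaN missing.
    method : {"rank", "spline"}
        ``"rank"`` replaces each value by the reference quantile at its
        (midrank-based) column quantile — classic quantile normalization.
        ``"spline"`` fits a monotone smooth (PCHIP through a coarse matched-
        quantile grid) from column values to the reference curve and
        evaluates it, preserving smooth distortions instead of forcing
        identical distributions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    if method not in ("rank", "spline"):
        raise ValueError(f"unknown method {method!r}")
    probs, ref = reference_quantile_curve(matrix)
    out = matrix.copy()
    for col in matrix.columns:
        v = matrix[col]
        obs = v.dropna()
        x = obs.to_numpy(dtype=float)
        if x.size == 0:
            continue
        if method == "rank":
            pr = (rankdata(x, method="average") - 0.5) / x.size
            new = np.interp(pr, probs, ref)
        else:
            new = _spline_map(x, probs, ref)
        out.loc[obs.index, col] = new
    return out


def _spline_map(x: np.ndarray, probs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Monotone smooth map of one column onto the reference quantile curve."""
    n = x.size
    if n == 1:
        return np.interp([0.5], probs, ref)
    k = int(min(n, max(4, round(np.sqrt(n)) * 2)))
    # anchor the grid at 0 and 1 so every data value lies inside the fitted
    # range (cubic extrapolation beyond it is not monotonicity-safe)
    grid = np.linspace(0.0, 1.0, k)
    xq = np.quantile(x, grid)
    yq = np.interp(grid, probs, ref)
    # collapse duplicate abscissae (heavy ties) before interpolating
    xs, idx = np.unique(xq, return_index=True)
    ys = np.array([yq[xq == val].mean() for val in xs])
    if xs.size == 1:
        return np.full(n, ys[0])
    f = PchipInterpolator(xs, ys, extrapolate=True)
    return np.asarray(f(x), dtype=float)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Column-wise quantile normalization as a scikit-learn transformer.

    ``fit`` learns the reference quantile curve from the columns of the
    training matrix; ``transform`` maps each column of a matrix onto it.

    Parameters
    ----------
    method : {"rank", "spline"}, default "rank"

    Attributes
    ----------
    reference_probs_, reference_curve_ : ndarray
        The learned mean quantile curve.
    """

    def __init__(self, method: str = "rank"):
        self.method = method

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if frame.shape[1] < 2:
            raise ValueError("quantile normalization needs at least 2 columns")
        if self.method not in ("rank", "spline"):
            raise ValueError(f"unknown method {self.method!r}")
        self.reference_probs_, self.reference_curve_ = reference_quantile_curve(frame)
        return self

    def transform(self, X):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        out = frame.copy()
        for col in frame.columns:
            obs = frame[col].dropna()
            x = obs.to_numpy(dtype=float)
            if x.size == 0:
                continue
            if self.method == "rank":
                pr = (rankdata(x, method="average") - 0.5) / x.size
                new = np.interp(pr, self.reference_probs_, self.reference_curve_)
            else:
                new = _spline_map(x, self.reference_probs_, self.reference_curve_)
            out.loc[obs.index, col] = new
        return out
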