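"""Pairwise-complete Pearson correlation with significance gating.

Correlations are computed over jointly non-missing observations only
("pairwise complete"), with the number of complete pairs tracked per cell.
Two-sided p-values for H0: r = 0 come from the t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n`` the per-pair overlap.
Pairs with too little overlap, or with a constant member, are *undefined*:
their r is NaN and they can never pass the significance gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMatrix", "pairwise_pearson", "significance_gate"]


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise-complete Pearson correlation structure.

    Attributes
    ----------
    item_ids : list of str
        Row/column labels (experiments or RNAs depending on the axis).
    r : ndarray
        Pearson r in [-1, 1]; NaN where undefined.
    n_pairs : ndarray of int
        Jointly non-missing observation counts per pair.
    p_raw : ndarray
        Two-sided p-values for H0: r = 0; NaN where r is undefined.
    min_overlap : int
        Pairs with fewer complete observations were marked undefined.
    """

    item_ids: list
    r: np.ndarray
    n_pairs: np.ndarray
    p_raw: np.ndarray
    min_overlap: int

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of defined (finite-r) cells."""
        return np.isfinite(self.r)

    def index_of(self, item_id) -> int:
        return self.item_ids.index(item_id)


def pairwise_pearson(
    matrix: pd.DataFrame, axis: str = "columns", min_overlap: int = 3
) -> CorrelationMatrix:
    """All-pairs pairwise-complete Pearson correlation over rows or columns.

    Parameters
    ----------
    matrix : DataFrame
        Log2-ratio matrix, NaN for missing cells.
    axis : {"columns", "rows"}
        ``"columns"`` correlates experiments (over RNAs); ``"rows"``
        correlates RNAs (over experiments).
    min_overlap : int
        Minimum number of complete observation pairs for a correlation to be
        defined; must be >= 3 so the t transform has positive df.
    """
    if axis not in ("columns", "rows"):
        raise ValueError(f"axis must be 'columns' or 'rows', got {axis!r}")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    data = matrix.to_numpy(dtype=float)
    if axis == "columns":
        item_ids = list(matrix.columns)
    else:
        item_ids = list(matrix.index)
        data = data.T
    if len(item_ids) < 2:
        raise ValueError("need at least 2 items to correlate")

    mask = np.isfinite(data)
    z = np.where(mask, data, 0.0)
    m = mask.astype(float)

    n = m.T @ m                      # joint overlap counts
    sx = z.T @ m                     # sum of x over the joint support of (x, y)
    sxy = z.T @ z
    sxx = (z * z).T @ m

    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sx.T
        varx = n * sxx - sx**2       # n * sum(x^2) - (sum x)^2 over joint support
        denom2 = varx * varx.T
        # Guard tiny negative values from cancellation and flag constant pairs.
        tol = np.maximum(n, 1) * np.finfo(float).eps * np.maximum(sxx, 1.0) * 10
        degenerate = (varx <= tol) | (varx.T <= tol)
        r = np.where(denom2 > 0, num / np.sqrt(np.where(denom2 > 0, denom2, 1.0)), np.nan)
    r = np.clip(r, -1.0, 1.0)
    n_pairs = np.rint(n).astype(int)
    undefined = (n_pairs < min_overlap) | degenerate
    r[undefined] = np.nan
    # symmetrize exactly and fix the diagonal
    r = (r + r.T) / 2.0
    diag_ok = np.diag(n_pairs) >= 2
    for i in np.flatnonzero(diag_ok & ~np.isnan(np.diag(r))):
        r[i, i] = 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        df = n_pairs - 2
        t = r * np.sqrt(np.where(df > 0, df, np.nan) / np.maximum(1.0 - r**2, 0.0))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.isfinite(r) & (np.abs(r) >= 1.0), 0.0, p)
    p[~np.isfinite(r)] = np.nan
    np.fill_diagonal(p, np.nan)
    return CorrelationMatrix(
        item_ids=item_ids, r=r, n_pairs=n_pairs, p_raw=p, min_overlap=min_overlap
    )


def significance_gate(
    corr: CorrelationMatrix, alpha: float = 0.01, correction: str = "bonferroni"
) -> np.ndarray:
    """Boolean pass matrix of the correlation significance test.

    A pair passes iff its correlation is defined and its (optionally
    Bonferroni-corrected) two-sided p-value for H0: r = 0 is <= ``alpha``.
    The Bonferroni multiplier is the number of defined off-diagonal
    upper-triangle pairs.  Undefined cells always fail; the diagonal is
    False.  The correlation *threshold* is not checked here — that belongs
    to the clustering step.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    k = corr.n_items
    defined = corr.defined.copy()
    np.fill_diagonal(defined, False)
    n_tests = int(np.triu(defined, 1).sum())
    if correction == "bonferroni" and n_tests > 0:
        p_adj = corr.p_raw * n_tests
    else:
        p_adj = corr.p_raw
    with np.errstate(invalid="ignore"):
        gate = defined & (p_adj <= alpha)
    gate = gate & gate.T
    np.fill_diagonal(gate, False)
    return gate
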