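"""Consistently enriched/depleted RNA sets within experiment clusters.

For each experiment of a PSR, the top- and bottom-k% RNAs by log2
fold-change are extracted; the intersection across all the PSR's
experiments defines the consistently enriched (respectively depleted)
set.  Thresholds of 1, 5 and 10% are the conventional choices.  Rank-based
extraction sidesteps per-study fold-change scale differences — the reason
a common fold-change cutoff across heterogeneous studies would be unsound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConsistencySets",
    "ConsistencyReport",
    "percentile_extremes",
    "psr_consistent_sets",
    "consistency_diagnostics",
]


@dataclass(frozen=True)
class ConsistencySets:
    """Per-PSR intersected top/bottom-k% RNA sets."""

    psr_id: str
    k_percent: float
    enriched: frozenset
    depleted: frozenset

    @property
    def combined_size(self) -> int:
        return len(self.enriched) + len(self.depleted)


def percentile_extremes(values: pd.Series, k_percent: float):
    """Top and bottom k% of a fold-change vector.

    Missing values are excluded before ranking; each set has
    ``ceil(k/100 * m)`` members with ``m`` the non-missing count.  Ties at
    the cutoff are resolved by a stable sort on (value, RNA id): the top set
    prefers larger values then lexicographically smaller ids, the bottom set
    smaller values then smaller ids.
    """
    if not 0.0 < k_percent <= 50.0:
        raise ValueError("k_percent must be in (0, 50]")
    obs = values.dropna()
    m = obs.size
    if m == 0:
        warnings.warn("no non-missing values; returning empty extreme sets")
        return frozenset(), frozenset()
    c = ceil(k_percent / 100.0 * m)
    ids = obs.index.to_numpy(dtype=object)
    vals = obs.to_numpy(dtype=float)
    order_top = np.lexsort((ids, -vals))   # primary: value desc, then id asc
    order_bot = np.lexsort((ids, vals))
    top = frozenset(ids[order_top[:c]])
    bottom = frozenset(ids[order_bot[:c]])
    return top, bottom


def psr_consistent_sets(
    matrix: pd.DataFrame,
    experiment_ids,
    k_percent: float,
    psr_id: str = "",
) -> ConsistencySets:
    """Intersect per-experiment extreme sets across a PSR's experiments.

    RNAs missing in *any* of the PSR's experiments are excluded up front:
    a consistency set only makes sense over RNAs measured everywhere in the
    PSR.
    """
    experiment_ids = list(experiment_ids)
    missing_cols = [e for e in experiment_ids if e not in matrix.columns]
    if missing_cols:
        raise KeyError(f"experiments absent from matrix: {missing_cols[:5]}")
    if len(experiment_ids) < 2:
        raise ValueError("a PSR needs at least 2 experiments")
    sub = matrix[experiment_ids].dropna(axis=0, how="any")
    enriched: frozenset | None = None
    depleted: frozenset | None = None
    for e in experiment_ids:
        top, bottom = percentile_extremes(sub[e], k_percent)
        enriched = top if enriched is None else (enriched & top)
        depleted = bottom if depleted is None else (depleted & bottom)
    return ConsistencySets(
        psr_id=psr_id, k_percent=k_percent, enriched=enriched or frozenset(),
        depleted=depleted or frozenset(),
    )


@dataclass
class ConsistencyReport:
    """Size diagnostics over all PSRs at one threshold.

    ``rho_size_vs_experiments`` is the rank correlation between a PSR's
    experiment count and its combined (enriched + depleted) set size;
    ``rho_up_vs_down`` the rank correlation between enriched and depleted
    sizes; ``wilcoxon_p`` the two-sided matched-pairs signed-rank p for the
    up-vs-down size balance.  Undefined statistics (constant inputs) are
    NaN; a degenerate signed-rank test (no nonzero differences) is reported
    as p = 1 by convention.
    """

    sizes: pd.DataFrame
    rho_size_vs_experiments: float
    rho_size_p: float
    rho_up_vs_down: float
    rho_up_down_p: float
    wilcoxon_p: float


def consistency_diagnostics(
    sets: list[ConsistencySets],
    experiment_counts,
    method: str = "spearman",
) -> ConsistencyReport:
    """Rank-correlation and paired-balance diagnostics across PSRs.

    Parameters
    ----------
    sets : list of ConsistencySets
        One entry per PSR (a single k threshold).
    experiment_counts : mapping
        PSR id -> number of experiments in the PSR.
    method : {"spearman", "pearson"}
        Correlation estimator; Spearman (midranks) is the default.
    """
    if len(sets) < 3:
        raise ValueError("need at least 3 PSRs for diagnostics")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for s in sets:
        rows.append(
            {
                "psr_id": s.psr_id,
                "n_experiments": int(experiment_counts[s.psr_id]),
                "n_enriched": len(s.enriched),
                "n_depleted": len(s.depleted),
                "combined": s.combined_size,
            }
        )
    df = pd.DataFrame(rows).set_index("psr_id")

    def corr(x, y):
        if np.all(x == x[0]) or np.all(y == y[0]):
            return float("nan"), float("nan")
        if method == "spearman":
            res = stats.spearmanr(x, y)
        else:
            res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)

    rho1, p1 = corr(df["n_experiments"].to_numpy(float), df["combined"].to_numpy(float))
    rho2, p2 = corr(df["n_enriched"].to_numpy(float), df["n_depleted"].to_numpy(float))
    diffs = df["n_enriched"].to_numpy(float) - df["n_depleted"].to_numpy(float)
    if np.all(diffs == 0):
        wp = 1.0
    else:
        wp = float(stats.wilcoxon(df["n_enriched"], df["n_depleted"]).pvalue)
    return ConsistencyReport(
        sizes=df,
        rho_size_vs_experiments=rho1,
        rho_size_p=p1,
        rho_up_vs_down=rho2,
        rho_up_down_p=p2,
        wilcoxon_p=wp,
    )
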