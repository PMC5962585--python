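"""The block-by-pattern activation/repression map.

For every (BTR, PSR) pair with enough members (>= 10 RNAs, >= 5
experiments by convention), each RNA's median log2 fold-change over the
PSR's experiments is computed; the resulting vector is tested against zero
with a two-sided one-sample Wilcoxon signed-rank test, and its median gives
the direction.  Benjamini-Hochberg FDR is applied once, jointly over all
performed tests; cells pass at adjusted p < 0.05 and are labeled enriched
(median > 0) or depleted (median < 0), otherwise no-change; cells with too
few measured RNAs are no-data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .enrichment import bh_adjust

__all__ = [
    "BlockResponseMap",
    "btr_psr_cell",
    "build_map",
    "large_change_flags",
    "heatmap_order",
    "signed_rank_p",
]

LABELS = ("enriched", "depleted", "no-change", "no-data")
_LABEL_CODE = {"enriched": 1.0, "depleted": -1.0, "no-change": 0.0, "no-data": 0.0}


def signed_rank_p(values: np.ndarray) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p against location 0.

    Zeros are dropped (standard convention).  The exact distribution is
    used for n <= 25 without tied absolute values; otherwise the normal
    approximation with continuity correction.  A vector with no nonzero
    entries is degenerate: NaN is returned and the caller labels the cell
    no-change.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    v = v[v != 0.0]
    n = v.size
    if n == 0:
        return float("nan")
    ties = np.unique(np.abs(v)).size < n
    if n <= 25 and not ties:
        method = "exact"
    else:
        method = "approx"
    with np.errstate(invalid="ignore"):
        res = stats.wilcoxon(v, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)


def btr_psr_cell(matrix: pd.DataFrame, btr_members, psr_experiments):
    """One map cell: (median effect, raw p, n_used).

    ``n_used`` counts the block's RNAs with at least one measurement in the
    PSR's experiments; fewer than 4 means the cell carries no usable signal
    and the caller should mark it no-data (p is NaN then).
    """
    rows = [r for r in btr_members if r in matrix.index]
    cols = [e for e in psr_experiments if e in matrix.columns]
    if not rows or not cols:
        return float("nan"), float("nan"), 0
    sub = matrix.loc[rows, cols]
    medians = sub.median(axis=1, skipna=True).dropna()
    n_used = int(medians.size)
    if n_used < 4:
        return float("nan"), float("nan"), n_used
    effect = float(medians.median())
    p = signed_rank_p(medians.to_numpy())
    return effect, p, n_used


@dataclass
class BlockResponseMap:
    """Long-format map plus pivoting helpers.

    ``table`` has one row per (btr, psr) with columns effect, p_raw,
    p_adjusted, n_used, label.
    """

    table: pd.DataFrame
    fdr: float

    def label_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="btr", columns="psr", values="label")

    def effect_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="btr", columns="psr", values="effect")

    def coded_matrix(self) -> pd.DataFrame:
        """Labels as +1 / -1 / 0 for distance-based ordering."""
        coded = self.table.assign(code=self.table["label"].map(_LABEL_CODE))
        return coded.pivot(index="btr", columns="psr", values="code")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_map(
    matrix: pd.DataFrame,
    btrs,
    psrs,
    min_btr: int = 10,
    min_psr: int = 5,
    fdr: float = 0.05,
) -> BlockResponseMap:
    """Test every eligible (BTR, PSR) cell and label at joint BH FDR.

    ``btrs`` and ``psrs`` are mappings id -> member ids; blocks below
    ``min_btr`` RNAs and patterns below ``min_psr`` experiments are dropped
    before testing.  BH runs once across all performed tests.
    """
    btrs = {b: list(m) for b, m in dict(btrs).items() if len(list(m)) >= min_btr}
    psrs = {p: list(m) for p, m in dict(psrs).items() if len(list(m)) >= min_psr}
    if not btrs or not psrs:
        raise ValueError("no eligible BTR/PSR pairs under the size thresholds")
    rows = []
    for bid, members in btrs.items():
        for pid, experiments in psrs.items():
            effect, p, n_used = btr_psr_cell(matrix, members, experiments)
            rows.append(dict(btr=bid, psr=pid, effect=effect, p_raw=p, n_used=n_used))
    table = pd.DataFrame(rows)
    tested = table["p_raw"].notna()
    table["p_adjusted"] = np.nan
    if tested.any():
        table.loc[tested, "p_adjusted"] = bh_adjust(table.loc[tested, "p_raw"])
    labels = []
    for _, row in table.iterrows():
        if row["n_used"] < 4:
            labels.append("no-data")
        elif (
            np.isfinite(row["p_adjusted"])
            and row["p_adjusted"] < fdr
            and row["effect"] != 0
        ):
            labels.append("enriched" if row["effect"] > 0 else "depleted")
        else:
            labels.append("no-change")
    table["label"] = labels
    return BlockResponseMap(table=table, fdr=fdr)


def large_change_flags(btrs, consistency_sets) -> pd.DataFrame:
    """Flag blocks whose members dominate a PSR's extreme-change subsets.

    ``consistency_sets`` is an iterable of :class:`ConsistencySets` (any
    mix of PSRs and k thresholds).  A (BTR, PSR, k) flag is True iff
    strictly more than half of the block's members lie in the union of the
    PSR's top and bottom k% sets.
    """
    rows = []
    for cs in consistency_sets:
        extreme = cs.enriched | cs.depleted
        for bid, members in dict(btrs).items():
            members = frozenset(members)
            inside = len(members & extreme)
            rows.append(
                dict(
                    btr=bid,
                    psr=cs.psr_id,
                    k_percent=cs.k_percent,
                    n_in_extremes=inside,
                    flag=inside * 2 > len(members),
                )
            )
    return pd.DataFrame(rows)


def heatmap_order(matrix: pd.DataFrame):
    """Row and column display orders from hierarchical clustering.

    Average-linkage clustering of Euclidean distances along rows and along
    columns; returns ``(row_ids, column_ids)`` in leaf order.  Matrices with
    fewer than 2 rows (columns) keep their input row (column) order.  NaNs
    are treated as 0 for distance purposes.
    """
    values = matrix.to_numpy(dtype=float)
    values = np.where(np.isfinite(values), values, 0.0)

    def order(data: np.ndarray, ids) -> list:
        if data.shape[0] < 2:
            return list(ids)
        lk = linkage(data, method="average", metric="euclidean")
        return [ids[i] for i in leaves_list(lk)]

    return order(values, list(matrix.index)), order(values.T, list(matrix.columns))
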