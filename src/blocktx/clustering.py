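"""Constrained complete-linkage correlation clustering.

Experiments (or RNAs) are agglomerated greedily, best linkage value first,
under a *clique constraint*: a merge is admissible only if every cross pair
has a defined correlation strictly above the threshold (default 0.5) AND
passes the significance gate.  Agglomeration stops when no admissible merge
remains; items never merged are reported as singletons.  Cluster numbers
record creation order — the first merge that creates a cluster fixes its
number, and that number is inherited through later growth.

The partition of experiments yields Patterns of Stress Response (PSRs); the
same procedure on rows yields Blocks of Transcriptional Responses (BTRs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .correlation import CorrelationMatrix, pairwise_pearson, significance_gate
from .io import GeneSetCollection

__all__ = [
    "ClusterSet",
    "ClusterComparison",
    "constrained_agglomerative",
    "compare_clusterings",
    "CorrelationClustering",
]

_LINKAGES = ("complete", "average", "single")


@dataclass
class ClusterSet:
    """An exclusive partition into numbered clusters plus unassigned singletons.

    ``clusters`` maps creation-order cluster numbers to member-id frozensets
    (every cluster has >= 2 members); ``singletons`` holds the unassigned
    item ids.  ``parameters`` records the clustering settings.
    """

    clusters: dict[int, frozenset]
    singletons: frozenset
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for num, members in self.clusters.items():
            if num <= 0:
                raise ValueError("cluster numbers must be positive")
            if len(members) < 2:
                raise ValueError(f"cluster {num} has fewer than 2 members")
            if seen & members:
                raise ValueError("clusters overlap")
            seen |= members
        if seen & self.singletons:
            raise ValueError("singletons overlap clusters")

    @property
    def item_ids(self) -> frozenset:
        out = set(self.singletons)
        for members in self.clusters.values():
            out |= members
        return frozenset(out)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> dict[int, int]:
        return {num: len(m) for num, m in self.clusters.items()}

    def labels(self) -> dict:
        """item id -> cluster number, or -1 for singletons."""
        out = {i: -1 for i in self.singletons}
        for num, members in self.clusters.items():
            for i in members:
                out[i] = num
        return out

    def to_gene_sets(self, prefix: str = "cluster") -> GeneSetCollection:
        sets = {
            f"{prefix}{num}": tuple(sorted(members))
            for num, members in sorted(self.clusters.items())
        }
        return GeneSetCollection(sets=sets)


def constrained_agglomerative(
    corr: CorrelationMatrix,
    gate: np.ndarray,
    r_star: float = 0.5,
    linkage: str = "complete",
) -> ClusterSet:
    """Greedy best-first agglomeration under the clique constraint.

    At each step the admissible cluster pair with the best linkage value is
    merged (complete linkage scores a merge by its *worst* cross-pair r;
    average by the mean; single by the best).  A pair of clusters is
    admissible only if every cross pair has defined r > ``r_star`` and
    passes ``gate``.  Ties on the linkage value are broken by the
    lexicographically smallest combined member-id tuple.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    n = corr.n_items
    if n == 0 or gate.shape != (n, n):
        raise ValueError("correlation matrix and gate must be congruent and non-empty")
    ids = [str(i) for i in corr.item_ids]

    r = corr.r.copy()
    edge = gate & np.isfinite(r) & (r > r_star)
    np.fill_diagonal(edge, False)
    rw = np.where(np.isfinite(r), r, -np.inf)

    # Per active-cluster-pair state, updated incrementally on merge:
    #   admiss  - all cross pairs are edges
    #   lk      - linkage value (complete: min r, single: max r, average: mean)
    admiss = edge.copy()
    if linkage == "complete":
        lk = np.where(edge, rw, -np.inf)
    elif linkage == "single":
        lk = np.where(edge, rw, -np.inf)
    else:  # average: track sums and counts of *defined* cross correlations
        lk_sum = np.where(np.isfinite(r), r, 0.0)
        lk_cnt = np.isfinite(r).astype(float)
        np.fill_diagonal(lk_cnt, 0.0)

    members: list[list[int] | None] = [[i] for i in range(n)]
    numbers: list[int | None] = [None] * n
    active = np.ones(n, dtype=bool)
    next_number = 1

    def linkage_matrix() -> np.ndarray:
        if linkage == "average":
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(lk_cnt > 0, lk_sum / np.maximum(lk_cnt, 1.0), -np.inf)
        return lk

    while True:
        lm = linkage_matrix()
        cand = admiss & active[:, None] & active[None, :]
        cand = np.triu(cand, 1)
        if not cand.any():
            break
        masked = np.where(cand, lm, -np.inf)
        best = masked.max()
        ii, jj = np.nonzero(masked == best)
        if len(ii) == 1:
            i, j = int(ii[0]), int(jj[0])
        else:
            # deterministic tie-break: smallest combined sorted member-id tuple
            def key(t):
                a, b = t
                return tuple(sorted(ids[x] for x in members[a] + members[b]))
            i, j = min(zip(ii.tolist(), jj.tolist()), key=key)

        # assign/creation-order numbering
        ni, nj = numbers[i], numbers[j]
        if ni is None and nj is None:
            num = next_number
            next_number += 1
        elif ni is None:
            num = nj
        elif nj is None:
            num = ni
        else:
            num = min(ni, nj)
        numbers[i] = num
        members[i] = members[i] + members[j]  # type: ignore[operator]
        members[j] = None
        active[j] = False

        # update pairwise state of merged cluster i against all others
        admiss[i, :] &= admiss[j, :]
        admiss[:, i] = admiss[i, :]
        admiss[i, i] = False
        if linkage == "complete":
            lk[i, :] = np.minimum(lk[i, :], lk[j, :])
            lk[:, i] = lk[i, :]
        elif linkage == "single":
            lk[i, :] = np.maximum(lk[i, :], lk[j, :])
            lk[:, i] = lk[i, :]
        else:
            lk_sum[i, :] += lk_sum[j, :]
            lk_cnt[i, :] += lk_cnt[j, :]
            lk_sum[:, i] = lk_sum[i, :]
            lk_cnt[:, i] = lk_cnt[i, :]
            lk_sum[i, i] = 0.0
            lk_cnt[i, i] = 0.0

    clusters: dict[int, frozenset] = {}
    singles: set = set()
    for idx in np.flatnonzero(active):
        mem = members[idx]
        assert mem is not None
        if len(mem) >= 2:
            clusters[int(numbers[idx])] = frozenset(ids[x] for x in mem)  # type: ignore[arg-type]
        else:
            singles.add(ids[mem[0]])
    return ClusterSet(
        clusters=clusters,
        singletons=frozenset(singles),
        parameters={"r_star": r_star, "linkage": linkage, "min_overlap": corr.min_overlap},
    )


@dataclass
class ClusterComparison:
    """Best-Jaccard agreement of one clustering against another."""

    best_jaccard: dict[int, float]
    fraction_identical: float
    fraction_above_half: float


def compare_clusterings(a: ClusterSet, b: ClusterSet) -> ClusterComparison:
    """Per-cluster best Jaccard of ``a``'s clusters against ``b``'s clusters.

    Only proper clusters (size >= 2) are compared; singletons are ignored on
    both sides.  If ``a`` has no proper clusters the summary is empty (NaN
    fractions).  The two clusterings must cover the same item universe.
    """
    if a.item_ids != b.item_ids:
        raise ValueError("clusterings cover different item universes")
    b_sets = list(b.clusters.values())
    best: dict[int, float] = {}
    for num, members in a.clusters.items():
        if not b_sets:
            best[num] = 0.0
            continue
        best[num] = max(
            len(members & other) / len(members | other) for other in b_sets
        )
    if not best:
        return ClusterComparison({}, float("nan"), float("nan"))
    vals = np.array(list(best.values()))
    return ClusterComparison(
        best_jaccard=best,
        fraction_identical=float(np.mean(vals == 1.0)),
        fraction_above_half=float(np.mean(vals > 0.5)),
    )


class CorrelationClustering(ClusterMixin, BaseEstimator):
    """Clique-constrained agglomerative clustering of correlated profiles.

    scikit-learn style estimator: ``fit(X)`` clusters the *rows* of ``X``
    (shape ``(n_samples, n_features)``, NaN allowed) by pairwise-complete
    Pearson correlation.  To cluster the experiments of an RNA-by-experiment
    matrix, pass its transpose.

    Parameters
    ----------
    threshold : float, default 0.5
        Minimum pairwise correlation, strict, required inside a cluster.
    alpha : float, default 0.01
        Significance level for H0: r = 0 on every within-cluster pair.
    correction : {"bonferroni", "none"}, default "bonferroni"
        Multiple-testing correction applied to the pair p-values.
    linkage : {"complete", "average", "single"}, default "complete"
        Merge-scoring rule; admissibility is always the clique constraint.
    min_overlap : int, default 3
        Minimum jointly non-missing observations for a pair correlation.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster number per sample; ``-1`` marks unassigned singletons.
    clusters_ : ClusterSet
        The full partition with creation-order numbering.
    correlation_ : CorrelationMatrix
        Pairwise correlation structure of the fitted data.
    gate_ : ndarray of bool
        Significance-gate pass matrix.
    """

    def __init__(
        self,
        threshold: float = 0.5,
        alpha: float = 0.01,
        correction: str = "bonferroni",
        linkage: str = "complete",
        min_overlap: int = 3,
    ):
        self.threshold = threshold
        self.alpha = alpha
        self.correction = correction
        self.linkage = linkage
        self.min_overlap = min_overlap

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-D")
            frame = pd.DataFrame(X, index=[str(i) for i in range(X.shape[0])])
        self.correlation_ = pairwise_pearson(
            frame, axis="rows", min_overlap=self.min_overlap
        )
        self.gate_ = significance_gate(
            self.correlation_, alpha=self.alpha, correction=self.correction
        )
        self.clusters_ = constrained_agglomerative(
            self.correlation_, self.gate_, r_star=self.threshold, linkage=self.linkage
        )
        label_map = self.clusters_.labels()
        self.labels_ = np.array([label_map[str(i)] for i in frame.index])
        self.n_clusters_ = self.clusters_.n_clusters
        return self
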