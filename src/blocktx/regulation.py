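"""Regulatory and interaction coherence of transcriptional blocks.

Three evidence lines that members of a block act together: shared
transcription-factor regulators (pairwise Jaccard of per-gene TF sets,
against resampled nulls), block-TF association (Fisher + Bonferroni over
the full tested grid), and within-block excess of protein-protein or
genetic interaction edges (random-sampling null).

All empirical p-values follow the +1 convention
``p = (1 + #{null >= observed}) / (1 + n_samples)`` and are reproducible
under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import TFTargetMap

__all__ = [
    "jaccard",
    "JaccardSummary",
    "block_jaccard_profile",
    "jaccard_resampling_null",
    "tf_block_association",
    "tf_block_network",
    "EdgeExcessResult",
    "within_block_edge_excess",
]


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets give 0 (no shared-regulator evidence)."""
    a, b = frozenset(a), frozenset(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def _pair_median(genes_a, genes_b, reg, within: bool) -> float:
    vals = []
    if within:
        genes = list(genes_a)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                vals.append(jaccard(reg[genes[i]], reg[genes[j]]))
    else:
        for g in genes_a:
            for h in genes_b:
                vals.append(jaccard(reg[g], reg[h]))
    return float(np.median(vals))


@dataclass
class JaccardSummary:
    """Within-block and between-block-pair median TF-sharing Jaccard.

    ``within`` maps block id -> median of all pairwise gene-level Jaccards;
    ``between`` maps an ordered (block_a, block_b) pair -> median cross
    Jaccard.  Null distributions and empirical p-values are attached by
    :func:`jaccard_resampling_null`.
    """

    within: dict[str, float]
    between: dict[tuple[str, str], float]
    n_unannotated: int = 0
    null_within: dict[str, np.ndarray] = field(default_factory=dict)
    null_between: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    p_within: dict[str, float] = field(default_factory=dict)
    p_between: dict[tuple[str, str], float] = field(default_factory=dict)
    n_samples: int = 0
    seed: int | None = None


def _annotated_blocks(blocks, tfmap: TFTargetMap):
    reg = tfmap.regulators
    kept: dict[str, list[str]] = {}
    dropped = 0
    for bid, members in dict(blocks).items():
        annotated = [g for g in members if g in reg]
        dropped += len(list(members)) - len(annotated)
        if len(annotated) < 2:
            warnings.warn(f"block {bid!r} has fewer than 2 TF-annotated genes; skipped")
            continue
        kept[bid] = annotated
    return kept, reg, dropped


def block_jaccard_profile(blocks, tfmap: TFTargetMap) -> JaccardSummary:
    """Median TF-sharing Jaccard within each block and between block pairs.

    ``blocks`` is a mapping block id -> gene ids.  Genes without any TF
    annotation are excluded (their count is recorded); blocks left with
    fewer than 2 annotated genes are skipped with a warning.
    """
    kept, reg, dropped = _annotated_blocks(blocks, tfmap)
    within = {bid: _pair_median(g, g, reg, within=True) for bid, g in kept.items()}
    between: dict[tuple[str, str], float] = {}
    ids = list(kept)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            between[(ids[i], ids[j])] = _pair_median(
                kept[ids[i]], kept[ids[j]], reg, within=False
            )
    return JaccardSummary(within=within, between=between, n_unannotated=dropped)


def jaccard_resampling_null(
    blocks, tfmap: TFTargetMap, n_samples: int = 1000, seed: int | None = None
) -> JaccardSummary:
    """Resampling nulls for the within/between median Jaccard statistics.

    For each block of size n, ``n_samples`` same-size uniform draws (without
    replacement) from the TF-annotated gene universe give the null of the
    within-block median; block pairs are resampled jointly for the between
    statistic.  Empirical p-values use the +1 convention with the >= tail
    (the between-block tail of interest is usually the lower one; use
    ``1 - p + 1/(n_samples+1)`` grid logic or inspect the stored null).
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    summary = block_jaccard_profile(blocks, tfmap)
    kept, reg, _ = _annotated_blocks(blocks, tfmap)
    universe = sorted(reg)
    rng = np.random.default_rng(seed)
    for bid, genes in kept.items():
        n = len(genes)
        if n > len(universe):
            raise ValueError(f"block {bid!r} larger than the annotated universe")
        null = np.empty(n_samples)
        for s in range(n_samples):
            draw = rng.choice(universe, size=n, replace=False)
            null[s] = _pair_median(draw, draw, reg, within=True)
        obs = summary.within[bid]
        summary.null_within[bid] = null
        summary.p_within[bid] = (1 + int(np.sum(null >= obs))) / (1 + n_samples)
    for (ba, bb), obs in summary.between.items():
        na, nb = len(kept[ba]), len(kept[bb])
        if na + nb > len(universe):
            raise ValueError("block pair larger than the annotated universe")
        null = np.empty(n_samples)
        for s in range(n_samples):
            draw = rng.choice(universe, size=na + nb, replace=False)
            null[s] = _pair_median(draw[:na], draw[na:], reg, within=False)
        summary.null_between[(ba, bb)] = null
        summary.p_between[(ba, bb)] = (1 + int(np.sum(null >= obs))) / (1 + n_samples)
    summary.n_samples = n_samples
    summary.seed = seed
    return summary


def tf_block_association(
    block, tf_targets, universe, n_blocks_tested: int = 1, n_tfs_tested: int = 1
):
    """Fisher association of one block with one TF's target set.

    Returns ``(odds_ratio, p_raw, p_bonferroni)``; the Bonferroni multiplier
    is the full tested grid, #blocks x #TFs.
    """
    block = frozenset(block)
    universe = frozenset(universe)
    if not block <= universe:
        raise ValueError("block is not contained in the universe")
    targets = frozenset(tf_targets) & universe
    if not targets:
        raise ValueError("TF has no targets in the universe")
    a = len(block & targets)
    b = len(block) - a
    c = len(targets) - a
    d = len(universe) - len(block) - c
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(targets), len(block)))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    multiplier = max(1, n_blocks_tested * n_tfs_tested)
    return float(odds), min(p, 1.0), min(p * multiplier, 1.0)


def tf_block_network(blocks, tfmap: TFTargetMap, universe, alpha: float = 0.01):
    """All block-TF associations; edges with Bonferroni-adjusted p < alpha.

    Returns ``(edges, all_tests)`` where each is a list of dicts with keys
    block, tf, odds_ratio, p_raw, p_adjusted.  Suitable for writing as a
    TSV edge list loadable by standard graph tools.
    """
    blocks = dict(blocks)
    universe = frozenset(universe)
    tested_tfs = {
        tf: frozenset(t) & universe
        for tf, t in tfmap.targets.items()
        if frozenset(t) & universe
    }
    multiplier = len(blocks) * len(tested_tfs)
    all_tests = []
    for bid, members in blocks.items():
        block = frozenset(members) & universe
        for tf, targets in tested_tfs.items():
            odds, p_raw, p_adj = tf_block_association(
                block, targets, universe,
                n_blocks_tested=len(blocks), n_tfs_tested=len(tested_tfs),
            )
            all_tests.append(
                dict(block=bid, tf=tf, odds_ratio=odds, p_raw=p_raw, p_adjusted=p_adj)
            )
    edges = [t for t in all_tests if t["p_adjusted"] < alpha]
    return edges, all_tests


@dataclass
class EdgeExcessResult:
    """Within-block interaction-edge count against a random-sampling null."""

    block_id: str
    observed: int
    null_mean: float
    null_sd: float
    p_value: float
    n_samples: int
    seed: int | None


def within_block_edge_excess(
    block,
    edges: set,
    universe=None,
    n_samples: int = 1000,
    seed: int | None = None,
    block_id: str = "",
) -> EdgeExcessResult:
    """Is a block internally more connected than random same-size gene draws?

    ``edges`` is a set of 2-element frozensets (undirected, deduplicated,
    no self-loops; PPI and GI should be tested separately).  The null draws
    same-size gene sets uniformly from ``universe`` (default: all genes
    incident to an edge) and counts internal edges; the empirical p uses
    the +1 convention.
    """
    block = frozenset(block)
    if universe is None:
        uni: set = set()
        for e in edges:
            uni |= set(e)
        universe = uni
    universe = sorted(frozenset(universe))
    if len(block) > len(universe):
        raise ValueError("block larger than the gene universe")
    adj: dict[str, set] = {}
    for e in edges:
        a, b = tuple(e)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def internal_edges(genes) -> int:
        gs = set(genes)
        count = 0
        for g in gs:
            count += len(adj.get(g, set()) & gs)
        return count // 2

    observed = internal_edges(block)
    rng = np.random.default_rng(seed)
    null = np.empty(n_samples)
    for s in range(n_samples):
        null[s] = internal_edges(rng.choice(universe, size=len(block), replace=False))
    p = (1 + int(np.sum(null >= observed))) / (1 + n_samples)
    return EdgeExcessResult(
        block_id=block_id,
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_samples > 1 else 0.0,
        p_value=p,
        n_samples=n_samples,
        seed=seed,
    )
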