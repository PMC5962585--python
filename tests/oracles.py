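"""Independent brute-force oracles used by the test suite.

Each function recomputes a statistic by direct enumeration or a naive
loop, sharing no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


def naive_pairwise_pearson(data: np.ndarray, min_overlap: int = 3):
    """Two-loop pairwise-complete Pearson over the columns of ``data``."""
    p = data.shape[1]
    r = np.full((p, p), np.nan)
    n = np.zeros((p, p), dtype=int)
    for i in range(p):
        for j in range(p):
            x, y = data[:, i], data[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            n[i, j] = ok.sum()
            if n[i, j] < min_overlap:
                continue
            xs, ys = x[ok], y[ok]
            sx, sy = xs.std(ddof=0), ys.std(ddof=0)
            if sx == 0 or sy == 0:
                continue
            r[i, j] = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
    return r, n


def hypergeom_tail(a: int, universe: int, term: int, query: int) -> float:
    """P(X >= a) for X hypergeometric, by direct summation of the pmf."""
    total = 0.0
    for k in range(a, min(term, query) + 1):
        total += (
            math.comb(term, k)
            * math.comb(universe - term, query - k)
            / math.comb(universe, query)
        )
    return min(total, 1.0)


def bh_step_up(p_values) -> np.ndarray:
    """Hand-written BH step-up: adj_i = min_{j>=rank(i)} (m/j) p_(j), clip 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for pos in range(m - 1, -1, -1):
        running = min(running, m / (pos + 1) * p[order[pos]])
        adj_sorted[pos] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def signed_rank_exact_p(values) -> float:
    """Two-sided one-sample signed-rank p by full 2^n enumeration.

    Zeros are dropped, |values| ranked with midranks; the null distributes
    each sign independently at 1/2.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    if n == 0:
        return float("nan")
    ranks = rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    stats = []
    for signs in itertools.product((0, 1), repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats)
    total = stats.size
    lower = np.sum(stats <= w_obs + 1e-12) / total
    upper = np.sum(stats >= w_obs - 1e-12) / total
    return min(1.0, 2.0 * min(lower, upper))


def greedy_clique_replay(ids, r, edge, r_star=0.5, linkage="complete"):
    """Naive replay of the best-first constrained agglomeration.

    ``r`` and ``edge`` are dense matrices over ``ids``; returns
    (set of frozenset clusters (size >= 2), frozenset of singletons).
    """
    clusters: list[list[int]] = [[i] for i in range(len(ids))]
    while True:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cross = [
                    (i, j) for i in clusters[a] for j in clusters[b]
                ]
                if not all(edge[i, j] and np.isfinite(r[i, j]) and r[i, j] > r_star
                           for i, j in cross):
                    continue
                vals = [r[i, j] for i, j in cross]
                if linkage == "complete":
                    score = min(vals)
                elif linkage == "single":
                    score = max(vals)
                else:
                    score = float(np.mean(vals))
                key = tuple(sorted(ids[x] for x in clusters[a] + clusters[b]))
                if best is None or score > best[0] or (score == best[0] and key < best[1]):
                    best = (score, key, a, b)
        if best is None:
            break
        _, _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    proper = {frozenset(ids[i] for i in c) for c in clusters if len(c) >= 2}
    singles = frozenset(ids[c[0]] for c in clusters if len(c) == 1)
    return proper, singles


def best_jaccard_all_pairs(a_sets, b_sets):
    """Brute-force per-cluster best Jaccard of ``a_sets`` against ``b_sets``."""
    out = {}
    for name, members in a_sets.items():
        members = frozenset(members)
        best = 0.0
        for other in b_sets.values():
            other = frozenset(other)
            if members | other:
                best = max(best, len(members & other) / len(members | other))
        out[name] = best
    return out


def exact_edge_excess_p(block_size, universe, edges, observed) -> float:
    """P(internal edges >= observed) by enumerating all same-size draws."""
    universe = sorted(universe)
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, block_size):
        s = set(combo)
        count = sum(1 for e in edges if set(e) <= s)
        total += 1
        hits += count >= observed
    return hits / total
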