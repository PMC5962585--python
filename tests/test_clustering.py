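import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from blocktx.clustering import (
    ClusterSet,
    CorrelationClustering,
    compare_clusterings,
    constrained_agglomerative,
)
from blocktx.correlation import CorrelationMatrix, pairwise_pearson, significance_gate
from blocktx.simulate import GeneratorConfig, generate_matrix

from oracles import best_jaccard_all_pairs, greedy_clique_replay


def corr_from_r(r, n=50):
    """Wrap a hand-built r matrix; every defined pair gets n observations."""
    r = np.asarray(r, dtype=float)
    k = r.shape[0]
    n_pairs = np.full((k, k), n, dtype=int)
    p = np.where(np.isfinite(r), 1e-12, np.nan)  # tiny p: gate decided by alpha alone
    np.fill_diagonal(p, np.nan)
    return CorrelationMatrix(
        item_ids=[f"i{x}" for x in range(k)], r=r, n_pairs=n_pairs, p_raw=p, min_overlap=3
    )


def all_true_gate(k):
    g = np.ones((k, k), dtype=bool)
    np.fill_diagonal(g, False)
    return g


class TestConstrainedAgglomerative:
    def test_mutually_correlated_triple_forms_one_cluster(self):
        r = np.full((3, 3), 0.9)
        np.fill_diagonal(r, 1.0)
        out = constrained_agglomerative(corr_from_r(r), all_true_gate(3))
        assert out.n_clusters == 1
        assert out.clusters[1] == frozenset({"i0", "i1", "i2"})
        assert not out.singletons

    def test_subthreshold_correlations_leave_singletons(self):
        r = np.full((4, 4), 0.5)  # threshold is strict: r > 0.5 required
        np.fill_diagonal(r, 1.0)
        out = constrained_agglomerative(corr_from_r(r), all_true_gate(4))
        assert out.n_clusters == 0
        assert len(out.singletons) == 4

    def test_gate_failure_blocks_merge(self):
        r = np.full((3, 3), 0.9)
        np.fill_diagonal(r, 1.0)
        gate = all_true_gate(3)
        gate[0, 1] = gate[1, 0] = False
        out = constrained_agglomerative(corr_from_r(r), gate)
        # 0 and 1 can never share a cluster; best pair among the rest wins
        labels = out.labels()
        assert labels["i0"] != labels["i1"] or labels["i0"] == -1

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_greedy_replay(self, seed, linkage):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 9))
        base = rng.uniform(-0.2, 1.0, size=(k, k))
        r = (base + base.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = corr_from_r(r)
        gate = all_true_gate(k)
        # knock out a few gate cells to exercise the constraint
        for _ in range(k // 2):
            i, j = rng.integers(0, k, size=2)
            if i != j:
                gate[i, j] = gate[j, i] = False
        out = constrained_agglomerative(corr, gate, linkage=linkage)
        edge = gate & (r > 0.5)
        oracle_clusters, oracle_singles = greedy_clique_replay(
            corr.item_ids, r, edge, r_star=0.5, linkage=linkage
        )
        assert set(out.clusters.values()) == oracle_clusters
        assert out.singletons == oracle_singles

    def test_exact_tie_broken_by_member_ids(self):
        # two identical-score candidate merges: (i0,i1) and (i2,i3)
        r = np.array(
            [
                [1.0, 0.8, 0.1, 0.1],
                [0.8, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.8],
                [0.1, 0.1, 0.8, 1.0],
            ]
        )
        out = constrained_agglomerative(corr_from_r(r), all_true_gate(4))
        # i0/i1 merge first -> cluster number 1; i2/i3 get number 2
        assert out.clusters[1] == frozenset({"i0", "i1"})
        assert out.clusters[2] == frozenset({"i2", "i3"})

    def test_clique_property_holds_post_hoc(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, 40, 15, missing=0.1)
        corr = pairwise_pearson(m, axis="columns")
        gate = significance_gate(corr, alpha=0.05, correction="none")
        out = constrained_agglomerative(corr, gate, r_star=0.3)
        idx = {str(i): k for k, i in enumerate(corr.item_ids)}
        for members in out.clusters.values():
            members = sorted(members)
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    i, j = idx[members[a]], idx[members[b]]
                    assert np.isfinite(corr.r[i, j]) and corr.r[i, j] > 0.3
                    assert gate[i, j]

    def test_raising_threshold_refines_partition(self):
        cfg = GeneratorConfig(
            seed=5,
            btr_sizes=(6, 6, 6),
            psr_sizes=(4, 4, 4),
            n_background_rna=10,
            n_background_experiments=3,
        )
        matrix, _ = generate_matrix(cfg)
        corr = pairwise_pearson(matrix, axis="columns")
        gate = significance_gate(corr, alpha=0.01)
        low = constrained_agglomerative(corr, gate, r_star=0.3)
        high = constrained_agglomerative(corr, gate, r_star=0.6)
        assert max(high.sizes().values(), default=0) <= max(low.sizes().values(), default=0)
        low_clusters = list(low.clusters.values())
        for members in high.clusters.values():
            assert any(members <= big for big in low_clusters), (
                "every high-threshold cluster must sit inside one low-threshold cluster"
            )

    def test_planted_blocks_recovered(self):
        for seed in (0, 1, 2):
            cfg = GeneratorConfig(
                seed=seed,
                btr_sizes=(8, 8, 8, 8),
                psr_sizes=(8,) * 6,
                n_background_rna=15,
                n_background_experiments=12,
            )
            matrix, truth = generate_matrix(cfg)
            model = CorrelationClustering().fit(matrix)
            labels = model.clusters_.labels()
            ids = [r for r in matrix.index if truth.rna_block[r] is not None]
            true = [truth.rna_block[r] for r in ids]
            found = []
            fresh = -2
            for r in ids:
                lab = labels[r]
                found.append(lab if lab != -1 else (fresh := fresh - 1))
            assert adjusted_rand_score(true, found) >= 0.95


class TestClusterSet:
    def test_partition_invariants_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            ClusterSet(
                clusters={1: frozenset({"a", "b"}), 2: frozenset({"b", "c"})},
                singletons=frozenset(),
            )
        with pytest.raises(ValueError, match="fewer than 2"):
            ClusterSet(clusters={1: frozenset({"a"})}, singletons=frozenset())

    def test_labels_and_gene_sets(self):
        cs = ClusterSet(
            clusters={1: frozenset({"a", "b"})}, singletons=frozenset({"c"})
        )
        assert cs.labels() == {"a": 1, "b": 1, "c": -1}
        assert cs.to_gene_sets(prefix="BTR").sets == {"BTR1": ("a", "b")}


class TestCompareClusterings:
    def test_identical_clusterings_fully_agree(self):
        cs = ClusterSet(
            clusters={1: frozenset({"a", "b"}), 2: frozenset({"c", "d", "e"})},
            singletons=frozenset({"f"}),
        )
        cmp_ = compare_clusterings(cs, cs)
        assert cmp_.fraction_identical == 1.0
        assert cmp_.fraction_above_half == 1.0

    def test_all_singletons_gives_empty_summary(self):
        a = ClusterSet(clusters={}, singletons=frozenset("abcdefghij"))
        b = ClusterSet(
            clusters={1: frozenset("abcdefghij")}, singletons=frozenset()
        )
        cmp_ = compare_clusterings(a, b)
        assert cmp_.best_jaccard == {}
        assert np.isnan(cmp_.fraction_identical)

    def test_disjoint_universes_rejected(self):
        a = ClusterSet(clusters={1: frozenset({"a", "b"})}, singletons=frozenset())
        b = ClusterSet(clusters={1: frozenset({"x", "y"})}, singletons=frozenset())
        with pytest.raises(ValueError):
            compare_clusterings(a, b)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"g{i}" for i in range(30)]

        def random_partition():
            labels = rng.integers(0, 6, size=30)
            clusters = {}
            singles = set()
            for lab in np.unique(labels):
                members = frozenset(np.array(items)[labels == lab])
                if len(members) >= 2:
                    clusters[len(clusters) + 1] = members
                else:
                    singles |= members
            return ClusterSet(clusters=clusters, singletons=frozenset(singles))

        a, b = random_partition(), random_partition()
        cmp_ = compare_clusterings(a, b)
        oracle = best_jaccard_all_pairs(
            {num: m for num, m in a.clusters.items()},
            {num: m for num, m in b.clusters.items()},
        )
        assert cmp_.best_jaccard == pytest.approx(oracle)


class TestEstimatorContract:
    def test_get_set_params_round_trip(self):
        model = CorrelationClustering(threshold=0.6, alpha=0.05)
        params = model.get_params()
        assert params["threshold"] == 0.6
        clone = CorrelationClustering().set_params(**params)
        assert clone.get_params() == params

    def test_fit_sets_sklearn_style_attributes(self, rng):
        X = rng.normal(size=(12, 30))
        model = CorrelationClustering(correction="none", alpha=0.2).fit(X)
        assert model.labels_.shape == (12,)
        assert hasattr(model, "clusters_") and hasattr(model, "correlation_")
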