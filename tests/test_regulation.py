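import itertools

import numpy as np
import pytest

from blocktx.io import TFTargetMap
from blocktx.regulation import (
    block_jaccard_profile,
    jaccard,
    jaccard_resampling_null,
    tf_block_association,
    tf_block_network,
    within_block_edge_excess,
)

from oracles import exact_edge_excess_p, hypergeom_tail


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)


def tfmap_from(regulators):
    pairs = [(tf, g) for g, tfs in regulators.items() for tf in tfs]
    return TFTargetMap.from_pairs(pairs)


class TestBlockJaccardProfile:
    def test_identical_tf_sets_give_median_one(self):
        reg = {f"g{i}": {"TF1", "TF2"} for i in range(4)}
        summary = block_jaccard_profile({"b": list(reg)}, tfmap_from(reg))
        assert summary.within["b"] == pytest.approx(1.0)

    def test_disjoint_vocabularies_give_between_zero(self):
        reg = {"a1": {"TFx"}, "a2": {"TFx"}, "b1": {"TFy"}, "b2": {"TFy"}}
        summary = block_jaccard_profile(
            {"A": ["a1", "a2"], "B": ["b1", "b2"]}, tfmap_from(reg)
        )
        assert summary.between[("A", "B")] == pytest.approx(0.0)

    def test_matches_brute_force_all_pairs(self, rng):
        genes = [f"g{i}" for i in range(12)]
        tfs = [f"TF{i}" for i in range(6)]
        reg = {
            g: set(rng.choice(tfs, size=rng.integers(1, 4), replace=False))
            for g in genes
        }
        blocks = {"b1": genes[:4], "b2": genes[4:8], "b3": genes[8:]}
        summary = block_jaccard_profile(blocks, tfmap_from(reg))
        for bid, members in blocks.items():
            vals = [jaccard(reg[a], reg[b]) for a, b in itertools.combinations(members, 2)]
            assert summary.within[bid] == pytest.approx(np.median(vals))
        for ba, bb in itertools.combinations(blocks, 2):
            vals = [jaccard(reg[a], reg[b])
                    for a in blocks[ba] for b in blocks[bb]]
            assert summary.between[(ba, bb)] == pytest.approx(np.median(vals))

    def test_unannotated_genes_excluded_small_blocks_skipped(self):
        reg = {"a1": {"TF1"}, "a2": {"TF1"}}
        blocks = {"ok": ["a1", "a2", "ghost"], "tiny": ["ghost2", "ghost3"]}
        with pytest.warns(UserWarning, match="tiny"):
            summary = block_jaccard_profile(blocks, tfmap_from(reg))
        assert set(summary.within) == {"ok"}
        assert summary.n_unannotated == 3


class TestJaccardResamplingNull:
    def _heterogeneous_map(self, rng, n_genes=60, n_tfs=12):
        genes = [f"g{i:02d}" for i in range(n_genes)]
        tfs = [f"TF{i}" for i in range(n_tfs)]
        reg = {
            g: set(rng.choice(tfs, size=rng.integers(1, 4), replace=False))
            for g in genes
        }
        return genes, reg

    def test_maximal_statistic_gives_minimal_p(self, rng):
        genes, reg = self._heterogeneous_map(rng)
        for g in genes[:5]:
            reg[g] = {"TFshared"}
        summary = jaccard_resampling_null(
            {"b": genes[:5]}, tfmap_from(reg), n_samples=100, seed=0
        )
        assert summary.p_within["b"] == pytest.approx(1 / 101)

    def test_fixed_seed_reproducible(self, rng):
        genes, reg = self._heterogeneous_map(rng)
        blocks = {"b": genes[:6]}
        s1 = jaccard_resampling_null(blocks, tfmap_from(reg), n_samples=100, seed=42)
        s2 = jaccard_resampling_null(blocks, tfmap_from(reg), n_samples=100, seed=42)
        np.testing.assert_array_equal(s1.null_within["b"], s2.null_within["b"])
        assert s1.p_within == s2.p_within

    def test_block_pair_larger_than_universe_rejected(self):
        # overlapping blocks can exceed the annotated universe jointly
        reg = {"a": {"TF1"}, "b": {"TF2"}, "c": {"TF1", "TF2"}}
        with pytest.raises(ValueError, match="universe"):
            jaccard_resampling_null(
                {"A": ["a", "b"], "B": ["b", "c"]},
                tfmap_from(reg),
                n_samples=100,
                seed=0,
            )

    def test_planted_blocks_within_above_between(self):
        # co-regulated planted blocks: within-median exceeds between-median
        from blocktx.simulate import GeneratorConfig, generate_matrix, generate_regulation

        wins = trials = 0
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed, btr_sizes=(10, 10, 10),
                                  psr_sizes=(5, 5), n_background_rna=40,
                                  n_background_experiments=3)
            _, truth = generate_matrix(cfg)
            _, tfmap, _ = generate_regulation(truth, cfg)
            summary = block_jaccard_profile(truth.block_members(), tfmap)
            trials += 1
            wins += np.median(list(summary.within.values())) > np.median(
                list(summary.between.values())
            )
        assert wins == trials


class TestTFBlockAssociation:
    def test_dedicated_tf_yields_minimal_p_and_edge(self):
        universe = [f"g{i:03d}" for i in range(300)]
        block = universe[:10]
        tfmap = TFTargetMap.from_pairs([("TFb", g) for g in block])
        odds, p_raw, p_adj = tf_block_association(
            block, tfmap.targets["TFb"], universe, n_blocks_tested=5, n_tfs_tested=4
        )
        assert p_raw == pytest.approx(hypergeom_tail(10, 300, 10, 10), rel=1e-9)
        edges, _ = tf_block_network({"b": block}, tfmap, universe)
        assert edges and edges[0]["tf"] == "TFb"

    def test_uniform_tf_is_null(self):
        universe = [f"g{i}" for i in range(100)]
        tfmap = TFTargetMap.from_pairs([("TFall", g) for g in universe])
        _, _, p_adj = tf_block_association(
            universe[:10], tfmap.targets["TFall"], universe,
            n_blocks_tested=3, n_tfs_tested=3,
        )
        assert p_adj == 1.0

    def test_toy_grid_matches_hypergeometric_oracle(self, rng):
        universe = [f"g{i:02d}" for i in range(40)]
        blocks = {f"b{k}": list(rng.choice(universe, size=6, replace=False))
                  for k in range(5)}
        tfmap = TFTargetMap.from_pairs(
            [(f"TF{k}", g)
             for k in range(4)
             for g in rng.choice(universe, size=10, replace=False)]
        )
        _, all_tests = tf_block_network(blocks, tfmap, universe)
        assert len(all_tests) == 20
        for t in all_tests:
            a = len(set(blocks[t["block"]]) & tfmap.targets[t["tf"]])
            expected = hypergeom_tail(
                a, 40, len(tfmap.targets[t["tf"]]), len(blocks[t["block"]])
            )
            assert t["p_raw"] == pytest.approx(expected, rel=1e-9)
            assert t["p_adjusted"] == pytest.approx(min(1.0, expected * 20), rel=1e-9)


class TestEdgeExcess:
    def test_empty_edge_list(self):
        result = within_block_edge_excess(
            {"a", "b", "c"}, set(), universe=list("abcdefgh"), n_samples=100, seed=0
        )
        assert result.observed == 0
        assert result.p_value == 1.0

    def test_clique_in_empty_graph_is_minimal_p(self):
        genes = [f"g{i}" for i in range(12)]
        clique = genes[:4]
        edges = {frozenset(e) for e in itertools.combinations(clique, 2)}
        result = within_block_edge_excess(
            clique, edges, universe=genes, n_samples=200, seed=1
        )
        assert result.observed == 6
        assert result.p_value == pytest.approx(1 / 201)

    def test_empirical_p_matches_exhaustive_enumeration(self, rng):
        genes = [f"g{i}" for i in range(12)]
        edges = {
            frozenset(pair)
            for pair in itertools.combinations(genes, 2)
            if rng.random() < 0.2
        }
        block = genes[:4]
        result = within_block_edge_excess(
            block, edges, universe=genes, n_samples=4000, seed=3
        )
        exact = exact_edge_excess_p(4, genes, edges, result.observed)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(result.p_value - exact) <= 3 * se + 1 / 4001

    def test_block_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            within_block_edge_excess(
                {"a", "b", "c"}, set(), universe=["a", "b"], n_samples=100, seed=0
            )
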