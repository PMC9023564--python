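"""Microsynteny detection, clustering, classification, randomization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from syntopo.synteny import (build_clusters, classify_clusters,
                             detect_pairwise_blocks, measure_block_geometry,
                             merge_blocks_to_clusters, sample_random_blocks,
                             shuffle_null)
from syntopo.synthetic import score_detection

from .conftest import make_genome, orthology_from_genomes, random_toy_pair
from .oracles import blocks_as_sets, oracle_pairwise_blocks


def detect_tokens(tokens_a, tokens_b, **kw):
    a = make_genome("A", {"c1": tokens_a})
    b = make_genome("B", {"c1": tokens_b})
    return detect_pairwise_blocks(a, b, orthology_from_genomes(a, b), **kw)


class TestDetector:
    def test_five_intervening_allowed(self):
        blocks = detect_tokens(
            ["f1", "x", "x", "x", "x", "x", "f2", "f3"], ["f1", "f2", "f3"])
        assert len(blocks) == 1
        assert blocks[0].families == {"f1", "f2", "f3"}

    def test_six_intervening_breaks_the_chain(self):
        blocks = detect_tokens(
            ["f1", "x", "x", "x", "x", "x", "x", "f2", "f3"],
            ["f1", "f2", "f3"])
        assert blocks == []

    def test_collinearity_not_required(self):
        blocks = detect_tokens(["f1", "f2", "f3"], ["f3", "f1", "f2"])
        assert len(blocks) == 1
        assert blocks[0].families == {"f1", "f2", "f3"}

    def test_tandem_array_does_not_qualify(self):
        # three copies of one family collapse to a single distinct family
        blocks = detect_tokens(["f1", "f1", "f1"], ["f1", "f1", "f1"])
        assert blocks == []

    def test_min_genes_below_two_rejected(self):
        with pytest.raises(ValueError):
            detect_tokens(["f1", "f2", "f3"], ["f1", "f2", "f3"], min_genes=1)

    def test_empty_genome_yields_empty_result(self):
        a = make_genome("A", {"c1": []})
        b = make_genome("B", {"c1": ["f1", "f2", "f3"]})
        assert detect_pairwise_blocks(a, b, orthology_from_genomes(a, b)) == []

    def test_symmetry_of_sides(self):
        a = make_genome("A", {"c1": ["f1", "x", "f2", "f3", "f4"]})
        b = make_genome("B", {"c1": ["f4", "f2", "x", "x", "f1", "f3"]})
        orth = orthology_from_genomes(a, b)
        ab = {(frozenset(x.genes_a), frozenset(x.genes_b))
              for x in detect_pairwise_blocks(a, b, orth)}
        ba = {(frozenset(x.genes_b), frozenset(x.genes_a))
              for x in detect_pairwise_blocks(b, a, orth)}
        assert ab == ba

    def test_matches_window_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a, b, orth = random_toy_pair(rng, max_genes=25)
            got = blocks_as_sets(detect_pairwise_blocks(a, b, orth))
            assert got == oracle_pairwise_blocks(a, b, orth)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reversal_invariance(self, seed):
        """Reversing a whole chromosome's order preserves the blocks."""
        rng = np.random.default_rng(seed)
        a, b, orth = random_toy_pair(rng, max_genes=20)
        genes = a.chromosomes["c1"]
        total = genes[-1].end
        from syntopo.genome import Gene, GenomeOrder
        rev = GenomeOrder("A", {"c1": [
            Gene(g.gene_id, total - g.end, total - g.start, g.strand)
            for g in genes]})
        fwd = {frozenset(x.genes_a) | frozenset(x.genes_b)
               for x in detect_pairwise_blocks(a, b, orth)}
        bwd = {frozenset(x.genes_a) | frozenset(x.genes_b)
               for x in detect_pairwise_blocks(rev, b, orth)}
        assert fwd == bwd


class TestMerge:
    def _blocks(self, tokens_by_species):
        genomes = {sp: make_genome(sp, {"c1": toks})
                   for sp, toks in tokens_by_species.items()}
        orth = orthology_from_genomes(*genomes.values())
        blocks = []
        names = list(genomes)
        for i, x in enumerate(names):
            for y in names[i + 1:]:
                blocks += detect_pairwise_blocks(genomes[x], genomes[y], orth)
        return blocks, genomes

    def test_three_species_identical_families_one_cluster(self):
        blocks, genomes = self._blocks({
            "A": ["f1", "f2", "f3"], "B": ["f1", "f2", "f3"],
            "C": ["f3", "f2", "f1"]})
        clusters = merge_blocks_to_clusters(blocks, genomes.values())
        assert len(clusters) == 1
        assert clusters[0].species_present == {"A", "B", "C"}

    def test_disjoint_families_stay_separate(self):
        blocks, genomes = self._blocks({
            "A": ["f1", "f2", "f3", "x", "x", "x", "x", "x", "x",
                  "g1", "g2", "g3"],
            "B": ["f1", "f2", "f3", "x", "x", "x", "x", "x", "x",
                  "g1", "g2", "g3"]})
        clusters = merge_blocks_to_clusters(blocks, genomes.values())
        assert len(clusters) == 2

    def test_transitive_closure_chains_clusters(self):
        """Jaccard edges merge transitively even when the extreme pair is
        below the threshold (union-find behaviour)."""
        import networkx as nx
        from syntopo.synteny import PairwiseBlock, _jaccard

        def pb(i, fams):
            return PairwiseBlock("A", "B", "c1", "c1",
                                 tuple(f"a{i}{k}" for k in range(3)),
                                 tuple(f"b{i}{k}" for k in range(3)),
                                 frozenset(fams))
        b1 = pb(1, ["f1", "f2", "f3", "f4"])
        b2 = pb(2, ["f2", "f3", "f4", "f5"])
        b3 = pb(3, ["f3", "f4", "f5", "f6"])
        assert _jaccard(b1.families, b2.families) >= 0.5
        assert _jaccard(b2.families, b3.families) >= 0.5
        assert _jaccard(b1.families, b3.families) < 0.5
        # union-find oracle
        uf = nx.utils.UnionFind([0, 1, 2])
        for i, x in enumerate([b1, b2, b3]):
            for j, y in enumerate([b1, b2, b3]):
                if i < j and _jaccard(x.families, y.families) >= 0.5:
                    uf.union(i, j)
        n_components = len(list(uf.to_sets()))
        genome_a = make_genome("A", {"c1": []})  # placeholder coords
        from syntopo.genome import Gene, GenomeOrder
        ga = GenomeOrder("A", {"c1": [
            Gene(f"a{i}{k}", 1000 * (10 * i + k), 1000 * (10 * i + k) + 100)
            for i in (1, 2, 3) for k in range(3)]})
        gb = GenomeOrder("B", {"c1": [
            Gene(f"b{i}{k}", 1000 * (10 * i + k), 1000 * (10 * i + k) + 100)
            for i in (1, 2, 3) for k in range(3)]})
        clusters = merge_blocks_to_clusters([b1, b2, b3], [ga, gb])
        assert len(clusters) == n_components == 1

    def test_merge_is_input_order_invariant(self):
        blocks, genomes = self._blocks({
            "A": ["f1", "f2", "f3"], "B": ["f1", "f2", "f3"],
            "C": ["f1", "f2", "f3"]})
        fwd = merge_blocks_to_clusters(blocks, genomes.values())
        rev = merge_blocks_to_clusters(blocks[::-1], genomes.values())
        assert {c.families for c in fwd} == {c.families for c in rev}


class TestClassify:
    def _cluster(self, species):
        from syntopo.synteny import ClusterInstance, SyntenyCluster
        return SyntenyCluster(
            "cl0", frozenset(["f1", "f2", "f3"]),
            {sp: [ClusterInstance("c1", ("g1", "g2", "g3"), 0, 100)]
             for sp in species})

    def test_reference_plus_clade_mate_is_novel(self):
        cl = self._cluster(["ref", "mate"])
        classify_clusters([cl], {"ref", "mate"}, {"ref", "mate", "o1", "o2"},
                          reference="ref")
        assert cl.label == "novel_clade"

    def test_reference_plus_seven_outgroups_is_ancient(self):
        outs = [f"o{i}" for i in range(7)]
        cl = self._cluster(["ref"] + outs)
        classify_clusters([cl], {"ref", "mate"},
                          {"ref", "mate", *outs}, reference="ref")
        assert cl.label == "ancient"

    def test_reference_plus_one_outgroup_is_other(self):
        cl = self._cluster(["ref", "o1"])
        classify_clusters([cl], {"ref", "mate"}, {"ref", "mate", "o1", "o2"},
                          reference="ref")
        assert cl.label == "other"

    def test_intermediate_clade_label(self):
        cl = self._cluster(["ref", "m1", "m2", "m3", "m4", "m5"])
        species = {"ref", "mate", "m1", "m2", "m3", "m4", "m5", "o1"}
        classify_clusters(
            [cl], {"ref", "mate"}, species, reference="ref",
            clade_hierarchy=[("molluscan",
                              {"ref", "mate", "m1", "m2", "m3", "m4", "m5"},
                              5)])
        assert cl.label == "molluscan"

    def test_missing_reference_counts_skip(self):
        cl = self._cluster(["o1", "o2"])
        with pytest.warns(UserWarning):
            _, skipped = classify_clusters(
                [cl], {"ref", "mate"}, {"ref", "mate", "o1", "o2"},
                reference="ref")
        assert skipped == 1


class TestRandomization:
    def test_no_shared_families_gives_zero_counts(self):
        a = make_genome("A", {"c1": ["f1", "f2", "f3"]})
        b = make_genome("B", {"c1": ["g1", "g2", "g3"]})
        orth = orthology_from_genomes(a, b)
        counts, median = shuffle_null([a, b], orth, {"A", "B"},
                                      reference="A", rounds=5, seed=0)
        assert counts == [0] * 5 and median == 0

    def test_toy_median_matches_exhaustive_permutation_expectation(self):
        """6 genes, 3 shared families: the exhaustive distribution over all
        relative orders fixes the median block count, which 200 shuffle
        rounds must reproduce."""
        from itertools import permutations
        tokens = ["f1", "f2", "f3", "x", "x", "x"]
        a = make_genome("A", {"c1": tokens})
        counts_exh = []
        for perm in permutations(tokens):
            b = make_genome("B", {"c1": list(perm)})
            orth = orthology_from_genomes(a, b)
            counts_exh.append(
                len(oracle_pairwise_blocks(a, b, orth)))
        expected_median = float(np.median(counts_exh))
        b = make_genome("B", {"c1": tokens})
        orth = orthology_from_genomes(a, b)
        counts, median = shuffle_null(
            [a, b], orth, {"A", "B"}, reference="A",
            query_class="novel_clade", rounds=200, seed=3)
        assert median == pytest.approx(expected_median)

    def test_planted_fixture_shuffle_median_far_below_observed(
            self, default_fixture):
        cfg, genomes, orth, truth = default_fixture
        eff_min = min(7, cfg.n_species_outgroup)
        clusters = build_clusters(genomes, orth, set(cfg.species_clade),
                                  reference=cfg.reference,
                                  ancient_min_species=eff_min)
        observed = sum(1 for c in clusters if c.label == "novel_clade")
        counts, median = shuffle_null(
            genomes, orth, set(cfg.species_clade), reference=cfg.reference,
            rounds=3, seed=5, ancient_min_species=eff_min)
        assert observed == cfg.n_novel_blocks
        assert median <= 0.05 * observed


class TestRandomBlocks:
    def test_size_distribution_preserved(self, small_fixture):
        cfg, genomes, orth, truth = small_fixture
        clusters = build_clusters(genomes, orth, set(cfg.species_clade),
                                  reference=cfg.reference,
                                  ancient_min_species=3)
        sizes = sorted(len(c.instance(cfg.reference).genes)
                       for c in clusters)
        sets = sample_random_blocks(genomes[0], clusters, iterations=5,
                                    seed=1)
        for it in sets:
            assert sorted(len(rb.genes) for rb in it) == sizes

    def test_single_possible_placement(self):
        from syntopo.synteny import ClusterInstance, SyntenyCluster
        g = make_genome("A", {"c1": [f"f{i}" for i in range(10)]})
        cl = SyntenyCluster("cl0", frozenset(f"f{i}" for i in range(10)),
                            {"A": [ClusterInstance(
                                "c1", tuple(gene.gene_id for gene in
                                            g.chromosomes["c1"]), 0, 100)]})
        sets = sample_random_blocks(g, [cl], iterations=3, seed=0)
        for it in sets:
            assert it[0].genes == tuple(
                gene.gene_id for gene in g.chromosomes["c1"])

    def test_block_too_large_raises(self):
        from syntopo.synteny import ClusterInstance, SyntenyCluster
        g = make_genome("A", {"c1": ["f1", "f2"]})
        cl = SyntenyCluster("cl0", frozenset(["f1", "f2", "f3"]),
                            {"A": [ClusterInstance(
                                "c1", ("a", "b", "c"), 0, 100)]})
        with pytest.raises(ValueError, match="chromosome"):
            sample_random_blocks(g, [cl], iterations=1, seed=0)

    def test_start_positions_uniform(self):
        """Empirical start distribution is uniform over eligible starts."""
        from syntopo.synteny import ClusterInstance, SyntenyCluster
        g = make_genome("A", {"c1": [f"f{i}" for i in range(13)]})
        cl = SyntenyCluster("cl0", frozenset(["f0", "f1", "f2", "f3"]),
                            {"A": [ClusterInstance(
                                "c1", ("f0", "f1", "f2", "f3"), 0, 100)]})
        sets = sample_random_blocks(g, [cl], iterations=10_000, seed=2)
        starts = [g.locate(it[0].genes[0])[1] for it in sets]
        n_eligible = 13 - 4 + 1
        freq = np.bincount(starts, minlength=n_eligible)
        assert chisquare(freq).pvalue > 0.01


class TestGeometry:
    def test_abutting_genes_have_zero_intergenic(self):
        from syntopo.genome import Gene, GenomeOrder
        from syntopo.synteny import ClusterInstance, SyntenyCluster
        g = GenomeOrder("A", {"c1": [Gene("a", 0, 100), Gene("b", 100, 200),
                                     Gene("c", 200, 300)]})
        cl = SyntenyCluster("cl0", frozenset("abc"),
                            {"A": [ClusterInstance("c1", ("a", "b", "c"),
                                                   0, 300)]})
        table, _ = measure_block_geometry([cl], [g])
        assert table.intergenic_bp.iloc[0] == 0

    def test_overlapping_genes_floor_at_zero(self):
        from syntopo.genome import Gene, GenomeOrder
        from syntopo.synteny import ClusterInstance, SyntenyCluster
        g = GenomeOrder("A", {"c1": [Gene("a", 0, 100), Gene("b", 200, 300),
                                     Gene("c", 250, 350)]})
        cl = SyntenyCluster("cl0", frozenset("abc"),
                            {"A": [ClusterInstance("c1", ("a", "b", "c"),
                                                   0, 350)]})
        table, _ = measure_block_geometry([cl], [g])
        assert table.intergenic_bp.iloc[0] == 100  # only the a-b gap

    def test_novel_blocks_have_smaller_intergenic_sums(self, default_fixture):
        cfg, genomes, orth, truth = default_fixture
        clusters = build_clusters(genomes, orth, set(cfg.species_clade),
                                  reference=cfg.reference,
                                  ancient_min_species=3)
        table, pvals = measure_block_geometry(clusters, genomes)
        ref = table[table.species == cfg.reference]
        novel = ref[ref.label == "novel_clade"].intergenic_bp
        ancient = ref[ref.label == "ancient"].intergenic_bp
        assert novel.median() < ancient.median()
        assert pvals["intergenic_bp_novel_vs_ancient"] < 0.05


class TestPlantedRecovery:
    def test_noise_free_recovery_is_exact(self, small_fixture):
        cfg, genomes, orth, truth = small_fixture
        clusters = build_clusters(genomes, orth, set(cfg.species_clade),
                                  reference=cfg.reference,
                                  ancient_min_species=3)
        score = score_detection(clusters, truth)
        assert score["precision"] == 1.0
        assert score["recall"] == 1.0
        assert score["class_errors"] == 0

    def test_novel_blocks_invisible_between_outgroups(self, small_fixture):
        cfg, genomes, orth, truth = small_fixture
        outs = [g for g in genomes if g.species in cfg.species_outgroup]
        novel_famsets = {frozenset(b.families)
                        for b in truth.blocks_of("novel")}
        for i, x in enumerate(outs):
            for y in outs[i + 1:]:
                for bl in detect_pairwise_blocks(x, y, orth):
                    assert bl.families not in novel_famsets
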