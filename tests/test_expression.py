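"""Co-expression, module clustering, dominance and tissue specificity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from syntopo.expression import (ModuleAssignment, cluster_expression_modules,
                                coexpression_coefficient, compare_coexpression,
                                dominance_and_relative, module_enrichment,
                                tissue_specificity_tau)
from syntopo.synthetic import SimulationConfig, simulate_expression

from .oracles import oracle_fisher_p, oracle_tau


def expr_frame(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestCoexpression:
    def test_identical_profiles_give_one(self):
        expr = expr_frame({"a": [1, 5, 9, 2], "b": [1, 5, 9, 2]})
        c, n, excl = coexpression_coefficient(["a", "b"], expr)
        assert c == pytest.approx(1.0) and n == 2 and excl == 0

    def test_opposite_z_profiles_give_minus_one(self):
        expr = expr_frame({"a": [1, 3, 5], "b": [5, 3, 1]})
        c, _, _ = coexpression_coefficient(["a", "b"], expr, log=False)
        assert c == pytest.approx(-1.0)

    def test_three_gene_mean_of_pairwise_correlations(self):
        """Mean of hand-computed pairwise r values."""
        rng = np.random.default_rng(0)
        mat = rng.random((3, 8)) * 50
        expr = pd.DataFrame(mat, index=["a", "b", "c"])
        logged = np.log2(mat + 1)
        r = np.corrcoef(logged)
        expected = (r[0, 1] + r[0, 2] + r[1, 2]) / 3
        c, _, _ = coexpression_coefficient(["a", "b", "c"], expr)
        assert c == pytest.approx(expected)

    def test_zero_variance_and_missing_genes_excluded(self):
        expr = expr_frame({"a": [1, 2, 3], "flat": [4, 4, 4]})
        c, n, excl = coexpression_coefficient(["a", "flat", "absent"], expr)
        assert c is None and n == 1 and excl == 2

    def test_invariant_to_tissue_permutation_and_scaling(self):
        rng = np.random.default_rng(1)
        mat = rng.random((4, 6)) * 100
        expr = pd.DataFrame(mat, index=list("abcd"))
        c1, _, _ = coexpression_coefficient(list("abcd"), expr, log=False)
        perm = rng.permutation(6)
        expr2 = expr.iloc[:, perm]
        c2, _, _ = coexpression_coefficient(list("abcd"), expr2, log=False)
        assert c1 == pytest.approx(c2)

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.random((30, 6)) * 10,
                            index=[f"g{i}" for i in range(30)])
        blocks = [[f"g{i}", f"g{i+1}"] for i in range(0, 30, 2)]
        dists, pvals = compare_coexpression(
            {"novel": blocks, "ancient": blocks},
            {"novel": blocks, "ancient": blocks}, expr)
        assert pvals["novel_vs_random_novel"] == pytest.approx(1.0)
        assert pvals["novel_vs_ancient"] == pytest.approx(1.0)

    def test_all_constant_expression_yields_empty_comparison(self):
        expr = expr_frame({"a": [1, 1, 1], "b": [2, 2, 2]})
        with pytest.warns(UserWarning):
            dists, pvals = compare_coexpression(
                {"novel": [["a", "b"]]}, {"novel": [["a", "b"]]}, expr)
        assert all(np.isnan(p) for p in pvals.values())


class TestLatentFactorModel:
    def test_full_correlation_no_noise(self):
        cfg = SimulationConfig(seed=3, within_block_corr=1.0, noise_cv=0.0,
                               gene_level_sd=0.0,
                               n_chromosomes=2, genes_per_chromosome=60,
                               n_ancestral_blocks=1, n_novel_blocks=1)
        from syntopo.synthetic import simulate_species_set
        genomes, orth, truth = simulate_species_set(cfg)
        bl = truth.planted_blocks[0]
        genes = list(bl.genes[cfg.reference])
        expr = simulate_expression(genes, truth, cfg)
        c, _, _ = coexpression_coefficient(genes, expr)
        assert c == pytest.approx(1.0)

    def test_zero_correlation_mean_near_zero(self):
        """Monte-Carlo: with rho=0 and no module template the mean
        within-block correlation vanishes over many blocks."""
        cfg = SimulationConfig(seed=4, within_block_corr=0.0, noise_cv=0.5,
                               n_tissues=10)
        rng = np.random.default_rng(4)
        coefs = []
        from syntopo.synthetic import PlantedBlock, TruthSet
        for b in range(200):
            genes = [f"b{b}_g{k}" for k in range(4)]
            truth = TruthSet(planted_blocks=[PlantedBlock(
                "novel", ("f0", "f1", "f2", "f3"),
                {cfg.reference: tuple(genes)}, module=1)])
            expr = simulate_expression(genes, truth, cfg, rng=rng,
                                       module_amplitude=0.0)
            c, _, _ = coexpression_coefficient(genes, expr)
            coefs.append(c)
        assert abs(np.mean(coefs)) < 0.05


class TestModules:
    def _module_fixture(self, noise_cv, seed=5, n_blocks=48, k=8):
        cfg = SimulationConfig(seed=seed, noise_cv=noise_cv, n_modules=k,
                               within_block_corr=0.3)
        from syntopo.synthetic import PlantedBlock, TruthSet
        truth = TruthSet()
        blocks = {}
        genes = []
        for b in range(n_blocks):
            gids = [f"b{b}_g{k2}" for k2 in range(4)]
            module = b % k + 1
            truth.planted_blocks.append(PlantedBlock(
                "ancestral", tuple(f"f{b}_{k2}" for k2 in range(4)),
                {cfg.reference: tuple(gids)}, module=module))
            for g in gids:
                truth.planted_modules[g] = module
            blocks[f"cl{b}"] = gids
            genes += gids
        expr = simulate_expression(genes, truth, cfg,
                                   rng=np.random.default_rng(seed))
        return cfg, truth, blocks, expr

    def test_k_one_puts_everything_in_one_module(self):
        _, _, blocks, expr = self._module_fixture(0.1)
        assignment, _ = cluster_expression_modules(blocks, expr, k=1)
        assert set(assignment.modules.values()) == {1}

    def test_noise_free_modules_recovered_exactly(self):
        cfg, truth, blocks, expr = self._module_fixture(0.0)
        assignment, _ = cluster_expression_modules(blocks, expr, k=8)
        true_labels = [int(cid[2:]) % 8 + 1 for cid in blocks]
        pred = [assignment.modules[cid] for cid in blocks]
        assert adjusted_rand_score(true_labels, pred) == 1.0

    def test_moderate_noise_keeps_high_ari(self):
        cfg, truth, blocks, expr = self._module_fixture(0.3)
        assignment, _ = cluster_expression_modules(blocks, expr, k=8)
        true_labels = [int(cid[2:]) % 8 + 1 for cid in blocks]
        pred = [assignment.modules[cid] for cid in blocks]
        assert adjusted_rand_score(true_labels, pred) >= 0.8

    def test_zscored_profiles_have_zero_mean_unit_sd(self):
        _, _, blocks, expr = self._module_fixture(0.2)
        _, means = cluster_expression_modules(blocks, expr, k=2)
        # module means of z-scored rows stay bounded; direct contract:
        from syntopo.expression import _log
        prof = np.array([_log(expr).loc[g].mean(axis=0) for g in
                         blocks.values()])
        z = (prof - prof.mean(1, keepdims=True)) / prof.std(1, keepdims=True)
        assert np.allclose(z.mean(1), 0, atol=1e-12)
        assert np.allclose(z.std(1), 1, atol=1e-12)

    def test_k_larger_than_blocks_rejected(self):
        _, _, blocks, expr = self._module_fixture(0.1, n_blocks=4)
        with pytest.raises(ValueError):
            cluster_expression_modules(blocks, expr, k=9)

    def test_deterministic_given_input_order(self):
        _, _, blocks, expr = self._module_fixture(0.2)
        a1, _ = cluster_expression_modules(blocks, expr, k=8)
        a2, _ = cluster_expression_modules(blocks, expr, k=8)
        assert a1.modules == a2.modules


class TestModuleEnrichment:
    def test_extreme_table_matches_exact_enumeration(self):
        assignment = ModuleAssignment(
            {f"n{i}": 1 for i in range(10)} | {f"a{i}": 2 for i in range(10)},
            k=2)
        classes = {f"n{i}": "novel" for i in range(10)}
        classes |= {f"a{i}": "ancient" for i in range(10)}
        table = module_enrichment(assignment, classes)
        row = table[table.module == 1].iloc[0]
        assert row.pvalue == pytest.approx(
            oracle_fisher_p([[10, 0], [0, 10]]), abs=1e-12)

    def test_balanced_table_p_one(self):
        assignment = ModuleAssignment(
            {f"g{i}": (1 if i < 10 else 2) for i in range(20)}, k=2)
        classes = {f"g{i}": ("novel" if i % 2 else "ancient")
                   for i in range(20)}
        table = module_enrichment(assignment, classes)
        assert table.pvalue.tolist() == pytest.approx([1.0, 1.0])

    def test_planted_bias_strongly_significant(self):
        rng = np.random.default_rng(8)
        modules = {}
        classes = {}
        for i in range(100):
            cls = "novel" if i < 50 else "ancient"
            p_in = 0.8 if cls == "novel" else 0.2
            modules[f"g{i}"] = 1 if rng.random() < p_in else 2
            classes[f"g{i}"] = cls
        table = module_enrichment(ModuleAssignment(modules, 2), classes)
        assert table[table.module == 1].pvalue.iloc[0] < 1e-5


class TestDominance:
    def test_single_gene_block_is_dominant(self):
        expr = expr_frame({"a": [10, 20]})
        res = dominance_and_relative({"b1": ["a"]}, expr)
        assert res.dominant_fraction == 1.0
        assert res.per_block_dominant_share["b1"] == 1.0

    def test_equal_totals_boundary_not_dominant(self):
        expr = expr_frame({"a": [10, 20], "b": [20, 10]})
        res = dominance_and_relative({"b1": ["a", "b"]}, expr)
        assert res.dominant_fraction == 0.0

    def test_hand_computed_share(self):
        expr = expr_frame({"a": [30, 30], "b": [20, 10], "c": [5, 5]})
        res = dominance_and_relative({"b1": ["a", "b", "c"]}, expr)
        assert res.per_block_dominant_share["b1"] == pytest.approx(0.6)

    def test_zero_total_block_excluded_from_denominator(self):
        expr = expr_frame({"a": [0, 0], "dom": [9, 1], "x": [1, 0]})
        res = dominance_and_relative(
            {"b0": ["a"], "b1": ["dom", "x"]}, expr)
        assert res.n_defined == 1
        assert res.dominant_fraction == 1.0

    def test_planted_dominance_fraction_exact(self):
        """80% of blocks built with a 0.7-share gene: fraction 0.8."""
        rows = {}
        blocks = {}
        for b in range(50):
            dominant = b < 40
            hi = 70.0 if dominant else 20.0  # 0.7 vs 1/3 share
            lo = 15.0 if dominant else 20.0
            rows[f"b{b}_hi"] = [hi, hi]
            rows[f"b{b}_lo1"] = [lo, lo]
            rows[f"b{b}_lo2"] = [lo, lo]
            blocks[f"b{b}"] = [f"b{b}_hi", f"b{b}_lo1", f"b{b}_lo2"]
        res = dominance_and_relative(blocks, expr_frame(rows))
        assert res.dominant_fraction == pytest.approx(0.8)


class TestTau:
    def test_single_tissue_expression_tau_one(self):
        expr = expr_frame({"a": [100, 0, 0, 0]})
        assert tissue_specificity_tau(expr)["a"] == pytest.approx(1.0)

    def test_uniform_expression_tau_zero(self):
        expr = expr_frame({"a": [7, 7, 7, 7]})
        assert tissue_specificity_tau(expr)["a"] == pytest.approx(0.0)

    def test_matches_direct_formula_oracle(self):
        profile = [8, 2, 2, 2]
        expr = expr_frame({"a": profile})
        assert tissue_specificity_tau(expr)["a"] == pytest.approx(
            oracle_tau(profile))

    def test_all_zero_gene_is_missing(self):
        expr = expr_frame({"a": [0, 0, 0]})
        assert np.isnan(tissue_specificity_tau(expr)["a"])
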