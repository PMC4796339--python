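"""Clustering, cut selection, Fisher enrichment (standard + LD-corrected),
cell-type signatures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from braincoex import (
    CoexpressionMatrix,
    ConfigError,
    build_celltype_signatures,
    celltype_enrichment,
    cluster_modules,
    coexpression_from_panel,
    fisher_enrichment,
    ld_corrected_fisher,
    module_enrichment_table,
    select_cut,
)
from braincoex.enrichment import ModulePartition
from braincoex.simulate import (
    LdReference,
    PlantedModule,
    SimulationConfig,
    simulate_expression,
)


def _block_matrix(sizes, within, between=0.0):
    n = sum(sizes)
    V = np.full((n, n), between)
    start = 0
    for s in sizes:
        V[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(V, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return CoexpressionMatrix(genes, V)


class TestClustering:
    def test_k1_single_module(self, toy_coexpr):
        part = cluster_modules(toy_coexpr, k=1)
        assert part.n_modules == 1
        assert set(part.labels) == {1}

    def test_noise_free_blocks_recovered_exactly(self):
        cm = _block_matrix([10, 15], within=0.9, between=0.0)
        part = cluster_modules(cm, k=2)
        truth = [0] * 10 + [1] * 15
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_five_planted_modules_recovered(self, default_cfg):
        cm = coexpression_from_panel(simulate_expression(default_cfg))
        part = cluster_modules(cm, k=5)
        planted = np.repeat(np.arange(5), 40)
        assert adjusted_rand_score(planted, part.labels.to_numpy()) >= 0.9

    def test_partition_covers_every_gene_once(self, toy_coexpr):
        part = cluster_modules(toy_coexpr, k=3)
        assert sorted(part.labels.index) == sorted(toy_coexpr.genes)
        sizes = [len(g) for g in part.modules().values()]
        assert sum(sizes) == len(toy_coexpr.genes)

    def test_k_larger_than_genes_rejected(self, toy_coexpr):
        with pytest.raises(ConfigError, match="exceeds"):
            cluster_modules(toy_coexpr, k=6)


class TestSelectCut:
    def test_single_configuration_returned_unchanged(self, toy_coexpr):
        linkage, k, table = select_cut(toy_coexpr, {"g1"}, ["complete"], [2])
        assert (linkage, k) == ("complete", 2)
        assert len(table) == 1

    def test_planted_enriched_module_selects_its_k(self):
        cm = _block_matrix([10, 10, 10, 10], within=0.9)
        candidates = {f"g{i}" for i in range(10)}  # exactly the first block
        linkage, k, table = select_cut(cm, candidates, ["complete"], [2, 4, 8])
        assert k == 4
        assert set(table["k"]) == {2, 4, 8}

    def test_empty_candidate_set_rejected(self, toy_coexpr):
        with pytest.raises(ConfigError, match="no candidates"):
            select_cut(toy_coexpr, set(), ["complete"], [2])


def brute_force_tail(a, module, special, universe):
    """Hypergeometric upper tail by explicit summation."""
    total = 0.0
    for x in range(a, min(module, special) + 1):
        total += (
            comb(special, x, exact=True)
            * comb(universe - special, module - x, exact=True)
        )
    return total / comb(universe, module, exact=True)


class TestFisherEnrichment:
    def test_zero_overlap_gives_p_one(self):
        res = fisher_enrichment({"a"}, {"b"}, {"a", "b", "c", "d"})
        assert res.p == pytest.approx(1.0)
        assert res.a == 0

    def test_counts_sum_to_universe(self):
        universe = {f"g{i}" for i in range(30)}
        res = fisher_enrichment(
            {f"g{i}" for i in range(8)}, {f"g{i}" for i in range(4, 14)}, universe
        )
        assert res.a + res.b + res.c + res.d == 30
        assert res.a + res.b == 8
        assert res.a + res.c == 10

    def test_matches_brute_force_on_all_small_tables(self):
        """Exhaustive check against the hypergeometric tail sum, universe <= 50."""
        rng = np.random.default_rng(12)
        for universe_n in (10, 25, 50):
            universe = [f"g{i}" for i in range(universe_n)]
            for _ in range(40):
                m = rng.integers(1, universe_n + 1)
                s = rng.integers(1, universe_n + 1)
                module = set(rng.choice(universe, m, replace=False))
                special = set(rng.choice(universe, s, replace=False))
                res = fisher_enrichment(module, special, universe)
                expected = brute_force_tail(res.a, m, s, universe_n)
                assert res.p == pytest.approx(expected, rel=1e-9)


class TestLdCorrectedFisher:
    def _setup(self, n=20, n_blocks=None, r=0.0):
        genes = [f"g{i}" for i in range(n)]
        snps = [f"rs{i}" for i in range(n)]
        top = dict(zip(genes, snps))
        if n_blocks is None:
            blocks = list(range(n))  # everything independent
        else:
            blocks = [i % n_blocks for i in range(n)]
        ld = LdReference(snps, blocks, {b: r for b in set(blocks)})
        return genes, top, ld

    def test_identity_ld_reduces_to_standard_fisher(self):
        genes, top, ld = self._setup(20)
        module = set(genes[:8])
        cand = set(genes[4:10])
        res = ld_corrected_fisher(module, cand, genes, top, ld)
        assert (res.eff_a, res.eff_b, res.eff_c, res.eff_d) == (
            res.a, res.b, res.c, res.d,
        )
        assert res.ld_p == pytest.approx(res.p)

    def test_shared_top_snp_counts_as_one_effective_gene(self):
        genes, top, ld = self._setup(10)
        top["g1"] = top["g0"]  # two module candidates tag the same SNP
        module = {"g0", "g1", "g2"}
        cand = {"g0", "g1"}
        res = ld_corrected_fisher(module, cand, genes, top, ld)
        assert res.a == 2 and res.eff_a == 1

    def test_effective_counts_match_per_cell_effective_number(self):
        """Corrected counts equal a direct effective-number computation per cell."""
        from braincoex.gene_assoc import effective_number

        rng = np.random.default_rng(7)
        genes, top, ld = self._setup(40, n_blocks=8, r=0.7)
        module = set(rng.choice(genes, 15, replace=False))
        cand = set(rng.choice(genes, 12, replace=False))
        res = ld_corrected_fisher(module, cand, genes, top, ld)
        cells = {
            "eff_a": sorted(module & cand),
            "eff_b": sorted(module - cand),
            "eff_c": sorted(cand - module),
            "eff_d": sorted(set(genes) - module - cand),
        }
        for key, members in cells.items():
            R = ld.correlation([top[g] for g in members])
            assert getattr(res, key) == max(1, round(effective_number(R)))


class TestCelltypeSignatures:
    def test_tenfold_rule_strict_boundary(self):
        rpkm = pd.DataFrame(
            [[100, 1, 1, 1, 1], [10, 1, 1, 1, 1], [3, 3, 3, 3, 3]],
            index=["clear", "boundary", "flat"],
            columns=list("ABCDE"),
        )
        sigs = build_celltype_signatures(rpkm, fold=10.0)
        assert "clear" in sigs["A"]
        assert "boundary" not in sigs["A"]  # 10 == 10x1 fails the strict rule
        assert all("flat" not in s for s in sigs.values())

    def test_signatures_pairwise_disjoint(self):
        rng = np.random.default_rng(6)
        rpkm = pd.DataFrame(
            rng.lognormal(1, 2, size=(500, 5)),
            index=[f"g{i}" for i in range(500)],
            columns=list("ABCDE"),
        )
        sigs = build_celltype_signatures(rpkm)
        for t1, t2 in itertools.combinations(sigs, 2):
            assert not sigs[t1] & sigs[t2]

    def test_empty_signature_flagged_with_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = celltype_enrichment(
            {"m1": {"g0", "g1"}}, {"neuron": set()}, universe
        )
        assert out.loc[0, "p"] == 1.0
        assert bool(out.loc[0, "empty_signature"])


class TestModuleEnrichmentTable:
    def test_null_candidates_rarely_significant(self):
        """Random candidate labels: module false-positive rate <= nominal."""
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(400)]
        labels = pd.Series(rng.integers(1, 9, 400), index=genes)
        # make labels contiguous 1..8
        labels = pd.Series(
            pd.factorize(labels)[0] + 1, index=genes
        )
        part = ModulePartition(labels, "complete", 8)
        hits = trials = 0
        for _ in range(60):
            cand = set(rng.choice(genes, 20, replace=False))
            table = module_enrichment_table(part, cand)
            hits += int((table["p"] < 0.05).sum())
            trials += len(table)
        rate = hits / trials
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)

    def test_bh_column_present_and_monotone(self, toy_coexpr):
        part = cluster_modules(toy_coexpr, k=2)
        table = module_enrichment_table(part, {"g1", "g2"})
        assert (table["bh_p"] >= table["p"] - 1e-12).all()
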