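"""SNP-to-gene windows, effective numbers of tests, and the gene statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from braincoex import (
    DataError,
    assign_snps_to_genes,
    classify_genes,
    effective_number,
    gates_p,
    gene_association_table,
)
from braincoex.gene_assoc import pvalue_correlation
from braincoex.simulate import LdReference, SimulationConfig, simulate_gwas


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p"])


GENE = pd.DataFrame(
    {"gene_id": ["G1"], "chrom": ["1"], "start": [100_000], "end": [120_000]}
)


class TestAssignment:
    @pytest.mark.parametrize(
        "pos,included",
        [
            (100_000 - 15_000, True),   # exactly at the closed lower boundary
            (100_000 - 15_001, False),  # one base outside
            (120_000 + 15_000, True),
            (120_000 + 15_001, False),
        ],
    )
    def test_window_boundaries_closed(self, pos, included):
        snps = _snps([("rs1", "1", pos, 0.5)])
        idx = assign_snps_to_genes(snps, GENE)["G1"]
        assert (len(idx) == 1) is included

    def test_snp_in_two_overlapping_windows_assigned_to_both(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["G1", "G2"],
                "chrom": ["1", "1"],
                "start": [100_000, 118_000],
                "end": [120_000, 140_000],
            }
        )
        snps = _snps([("rs1", "1", 119_000, 0.5)])
        out = assign_snps_to_genes(snps, genes)
        assert out["G1"] == out["G2"] == [0]

    def test_wrong_chromosome_excluded(self):
        snps = _snps([("rs1", "2", 110_000, 0.5)])
        assert assign_snps_to_genes(snps, GENE)["G1"] == []


class TestEffectiveNumber:
    def test_identity_gives_m(self):
        assert effective_number(np.eye(5)) == pytest.approx(5.0)

    def test_perfect_ld_gives_one(self):
        assert effective_number(np.ones((3, 3))) == pytest.approx(1.0)

    def test_half_correlated_pair(self):
        # eigenvalues {1.5, 0.5} -> Me = 2 - 0.5 = 1.5
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert effective_number(R) == pytest.approx(1.5)

    def test_invariant_to_sign_flips(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((6, 20))
        R = np.corrcoef(A)
        D = np.diag([1, -1, 1, -1, -1, 1])
        assert effective_number(D @ R @ D) == pytest.approx(effective_number(R))

    def test_non_symmetric_rejected(self):
        with pytest.raises(DataError, match="symmetric"):
            effective_number(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestPvalueCorrelation:
    def test_endpoints(self):
        assert pvalue_correlation(np.array(0.0)) == pytest.approx(0.0, abs=1e-9)
        assert pvalue_correlation(np.array(1.0)) == pytest.approx(1.0, abs=1e-3)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(8)
        for r in (0.3, 0.7, 0.9):
            z1 = rng.standard_normal(400_000)
            z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(400_000)
            from scipy import stats

            p1 = 2 * stats.norm.sf(np.abs(z1))
            p2 = 2 * stats.norm.sf(np.abs(z2))
            emp = np.corrcoef(p1, p2)[0, 1]
            assert pvalue_correlation(np.array(r)) == pytest.approx(emp, abs=0.01)

    def test_abs_transform(self):
        assert pvalue_correlation(np.array(-0.4), "abs") == pytest.approx(0.4)


class TestGatesP:
    def test_single_snp_returns_its_p(self):
        assert gates_p([0.01], np.eye(1)) == pytest.approx(0.01)

    def test_two_independent_snps_reduce_to_simes(self):
        # min(2*0.01/1, 2*0.04/2) = 0.02
        assert gates_p([0.01, 0.04], np.eye(2)) == pytest.approx(0.02)

    def test_perfectly_correlated_pair_counts_once(self):
        R = np.ones((2, 2))
        assert gates_p([0.01, 0.01], R) == pytest.approx(0.01)

    @given(
        ps=st.lists(st.floats(1e-6, 1.0, width=64), min_size=1, max_size=20),
    )
    def test_identity_ld_equals_simes_closed_form(self, ps):
        p = np.sort(np.asarray(ps))
        M = len(p)
        simes = np.min(M * p / np.arange(1, M + 1))
        assert gates_p(p, np.eye(M)) == pytest.approx(min(simes, 1.0), rel=1e-9)

    @given(
        ps=st.lists(st.floats(1e-6, 1.0, width=64), min_size=2, max_size=8),
        r=st.floats(0.0, 0.95),
    )
    def test_bounds_min_p_and_bonferroni(self, ps, r):
        p = np.sort(np.asarray(ps))
        M = len(p)
        R = np.full((M, M), r)
        np.fill_diagonal(R, 1.0)
        gp = gates_p(p, R)
        assert gp >= p[0] - 1e-12
        assert gp <= min(1.0, M * p[0]) + 1e-9


class TestClassification:
    def test_candidate_vs_high_confidence_thresholds(self):
        table = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(10)],
                "gene_p": [0.04, 0.004] + [0.5] * 8,
            }
        )
        out = classify_genes(table, alpha=0.05)
        assert out.loc[0, "class"] == "candidate"      # 0.04*10 = 0.4 not < 0.05
        assert out.loc[1, "class"] == "high_confidence"  # 0.004*10 = 0.04 < 0.05

    def test_high_confidence_subset_of_candidates(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            {"gene_id": range(100), "gene_p": rng.uniform(1e-5, 1, 100)}
        )
        out = classify_genes(table)
        hc = set(out.loc[out["class"] == "high_confidence", "gene_id"])
        cand = set(out.loc[out["class"] != "none", "gene_id"])
        assert hc <= cand

    def test_zero_snp_genes_excluded_from_bonferroni(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "gene_p": [0.02, np.nan, np.nan]}
        )
        out = classify_genes(table, alpha=0.05)
        # N = 1 defined gene, so 0.02 * 1 < 0.05 -> high confidence
        assert out.loc[0, "class"] == "high_confidence"
        assert (out.loc[1:, "class"] == "none").all()


class TestAssociationTable:
    def test_planted_gene_ranks_first_often(self, assoc_setup):
        """One noncentrality-6 gene among 20 nulls recovers rank 1 in >=90%."""
        gm, blocks, n_snps = assoc_setup
        wins = 0
        n_rep = 120
        for rep in range(n_rep):
            cfg = SimulationConfig(
                seed=5000 + rep, n_genes=21, gene_models=gm, n_snps=n_snps,
                ld_blocks=blocks, associated_genes={"G00000": 6.0},
                region_labels=(("cortex", 1.0),),
            )
            snps, ld = simulate_gwas(cfg)
            assoc = gene_association_table(snps, gm, ld)
            wins += assoc.sort_values("gene_p").iloc[0]["gene_id"] == "G00000"
        assert wins / n_rep >= 0.9

    def test_me_between_one_and_n_snps_and_gene_p_above_min_p(self, assoc_setup):
        gm, blocks, n_snps = assoc_setup
        cfg = SimulationConfig(
            seed=1, n_genes=21, gene_models=gm, n_snps=n_snps, ld_blocks=blocks,
            region_labels=(("cortex", 1.0),),
        )
        snps, ld = simulate_gwas(cfg)
        assoc = gene_association_table(snps, gm, ld)
        defined = assoc[assoc["gene_p"].notna()]
        assert ((defined["me_total"] >= 1) & (defined["me_total"] <= defined["n_snps"])).all()
        assignment = assign_snps_to_genes(snps, gm)
        for row in defined.itertuples():
            min_p = snps.loc[assignment[row.gene_id], "p"].min()
            assert row.gene_p >= min_p - 1e-12

    def test_top_snp_deterministic_under_ties(self):
        snps = _snps(
            [("rsA", "1", 110_000, 0.01), ("rsB", "1", 105_000, 0.01)]
        )
        ld = LdReference(["rsA", "rsB"], [0, 1], {0: 0.0, 1: 0.0})
        out = gene_association_table(snps, GENE, ld)
        assert out.loc[0, "top_snp"] == "rsB"  # tie broken by position
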