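"""Module detection and gene-set enrichment.

Modules come from agglomerative hierarchical clustering of the co-expression
matrix with distance = 1 - correlation.  Candidate-gene enrichment per module
uses a one-sided Fisher exact test; a second, LD-corrected variant replaces
each cell of the 2x2 table with the effective number of independent genes,
computed from the LD between the member genes' top SNPs, to guard against
counting several genes that merely tag the same association signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .coexpression import CoexpressionMatrix
from .errors import ConfigError, DataError
from .gene_assoc import effective_number
from .simulate import LdReference

__all__ = [
    "ModulePartition",
    "EnrichmentResult",
    "cluster_modules",
    "select_cut",
    "fisher_enrichment",
    "ld_corrected_fisher",
    "module_enrichment_table",
    "build_celltype_signatures",
    "celltype_enrichment",
    "export_module_gene_lists",
]


@dataclass
class ModulePartition:
    """A hard partition of the clustered genes into labelled modules."""

    labels: pd.Series  # gene id -> module label (1..k, contiguous)
    linkage: str
    k: int

    def __post_init__(self) -> None:
        found = sorted(set(self.labels))
        if found != list(range(1, len(found) + 1)):
            raise DataError(f"module labels not contiguous from 1: {found[:10]}")

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    def module_genes(self, module: int) -> set[str]:
        return set(self.labels.index[self.labels == module])

    def modules(self) -> dict[int, set[str]]:
        return {m: self.module_genes(m) for m in range(1, self.n_modules + 1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.labels.index, "module": self.labels.to_numpy()})


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment test, optionally with LD-effective counts."""

    module_id: str
    a: int  # in set, special
    b: int  # in set, not special
    c: int  # out of set, special
    d: int  # out of set, not special
    odds_ratio: float
    p: float
    eff_a: int | None = None
    eff_b: int | None = None
    eff_c: int | None = None
    eff_d: int | None = None
    ld_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "p": self.p,
            "eff_a": self.eff_a,
            "eff_b": self.eff_b,
            "eff_c": self.eff_c,
            "eff_d": self.eff_d,
            "ld_p": self.ld_p,
        }


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_modules(
    coexpr: CoexpressionMatrix,
    linkage: str = "complete",
    k: int = 18,
) -> ModulePartition:
    """Cut an agglomerative tree on distance 1 - correlation into k modules.

    Labels are relabelled 1..k in order of first appearance along the gene
    list, so the partition is deterministic given the input matrix.
    """
    n = len(coexpr.genes)
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > n:
        raise ConfigError(f"k={k} exceeds the {n} genes available")
    D = 1.0 - coexpr.values
    np.fill_diagonal(D, 0.0)
    condensed = squareform(np.clip(D, 0.0, None), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return ModulePartition(pd.Series(labels, index=coexpr.genes), linkage, k)


def select_cut(
    coexpr: CoexpressionMatrix,
    candidate_genes: Iterable[str],
    linkages: Sequence[str] = ("complete",),
    k_grid: Sequence[int] = (18,),
) -> tuple[str, int, pd.DataFrame]:
    """Choose the (linkage, k) whose best module is most candidate-enriched.

    Score per configuration = the minimum module Fisher P; the returned
    configuration minimises the score, ties broken toward smaller k then
    lexicographic linkage.  The full score table is returned alongside.
    """
    candidates = set(candidate_genes) & set(coexpr.genes)
    if not candidates:
        raise ConfigError("no candidates to score")
    if not linkages or not k_grid:
        raise ConfigError("linkage and k grids must be non-empty")
    universe = set(coexpr.genes)
    rows = []
    for linkage in sorted(linkages):
        for k in sorted(k_grid):
            part = cluster_modules(coexpr, linkage, k)
            score = min(
                fisher_enrichment(genes, candidates, universe).p
                for genes in part.modules().values()
            )
            rows.append((linkage, k, score))
    table = pd.DataFrame(rows, columns=["linkage", "k", "min_module_p"])
    best = table.sort_values(["min_module_p", "k", "linkage"], kind="stable").iloc[0]
    return str(best["linkage"]), int(best["k"]), table


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def _fisher_from_counts(a: int, b: int, c: int, d: int, alternative: str) -> tuple[float, float]:
    oddsratio, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(oddsratio), float(p)


def fisher_enrichment(
    module_genes: Iterable[str],
    special_genes: Iterable[str],
    universe: Iterable[str],
    module_id: str = "",
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher exact test for over-representation of a gene set.

    The 2x2 table counts (in-module special, in-module other, out-module
    special, out-module other) within ``universe``; P is the hypergeometric
    upper tail P(X >= a).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    module = set(module_genes) & universe
    special = set(special_genes) & universe
    a = len(module & special)
    b = len(module) - a
    c = len(special) - a
    d = len(universe) - a - b - c
    oddsratio, p = _fisher_from_counts(a, b, c, d, alternative)
    return EnrichmentResult(module_id, a, b, c, d, oddsratio, p)


def _effective_count(
    genes: Sequence[str],
    top_snps: Mapping[str, str],
    ld: LdReference,
    snp_chrom: Mapping[str, str] | None = None,
) -> int:
    """Effective number of independent genes in a cell of the 2x2 table.

    The genes' top SNPs are grouped by chromosome (cross-chromosome LD is
    zero) and the effective-number rule applied per group, summing the
    results; rounded to the nearest integer, floored at 1 for non-empty
    cells.
    """
    if not genes:
        return 0
    missing = [g for g in genes if g not in top_snps or top_snps[g] is None]
    if missing:
        raise DataError(f"genes without a top SNP: {sorted(missing)[:5]}")
    snps = [top_snps[g] for g in sorted(genes)]
    if snp_chrom is not None:
        chrom_groups: dict[str, list[str]] = {}
        for s in snps:
            chrom_groups.setdefault(str(snp_chrom.get(s, "?")), []).append(s)
        groups = [g for cg in chrom_groups.values() for g in ld.partition_independent(cg)]
    else:
        groups = ld.partition_independent(snps)
    me = sum(effective_number(ld.correlation(g)) for g in groups)
    return max(1, round(me))


def ld_corrected_fisher(
    module_genes: Iterable[str],
    candidate_genes: Iterable[str],
    universe: Iterable[str],
    top_snps: Mapping[str, str],
    ld: LdReference,
    module_id: str = "",
    snp_chrom: Mapping[str, str] | None = None,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fisher test on LD-effective gene counts.

    Each cell count of the standard table is replaced by the effective
    number of independent genes among that cell's members, so genes whose
    top SNPs are in LD no longer count as independent evidence.  When all
    top SNPs are mutually independent this reduces exactly to the standard
    test.
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    module = set(module_genes) & universe
    special = set(candidate_genes) & universe
    cells = {
        "a": module & special,
        "b": module - special,
        "c": special - module,
        "d": universe - module - special,
    }
    raw = fisher_enrichment(module, special, universe, module_id, alternative)
    eff = {
        key: _effective_count(sorted(genes), top_snps, ld, snp_chrom)
        for key, genes in cells.items()
    }
    _, ld_p = _fisher_from_counts(eff["a"], eff["b"], eff["c"], eff["d"], alternative)
    raw.eff_a, raw.eff_b, raw.eff_c, raw.eff_d = eff["a"], eff["b"], eff["c"], eff["d"]
    raw.ld_p = ld_p
    return raw


def module_enrichment_table(
    partition: ModulePartition,
    candidate_genes: Iterable[str],
    universe: Iterable[str] | None = None,
    top_snps: Mapping[str, str] | None = None,
    ld: LdReference | None = None,
    snp_chrom: Mapping[str, str] | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Standard (and, if LD is given, LD-corrected) enrichment per module.

    A Benjamini-Hochberg column over the per-module P-values is appended
    for information only; selection elsewhere uses nominal P.
    """
    universe = set(universe) if universe is not None else set(partition.labels.index)
    results = []
    for module, genes in partition.modules().items():
        if ld is not None and top_snps is not None:
            res = ld_corrected_fisher(
                genes, candidate_genes, universe, top_snps, ld,
                module_id=str(module), snp_chrom=snp_chrom, alternative=alternative,
            )
        else:
            res = fisher_enrichment(
                genes, candidate_genes, universe, module_id=str(module),
                alternative=alternative,
            )
        results.append(res.as_dict())
    table = pd.DataFrame(results)
    table["bh_p"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# Cell-type signatures
# ---------------------------------------------------------------------------

def build_celltype_signatures(
    rpkm: pd.DataFrame,
    fold: float = 10.0,
) -> dict[str, set[str]]:
    """Genes specific to one cell type under the strict tenfold rule.

    Gene g joins type t's signature iff RPKM(g, t) > fold * mean of the
    other types' RPKM.  The strict inequality with fold > 1 makes the
    signatures pairwise disjoint.
    """
    if rpkm.shape[1] < 2:
        raise DataError("need >= 2 cell types")
    if (rpkm.to_numpy() < 0).any():
        raise DataError("RPKM values must be >= 0")
    if fold <= 1:
        raise ConfigError("fold threshold must exceed 1 for disjoint signatures")
    vals = rpkm.to_numpy(dtype=float)
    k = vals.shape[1]
    totals = vals.sum(axis=1, keepdims=True)
    other_mean = (totals - vals) / (k - 1)
    passes = vals > fold * other_mean
    signatures: dict[str, set[str]] = {t: set() for t in rpkm.columns}
    for j, t in enumerate(rpkm.columns):
        signatures[t] = set(rpkm.index[passes[:, j]])
    return signatures


def celltype_enrichment(
    gene_sets: Mapping[str, Iterable[str]],
    signatures: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher enrichment of every gene set against every cell-type signature.

    Empty signatures yield P = 1 rows flagged ``empty_signature``.
    """
    universe = set(universe)
    rows = []
    for set_id in gene_sets:
        for cell_type, sig in signatures.items():
            sig = set(sig)
            if not sig & universe:
                rows.append(
                    {
                        "module_id": str(set_id),
                        "cell_type": cell_type,
                        "a": 0, "b": len(set(gene_sets[set_id]) & universe),
                        "c": 0, "d": len(universe) - len(set(gene_sets[set_id]) & universe),
                        "odds_ratio": np.nan, "p": 1.0, "empty_signature": True,
                    }
                )
                continue
            res = fisher_enrichment(
                gene_sets[set_id], sig, universe, module_id=str(set_id),
                alternative=alternative,
            )
            row = res.as_dict()
            row["cell_type"] = cell_type
            row["empty_signature"] = False
            rows.append({k: row[k] for k in (
                "module_id", "cell_type", "a", "b", "c", "d", "odds_ratio", "p",
                "empty_signature",
            )})
    return pd.DataFrame(rows)


def export_module_gene_lists(
    partition: ModulePartition,
    outdir: str | Path,
    gene_p: Mapping[str, float] | None = None,
) -> list[Path]:
    """Write one ranked gene list per module (for external annotation tools).

    Genes are ordered by gene-based P when provided (missing P sorts last),
    else lexicographically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for module, genes in partition.modules().items():
        if gene_p:
            ordered = sorted(genes, key=lambda g: (gene_p.get(g) is None,
                                                   gene_p.get(g, 0.0), g))
        else:
            ordered = sorted(genes)
        path = outdir / f"module_{module:02d}_genes.txt"
        path.write_text("\n".join(ordered) + "\n")
        paths.append(path)
    return paths
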