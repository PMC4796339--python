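"""Synthetic data with the statistical structure the analysis assumes.

Three generators driven by one :class:`SimulationConfig`:

* ``simulate_expression`` — multi-donor genes x samples panels in which each
  planted module shares a per-region mean profile and a per-sample latent
  factor, so module genes are spatially co-expressed across donors;
* ``simulate_gwas`` — SNP z-scores drawn block-wise from exchangeable
  multivariate normals (a simple stand-in for LD), with association injected
  at one causal SNP per associated gene and propagated to block partners;
* ``simulate_celltype_rpkm`` — a genes x cell-types RPKM table in which
  designated genes strictly exceed the tenfold specificity rule for exactly
  one cell type.

All three are deterministic functions of ``config.seed``; independent
substreams are spawned per generator so adding donors does not perturb the
GWAS draw.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .expression import DonorExpression

__all__ = [
    "PlantedModule",
    "LdBlock",
    "CellTypeConfig",
    "SimulationConfig",
    "LdReference",
    "make_gene_models",
    "default_config",
    "simulate_expression",
    "simulate_gwas",
    "simulate_celltype_rpkm",
]


@dataclass(frozen=True)
class PlantedModule:
    """A co-expression module planted into the expression panel.

    ``region_means`` maps region label -> mean activity of the module there;
    ``strength`` in [0, 1] scales the shared per-sample latent factor.
    """

    genes: tuple[int, ...]
    region_means: Mapping[str, float]
    strength: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigError(f"module strength must be in [0,1], got {self.strength}")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("planted module lists a gene index twice")


@dataclass(frozen=True)
class LdBlock:
    """A run of consecutive SNPs sharing one exchangeable correlation r."""

    size: int
    r: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigError("LD block size must be >= 1")
        if not -1.0 < self.r < 1.0:
            raise ConfigError(f"|r| must be < 1 within a block, got {self.r}")
        # exchangeable correlation is positive definite only above -1/(m-1)
        if self.size > 1 and self.r <= -1.0 / (self.size - 1):
            raise ConfigError(
                f"exchangeable r={self.r} not positive definite for block size {self.size}"
            )


@dataclass(frozen=True)
class CellTypeConfig:
    """Log-normal RPKM parameters plus per-gene specificity assignments.

    ``specific`` maps gene id -> cell type that gene is specific to.
    """

    cell_types: tuple[str, ...] = (
        "neuron",
        "astrocyte",
        "oligodendrocyte",
        "microglia",
        "endothelial",
    )
    meanlog: float = 1.0
    sdlog: float = 1.0
    specific: Mapping[str, str] = field(default_factory=dict)
    fold: float = 10.0

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ConfigError("need >= 2 cell types")
        bad = set(self.specific.values()) - set(self.cell_types)
        if bad:
            raise ConfigError(f"specificity assigned to unknown cell types: {sorted(bad)}")


@dataclass
class SimulationConfig:
    """Everything the three generators need; validated on construction.

    Defaults are a desk-scale panel: 3 donors x ~300 samples over 4 regions,
    200 genes in 5 planted modules of strength 0.85, 2,000 SNPs in mixed LD
    blocks, and a 5-cell-type RPKM table.
    """

    seed: int = 0
    n_donors: int = 3
    n_samples_per_donor: int | Sequence[int] = 300
    region_labels: Sequence[tuple[str, float]] = (
        ("cortex", 0.4),
        ("cerebellum", 0.2),
        ("subcortex", 0.25),
        ("brainstem", 0.15),
    )
    n_genes: int = 200
    planted_modules: Sequence[PlantedModule] = ()
    noise_sd: float = 0.5
    donor_offset_sd: float = 0.3
    n_snps: int = 2000
    ld_blocks: Sequence[LdBlock] = ()
    gene_models: pd.DataFrame | None = None
    associated_genes: Mapping[str, float] = field(default_factory=dict)
    celltype_config: CellTypeConfig = field(default_factory=CellTypeConfig)

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_genes", "n_snps"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd < 0 or self.donor_offset_sd < 0:
            raise ConfigError("noise/offset standard deviations must be >= 0")
        seen: set[int] = set()
        for mod in self.planted_modules:
            overlap = seen & set(mod.genes)
            if overlap:
                raise ConfigError(f"planted modules overlap at gene indices {sorted(overlap)}")
            seen |= set(mod.genes)
            if max(mod.genes, default=-1) >= self.n_genes:
                raise ConfigError("planted module gene index out of range")
            regions = {r for r, _ in self.region_labels}
            missing = regions - set(mod.region_means)
            if missing:
                raise ConfigError(f"module region_means missing regions {sorted(missing)}")
        if self.ld_blocks and sum(b.size for b in self.ld_blocks) != self.n_snps:
            raise ConfigError("ld_blocks must tile the SNP list exactly")
        if self.gene_models is not None:
            gm = self.gene_models
            required = {"gene_id", "chrom", "start", "end"}
            if not required <= set(gm.columns):
                raise ConfigError(f"gene_models needs columns {sorted(required)}")
            known = set(gm["gene_id"])
            bad = set(self.associated_genes) - known
            if bad:
                raise ConfigError(f"associated genes absent from gene_models: {sorted(bad)}")
        elif self.associated_genes:
            raise ConfigError("associated_genes given without gene_models")

    def donor_sample_counts(self) -> list[int]:
        n = self.n_samples_per_donor
        if isinstance(n, int):
            return [n] * self.n_donors
        counts = list(n)
        if len(counts) != self.n_donors:
            raise ConfigError("n_samples_per_donor list length != n_donors")
        return counts

    def gene_ids(self) -> list[str]:
        if self.gene_models is not None:
            return list(self.gene_models["gene_id"])
        return [f"G{i:05d}" for i in range(self.n_genes)]


def make_gene_models(
    n_genes: int,
    gene_length: int = 20_000,
    spacing: int = 80_000,
    n_chromosomes: int = 2,
    prefix: str = "G",
) -> pd.DataFrame:
    """Evenly spaced gene models (1-based inclusive coordinates).

    With the default 15-kb flank and 80-kb spacing, adjacent windows do not
    overlap, so every SNP belongs to at most one gene.
    """
    per_chrom = int(np.ceil(n_genes / n_chromosomes))
    rows = []
    for i in range(n_genes):
        chrom = str(i // per_chrom + 1)
        j = i % per_chrom
        start = 1 + j * spacing
        rows.append((f"{prefix}{i:05d}", chrom, start, start + gene_length - 1))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def default_config(seed: int = 0) -> SimulationConfig:
    """The standard synthetic study: 5 planted modules, mixed LD, 10 associated genes."""
    n_genes = 200
    regions = (("cortex", 0.4), ("cerebellum", 0.2), ("subcortex", 0.25), ("brainstem", 0.15))
    region_names = [r for r, _ in regions]
    # one-high-rest-low activity patterns, rotating the high region per module
    modules = []
    for m in range(5):
        genes = tuple(range(m * 40, (m + 1) * 40))
        means = {r: 2.0 if i == m % len(region_names) else 0.0 for i, r in enumerate(region_names)}
        if m == 4:  # last module: graded pattern so not all modules are one-hot
            means = {r: 0.5 * i for i, r in enumerate(region_names)}
        modules.append(PlantedModule(genes, means, 0.85))
    gm = make_gene_models(n_genes)
    blocks: list[LdBlock] = []
    sizes = [1, 2, 5, 10]
    rs = [0.0, 0.3, 0.6, 0.8]
    total, i = 0, 0
    n_snps = 2000
    while total < n_snps:
        size = min(sizes[i % 4], n_snps - total)
        blocks.append(LdBlock(size, rs[i % 4] if size > 1 else 0.0))
        total += size
        i += 1
    associated = {f"G{g:05d}": 5.0 for g in range(0, 40, 4)}  # 10 genes in module 1
    specific = {}
    cts = CellTypeConfig().cell_types
    for i in range(0, n_genes, 7):  # ~29 specific genes, round-robin cell types
        specific[f"G{i:05d}"] = cts[(i // 7) % len(cts)]
    return SimulationConfig(
        seed=seed,
        planted_modules=tuple(modules),
        region_labels=regions,
        gene_models=gm,
        n_snps=n_snps,
        ld_blocks=tuple(blocks),
        associated_genes=associated,
        celltype_config=CellTypeConfig(specific=specific),
    )


def _spawn(seed: int, stream: str) -> np.random.Generator:
    """Independent, named substream derived from the master seed."""
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig) -> list[DonorExpression]:
    """Generate one genes x samples matrix per donor.

    A gene in planted module *m* gets ``region_mean + strength * f_s +
    noise_sd * eps`` where ``f_s`` is a per-sample standard-normal latent
    factor shared by the module's genes within a donor; background genes are
    pure noise.  An additive per-(donor, gene) offset (sd
    ``donor_offset_sd``) models between-donor level differences; it is
    constant across samples, so within-donor correlations are unaffected but
    donor averaging is exercised downstream.
    """
    rng = _spawn(config.seed, "expression")
    gene_ids = config.gene_ids()
    regions = list(config.region_labels)
    weights = np.array([w for _, w in regions], dtype=float)
    weights = weights / weights.sum()
    panel: list[DonorExpression] = []
    for d, n_samples in enumerate(config.donor_sample_counts()):
        donor_id = f"D{d + 1}"
        # deterministic proportional region allocation (largest remainder)
        alloc = np.floor(weights * n_samples).astype(int)
        remainder = n_samples - alloc.sum()
        order = np.argsort(-(weights * n_samples - alloc), kind="stable")
        alloc[order[:remainder]] += 1
        region_per_sample = np.repeat([r for r, _ in regions], alloc)
        sample_ids = [f"{donor_id}_S{i:04d}" for i in range(n_samples)]
        X = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
        offsets = rng.normal(0.0, config.donor_offset_sd, size=config.n_genes)
        X += offsets[:, None]
        for mod in config.planted_modules:
            mu = np.array([mod.region_means[r] for r in region_per_sample])
            latent = rng.standard_normal(n_samples)
            X[list(mod.genes), :] += mu + mod.strength * latent
        df = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
        reg = pd.Series(region_per_sample, index=sample_ids, name="region")
        panel.append(DonorExpression(donor_id, df, reg))
    return panel


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

class LdReference:
    """Pairwise SNP correlations, as explicit blocks or a dense matrix.

    Correlation between SNPs in different blocks (or absent from a dense
    matrix) is taken to be zero — LD does not span blocks, and in particular
    never spans chromosomes.
    """

    def __init__(
        self,
        snp_ids: Sequence[str],
        block_ids: Sequence[int] | None = None,
        block_r: Mapping[int, float] | None = None,
        matrix: np.ndarray | None = None,
    ):
        self.snp_ids = list(snp_ids)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if matrix is not None:
            matrix = np.asarray(matrix, dtype=float)
            if matrix.shape != (len(self.snp_ids),) * 2:
                raise ConfigError("LD matrix shape does not match snp_ids")
            self.matrix = matrix
            self.block_ids = None
            self.block_r = None
        else:
            if block_ids is None or block_r is None:
                raise ConfigError("need either a matrix or block_ids + block_r")
            if len(block_ids) != len(self.snp_ids):
                raise ConfigError("block_ids length does not match snp_ids")
            self.matrix = None
            self.block_ids = list(block_ids)
            self.block_r = dict(block_r)

    def correlation(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Dense correlation matrix for the requested SNPs (order preserved).

        Unknown SNPs are treated as independent of everything.  Repeated ids
        (two genes sharing a top SNP) yield correlation 1 between the copies.
        """
        m = len(snp_ids)
        idx = np.array([self._index.get(s, -1) for s in snp_ids])
        known = idx >= 0
        if self.matrix is not None:
            R = np.zeros((m, m))
            sel = np.flatnonzero(known)
            R[np.ix_(sel, sel)] = self.matrix[np.ix_(idx[sel], idx[sel])]
        else:
            blocks = np.full(m, -1)
            rvals = np.zeros(m)
            for i in np.flatnonzero(known):
                b = self.block_ids[idx[i]]
                blocks[i] = b
                rvals[i] = self.block_r[b]
            same_block = (blocks[:, None] == blocks[None, :]) & (blocks[:, None] >= 0)
            R = np.where(same_block, rvals[:, None], 0.0)
        # repeated ids (e.g. two genes sharing a top SNP) correlate perfectly
        ids = np.array(snp_ids, dtype=object)
        R[ids[:, None] == ids[None, :]] = 1.0
        np.fill_diagonal(R, 1.0)
        return (R + R.T) / 2.0

    def partition_independent(self, snp_ids: Sequence[str]) -> list[list[str]]:
        """Split SNPs into groups that are mutually independent of each other.

        With block-structured LD the groups are the blocks (unknown SNPs are
        singletons, except repeats of one id which stay together); with a
        dense matrix everything lands in one group.  Eigen-based effective
        numbers can then be computed per group and summed.
        """
        if self.block_ids is None:
            return [list(snp_ids)]
        groups: dict[tuple, list[str]] = {}
        for s in snp_ids:
            i = self._index.get(s)
            key = ("block", self.block_ids[i]) if i is not None else ("snp", s)
            groups.setdefault(key, []).append(s)
        return list(groups.values())

    def to_frame(self) -> pd.DataFrame:
        """Block descriptor table (snp_id, block_id, r); requires block form."""
        if self.block_ids is None:
            raise ConfigError("dense-matrix LD reference has no block descriptor")
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "block_id": self.block_ids,
                "r": [self.block_r[b] for b in self.block_ids],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LdReference":
        block_r = df.groupby("block_id")["r"].first().to_dict()
        return cls(list(df["snp_id"]), list(df["block_id"].astype(int)), block_r)


def _snp_positions(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced SNPs over the span of the gene models (or one contig)."""
    if config.gene_models is None:
        pos = np.arange(1, config.n_snps + 1) * 1000
        return pd.DataFrame(
            {"snp_id": [f"rs{i:06d}" for i in range(config.n_snps)], "chrom": "1", "pos": pos}
        )
    gm = config.gene_models
    chroms = list(dict.fromkeys(gm["chrom"]))
    spans = {c: int(gm.loc[gm["chrom"] == c, "end"].max()) + 15_000 for c in chroms}
    total = sum(spans.values())
    rows = []
    i = 0
    for c in chroms:
        n_c = max(1, round(config.n_snps * spans[c] / total))
        if c == chroms[-1]:
            n_c = config.n_snps - i
        step = max(1, spans[c] // max(n_c, 1))
        for j in range(n_c):
            rows.append((f"rs{i:06d}", c, 1 + j * step))
            i += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def simulate_gwas(config: SimulationConfig) -> tuple[pd.DataFrame, LdReference]:
    """Generate SNP summary statistics plus the true LD reference.

    Per block, z-scores are one draw from an exchangeable multivariate
    normal.  For each associated gene the configured noncentrality is added
    to the SNP nearest the gene's midpoint within its 15-kb flanked window
    (the designated causal SNP) and propagated as ``r * noncentrality`` to
    the causal SNP's block partners.  P-values are two-sided normal tails.
    """
    rng = _spawn(config.seed, "gwas")
    snps = _snp_positions(config)
    if config.ld_blocks:
        blocks = list(config.ld_blocks)
    else:
        blocks = [LdBlock(1, 0.0)] * config.n_snps
    if sum(b.size for b in blocks) != len(snps):
        raise ConfigError("ld_blocks must tile the SNP list exactly")

    z = np.empty(len(snps))
    block_ids = np.empty(len(snps), dtype=int)
    block_r: dict[int, float] = {}
    start = 0
    for b_id, blk in enumerate(blocks):
        stop = start + blk.size
        block_ids[start:stop] = b_id
        block_r[b_id] = blk.r
        if blk.size == 1 or blk.r == 0.0:
            z[start:stop] = rng.standard_normal(blk.size)
        elif blk.r > 0:
            shared = rng.standard_normal()
            z[start:stop] = np.sqrt(blk.r) * shared + np.sqrt(1 - blk.r) * rng.standard_normal(
                blk.size
            )
        else:
            S = np.full((blk.size, blk.size), blk.r)
            np.fill_diagonal(S, 1.0)
            z[start:stop] = np.linalg.cholesky(S) @ rng.standard_normal(blk.size)
        start = stop

    if config.associated_genes:
        gm = config.gene_models.set_index("gene_id")
        pos = snps["pos"].to_numpy()
        chrom = snps["chrom"].to_numpy()
        for gene_id in sorted(config.associated_genes):
            delta = config.associated_genes[gene_id]
            g = gm.loc[gene_id]
            in_window = (
                (chrom == g["chrom"])
                & (pos >= g["start"] - 15_000)
                & (pos <= g["end"] + 15_000)
            )
            if not in_window.any():
                raise ConfigError(f"associated gene {gene_id!r} has no SNPs in its window")
            mid = (g["start"] + g["end"]) / 2
            candidates = np.flatnonzero(in_window)
            causal = candidates[np.argmin(np.abs(pos[candidates] - mid))]
            z[causal] += delta
            partners = np.flatnonzero(block_ids == block_ids[causal])
            partners = partners[partners != causal]
            z[partners] += block_r[block_ids[causal]] * delta

    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = snps.assign(z=z, p=p)
    ld = LdReference(list(snps["snp_id"]), list(block_ids), block_r)
    return table, ld


# ---------------------------------------------------------------------------
# Cell-type RPKM
# ---------------------------------------------------------------------------

def simulate_celltype_rpkm(config: SimulationConfig) -> pd.DataFrame:
    """Genes x cell-types RPKM table honouring the tenfold specificity rule.

    Non-specific genes draw i.i.d. log-normal RPKM across cell types
    (exchangeable).  A gene designated specific to type *t* first draws the
    other types, then sets RPKM(t) to ``fold * mean(others) * u`` with
    ``u ~ Uniform(1.2, 5)``, so the strict rule holds by construction for
    *t* and (almost surely) no other type.
    """
    cc = config.celltype_config
    rng = _spawn(config.seed, "celltype")
    gene_ids = config.gene_ids()
    k = len(cc.cell_types)
    vals = rng.lognormal(cc.meanlog, cc.sdlog, size=(len(gene_ids), k))
    type_index = {t: j for j, t in enumerate(cc.cell_types)}
    for i, g in enumerate(gene_ids):
        t = cc.specific.get(g)
        if t is None:
            continue
        j = type_index[t]
        others = np.delete(vals[i], j)
        vals[i, j] = cc.fold * others.mean() * rng.uniform(1.2, 5.0)
    return pd.DataFrame(vals, index=gene_ids, columns=list(cc.cell_types))
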