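"""Gene-based association from GWAS summary statistics.

The gene statistic is an extended Simes combination of a gene's SNP
P-values: with the SNPs ordered p(1) <= ... <= p(M),

    gene_p = min_j  Me(M) * p(j) / Me(j),

where Me(j) is the effective number of independent tests among the j most
significant SNPs, derived from the eigenvalues of their P-value correlation
matrix: Me = M - sum over eigenvalues lambda > 1 of (lambda - 1).  For
independent SNPs this reduces exactly to the Simes statistic; for perfectly
correlated SNPs it reduces to min p.

The correlation between two-sided P-values is obtained from the SNP (LD)
correlation r through a pluggable transform.  The default, ``"gaussian"``,
evaluates corr(P_i, P_j) for bivariate-normal z-scores exactly by
quadrature; ``"abs"`` uses |r| directly, which overstates P-value
correlation and makes the tail anti-conservative — it is kept for
comparison with implementations that use it.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .simulate import LdReference

__all__ = [
    "assign_snps_to_genes",
    "effective_number",
    "pvalue_correlation",
    "gates_p",
    "gene_association_table",
    "classify_genes",
    "load_snp_table",
    "load_gene_models",
]

DEFAULT_FLANK_BP = 15_000


# ---------------------------------------------------------------------------
# SNP-to-gene assignment
# ---------------------------------------------------------------------------

def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> dict[str, list[int]]:
    """Map each gene to the row indices of SNPs in its flanked window.

    A SNP s belongs to gene g iff ``start - flank <= pos(s) <= end + flank``
    on g's chromosome (closed interval, 1-based inclusive coordinates).  A
    SNP may belong to several genes; genes with no SNPs map to an empty list.
    """
    if flank_bp < 0:
        raise ConfigError("flank_bp must be >= 0")
    for col in ("snp_id", "chrom", "pos"):
        if col not in snps.columns:
            raise DataError(f"SNP table missing column {col!r}")
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in genes.columns:
            raise DataError(f"gene table missing column {col!r}")
    out: dict[str, list[int]] = {}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in snps.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        by_chrom[str(chrom)] = (sub["pos"].to_numpy()[order], sub.index.to_numpy()[order])
    for row in genes.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in by_chrom:
            out[row.gene_id] = []
            continue
        pos, idx = by_chrom[chrom]
        lo = np.searchsorted(pos, row.start - flank_bp, side="left")
        hi = np.searchsorted(pos, row.end + flank_bp, side="right")
        out[row.gene_id] = idx[lo:hi].tolist()
    return out


# ---------------------------------------------------------------------------
# Effective number of tests
# ---------------------------------------------------------------------------

def effective_number(corr: np.ndarray) -> float:
    """Effective number of independent tests from a correlation matrix.

    Me = M - sum_i max(lambda_i - 1, 0) over the eigenvalues of ``corr``;
    equals M for the identity and 1 for an all-ones matrix.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise DataError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise DataError("correlation matrix must be symmetric")
    M = corr.shape[0]
    lam = np.linalg.eigvalsh(corr)
    me = M - float(np.sum(np.clip(lam - 1.0, 0.0, None)))
    return float(min(max(me, 1.0), M))


# ---------------------------------------------------------------------------
# P-value correlation transforms
# ---------------------------------------------------------------------------

def _gaussian_pcorr_table(n_grid: int = 201, nodes: int = 120, zmax: float = 8.0):
    """Tabulate corr(P_i, P_j) for two-sided P-values of bivariate-normal z.

    E[P1 P2] is integrated over the positive quadrant with the density
    folded across both axes (the integrand has a kink at z = 0, so plain
    Gauss-Hermite converges poorly).  corr = (E - 1/4) / (1/12); it depends
    on |r| only.
    """
    x, w = np.polynomial.legendre.leggauss(nodes)
    a = 0.5 * zmax * (x + 1.0)
    wa = 0.5 * zmax * w
    pv = 2.0 * stats.norm.sf(a)
    A, B = a[:, None], a[None, :]
    grid = np.linspace(0.0, 0.999, n_grid)
    out = np.empty(n_grid)
    for i, r in enumerate(grid):
        det = 1.0 - r * r
        q1 = np.exp(-(A * A - 2 * r * A * B + B * B) / (2 * det))
        q2 = np.exp(-(A * A + 2 * r * A * B + B * B) / (2 * det))
        fold = 2.0 * (q1 + q2) / (2 * np.pi * np.sqrt(det))
        E = wa @ (pv[:, None] * pv[None, :] * fold) @ wa
        out[i] = (E - 0.25) / (1.0 / 12.0)
    out[0] = 0.0
    return grid, np.clip(out, 0.0, 1.0)


_PCORR_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def pvalue_correlation(r: np.ndarray, transform: str | Callable = "gaussian") -> np.ndarray:
    """Map SNP correlations r to P-value correlations.

    ``"gaussian"`` — exact two-sided-P correlation under bivariate normality
    (tabulated once per process, interpolated); ``"abs"`` — |r|; or any
    callable r -> rho.
    """
    r = np.asarray(r, dtype=float)
    if callable(transform):
        rho = np.asarray(transform(r), dtype=float)
    elif transform == "abs":
        rho = np.abs(r)
    elif transform == "gaussian":
        global _PCORR_CACHE
        if _PCORR_CACHE is None:
            _PCORR_CACHE = _gaussian_pcorr_table()
        grid, table = _PCORR_CACHE
        rho = np.interp(np.clip(np.abs(r), 0.0, 1.0), grid, table)
        rho = np.where(np.abs(r) >= 1.0, 1.0, rho)
    else:
        raise ConfigError(f"unknown P-value correlation transform {transform!r}")
    out = np.clip(rho, 0.0, 1.0)
    if out.ndim == 2:
        np.fill_diagonal(out, 1.0)
    return out


# ---------------------------------------------------------------------------
# Gene statistic
# ---------------------------------------------------------------------------

def gates_p(
    snp_ps: Sequence[float],
    corr: np.ndarray,
    transform: str | Callable = "gaussian",
) -> float:
    """Extended-Simes gene P-value for one gene.

    Parameters
    ----------
    snp_ps : sequence of float
        The gene's SNP P-values, already ordered ascending.
    corr : ndarray
        SNP (LD) correlation matrix in the same order as ``snp_ps``.
    """
    p = np.asarray(snp_ps, dtype=float)
    M = len(p)
    if M == 0:
        raise DataError("gene has no SNPs; gene P undefined")
    if np.any(np.diff(p) < 0):
        raise DataError("snp_ps must be sorted ascending")
    rho = pvalue_correlation(np.asarray(corr, dtype=float), transform)
    me = np.array([effective_number(rho[:j, :j]) for j in range(1, M + 1)])
    gene_p = float(np.min(me[-1] * p / me))
    return float(min(max(gene_p, np.finfo(float).tiny), 1.0))


def gene_association_table(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    ld: LdReference,
    flank_bp: int = DEFAULT_FLANK_BP,
    alpha: float = 0.05,
    transform: str | Callable = "gaussian",
) -> pd.DataFrame:
    """Per-gene association table: gene_p, top SNP, Me, class label.

    Genes with no SNPs in their window get ``gene_p = NaN`` and class
    ``"none"``; they are excluded from the Bonferroni denominator.
    SNPs within a gene are ordered by (p, pos) so ties are deterministic.
    """
    if "p" not in snps.columns:
        raise DataError("SNP table missing column 'p'")
    pvals = snps["p"].to_numpy(dtype=float)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise DataError("SNP P-values must lie in (0, 1]")
    assignment = assign_snps_to_genes(snps, genes, flank_bp)
    rows = []
    for gene_id in genes["gene_id"]:
        idx = assignment[gene_id]
        if not idx:
            rows.append((gene_id, 0, np.nan, None, np.nan))
            continue
        sub = snps.loc[idx, ["snp_id", "pos", "p"]].sort_values(
            ["p", "pos"], kind="stable"
        )
        R = ld.correlation(list(sub["snp_id"]))
        rho = pvalue_correlation(R, transform)
        me_total = effective_number(rho)
        gp = gates_p(sub["p"].to_numpy(), R, transform)
        rows.append((gene_id, len(idx), me_total, sub["snp_id"].iloc[0], gp))
    table = pd.DataFrame(
        rows, columns=["gene_id", "n_snps", "me_total", "top_snp", "gene_p"]
    )
    return classify_genes(table, alpha=alpha)


def classify_genes(assocs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label genes: candidate (gene_p < alpha) and high-confidence
    (Bonferroni: gene_p * N < alpha, N = genes with defined gene_p)."""
    table = assocs.copy()
    defined = table["gene_p"].notna()
    n_tested = int(defined.sum())
    label = np.full(len(table), "none", dtype=object)
    cand = defined & (table["gene_p"] < alpha)
    hc = defined & (table["gene_p"] * n_tested < alpha)
    label[cand.to_numpy()] = "candidate"
    label[(cand & hc).to_numpy()] = "high_confidence"
    table["class"] = label
    return table


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def load_snp_table(path) -> pd.DataFrame:
    snps = pd.read_csv(path, sep="\t", comment="#")
    required = {"snp_id", "chrom", "pos", "p"}
    if not required <= set(snps.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    snps["chrom"] = snps["chrom"].astype(str)
    return snps


def load_gene_models(path, bed_style: bool = False) -> pd.DataFrame:
    """Gene models with 1-based inclusive coordinates.

    ``bed_style=True`` accepts 0-based half-open rows and converts on load.
    """
    gm = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "start", "end"}
    if not required <= set(gm.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    gm["chrom"] = gm["chrom"].astype(str)
    if bed_style:
        gm["start"] = gm["start"] + 1
    if (gm["start"] > gm["end"]).any():
        raise DataError(f"{path}: gene start > end")
    return gm
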