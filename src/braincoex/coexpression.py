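"""Robust spatial co-expression: biweight midcorrelation averaged over donors.

Correlations are computed per donor across that donor's samples, then
averaged element-wise across donors, so the result reflects spatial
expression patterns rather than between-donor level differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .expression import DonorExpression

__all__ = [
    "CoexpressionMatrix",
    "bicor",
    "bicor_matrix",
    "donor_average",
    "donor_consistency",
    "coexpression_from_panel",
    "save_coexpression",
    "load_coexpression",
]

_TOL = 1e-12


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene correlation matrix with unit diagonal."""

    genes: list[str]
    values: np.ndarray
    n_donors_averaged: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if v.shape != (n, n):
            raise DataError(f"matrix shape {v.shape} does not match {n} genes")
        if not np.allclose(v, v.T, atol=_TOL):
            raise DataError("co-expression matrix is not symmetric")
        if np.abs(v).max(initial=0.0) > 1.0 + _TOL:
            raise DataError("co-expression values outside [-1, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=_TOL):
            raise DataError("co-expression diagonal must be 1")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise DataError(f"genes absent from co-expression matrix: {missing[:5]}")
        sel = [idx[g] for g in genes]
        return self.values[np.ix_(sel, sel)]


def _biweight_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise median-centred, Tukey-biweighted, unit-norm vectors.

    u_i = (x_i - median) / (9 * MAD); weights (1 - u^2)^2 for |u| < 1, else 0.
    Rows with MAD = 0 (but not constant) fall back to unit weights on the
    median-centred values, the usual robust-correlation convention.
    Constant rows raise: correlation is undefined for them.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0.0
    constant = np.all(dev == 0.0, axis=1)
    if constant.any():
        raise DataError(
            f"constant rows have no defined correlation (indices {np.flatnonzero(constant)[:5].tolist()})"
        )
    safe_mad = np.where(mad == 0.0, 1.0, mad)
    u = dev / (9.0 * safe_mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    w[zero_mad] = 1.0  # MAD=0 fallback: median-centred Pearson weights
    a = dev * w
    norms = np.sqrt(np.sum(a**2, axis=1, keepdims=True))
    degenerate = norms[:, 0] == 0.0
    if degenerate.any():
        # all points beyond the biweight cutoff: fall back to plain weights too
        a[degenerate] = dev[degenerate]
        norms = np.sqrt(np.sum(a**2, axis=1, keepdims=True))
    return a / norms


def bicor(x: Sequence[float], y: Sequence[float]) -> float:
    """Biweight midcorrelation of two vectors, in [-1, 1].

    Raises
    ------
    DataError
        For vectors shorter than 3, mismatched lengths, or constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("bicor needs two equal-length 1-D vectors")
    if len(x) < 3:
        raise DataError("bicor needs at least 3 observations")
    A = _biweight_rows(np.vstack([x, y]))
    return float(np.clip(A[0] @ A[1], -1.0, 1.0))


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """All pairwise biweight midcorrelations of the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise DataError("bicor needs at least 3 samples")
    A = _biweight_rows(X)
    C = np.clip(A @ A.T, -1.0, 1.0)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def coexpression_from_panel(
    panel: Sequence[DonorExpression],
    drop_zero_variance: bool = True,
) -> CoexpressionMatrix:
    """Per-donor biweight midcorrelation, averaged element-wise across donors.

    Genes constant in any donor have no defined correlation there; by default
    they are dropped from the whole panel with a warning.
    """
    if not panel:
        raise DataError("empty panel")
    genes = panel[0].genes
    for donor in panel[1:]:
        if donor.genes != genes:
            raise DataError("donors must share an identical ordered gene set")
    keep = np.ones(len(genes), dtype=bool)
    for donor in panel:
        M = donor.matrix
        keep &= ~np.all(M == M[:, :1], axis=1)
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        if not drop_zero_variance:
            raise DataError(f"zero-variance genes present: {dropped[:5]}")
        warnings.warn(f"dropping {len(dropped)} zero-variance genes: {dropped[:5]}")
    kept_genes = [g for g, k in zip(genes, keep) if k]
    per_donor = [
        CoexpressionMatrix(kept_genes, bicor_matrix(donor.matrix[keep]), 1) for donor in panel
    ]
    return donor_average(per_donor)


def donor_average(per_donor: Sequence[CoexpressionMatrix]) -> CoexpressionMatrix:
    """Element-wise arithmetic mean of per-donor correlation matrices."""
    if not per_donor:
        raise DataError("no matrices to average")
    genes = per_donor[0].genes
    for cm in per_donor[1:]:
        if cm.genes != genes:
            raise DataError("mismatched gene sets across donors")
    mean = np.mean([cm.values for cm in per_donor], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CoexpressionMatrix(list(genes), mean, n_donors_averaged=len(per_donor))


def donor_consistency(per_donor: Sequence[CoexpressionMatrix]) -> pd.Series:
    """Leave-one-out agreement score per donor.

    For each donor: the Pearson correlation between its vectorised
    upper-triangle and that of the mean of all other donors.  A QC readout
    only; nothing downstream filters on it.
    """
    if len(per_donor) < 3:
        raise DataError("donor consistency needs >= 3 donors")
    genes = per_donor[0].genes
    for cm in per_donor[1:]:
        if cm.genes != genes:
            raise DataError("mismatched gene sets across donors")
    iu = np.triu_indices(len(genes), k=1)
    vecs = np.array([cm.values[iu] for cm in per_donor])
    scores = {}
    for i in range(len(per_donor)):
        others = np.mean(np.delete(vecs, i, axis=0), axis=0)
        scores[f"donor_{i}"] = float(np.corrcoef(vecs[i], others)[0, 1])
    return pd.Series(scores, name="consistency")


# ---------------------------------------------------------------------------
# Persistence: dense binary values + plain-text gene sidecar
# ---------------------------------------------------------------------------

def save_coexpression(cm: CoexpressionMatrix, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>`` (.npy values) and ``<path>.genes.txt`` sidecar.

    The sidecar's first line records the donor count; the rest is one gene id
    per line in matrix order.  The pair round-trips exactly.
    """
    path = Path(path)
    np.save(path, cm.values)
    npy = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = Path(str(npy) + ".genes.txt")
    with open(sidecar, "w") as fh:
        fh.write(f"#n_donors_averaged={cm.n_donors_averaged}\n")
        fh.write("\n".join(cm.genes) + "\n")
    return npy, sidecar


def load_coexpression(path: str | Path) -> CoexpressionMatrix:
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(path.suffix + ".npy")
    values = np.load(path)
    sidecar = Path(str(path) + ".genes.txt")
    with open(sidecar) as fh:
        first = fh.readline().strip()
        n_donors = int(first.split("=", 1)[1]) if first.startswith("#") else 1
        genes = [line.strip() for line in fh if line.strip()]
        if not first.startswith("#"):
            genes.insert(0, first)
    return CoexpressionMatrix(genes, values, n_donors_averaged=n_donors)
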