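"""Spatial expression panels: probe-to-gene collapsing and region profiles.

A *panel* is a list of :class:`DonorExpression`, one per donor, all over the
identical ordered gene set but with donor-specific samples.  Expression values
are treated as already normalised; the loaders do not transform them unless
``log2=True`` is requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "DonorExpression",
    "map_probes_to_genes",
    "region_profile",
    "load_expression_matrix",
    "load_sample_annotations",
    "write_expression_matrix",
    "write_sample_annotations",
    "load_panel",
    "write_panel",
]


@dataclass
class DonorExpression:
    """One donor's genes x samples expression matrix with region labels.

    Parameters
    ----------
    donor_id : str
        Donor identifier.
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns.
    regions : pandas.Series
        Region label per sample, indexed by sample id; must cover exactly
        the matrix columns.
    """

    donor_id: str
    values: pd.DataFrame
    regions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise DataError(
                f"donor {self.donor_id!r}: need >= 2 samples, got {self.values.shape[1]}"
            )
        if not self.values.index.is_unique:
            raise DataError(f"donor {self.donor_id!r}: duplicate gene ids")
        missing = set(self.values.columns) - set(self.regions.index)
        if missing:
            raise DataError(
                f"donor {self.donor_id!r}: samples without region label: {sorted(missing)[:5]}"
            )
        self.regions = self.regions.loc[self.values.columns]
        if self.values.isna().any().any():
            raise DataError(
                f"donor {self.donor_id!r}: missing expression values are not allowed"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()


def map_probes_to_genes(
    probe_values: pd.DataFrame,
    probe_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    Probes mapping to zero or to more than one gene are discarded.  When
    several probes map to the same gene, the gene's profile is the per-sample
    arithmetic mean of those probes, on the loaded scale.

    Parameters
    ----------
    probe_values : pandas.DataFrame
        Probe ids in the index, samples in columns.
    probe_map : mapping of probe id -> iterable of gene ids
        Probes absent from the map are treated as unmapped.

    Returns
    -------
    pandas.DataFrame
        Genes x samples, gene ids sorted lexicographically.

    Raises
    ------
    DataError
        If no probe survives the mapping rules.
    """
    if not probe_values.index.is_unique:
        raise DataError("duplicate probe ids in probe matrix")
    gene_of: dict[str, str] = {}
    for probe in probe_values.index:
        genes = set(probe_map.get(probe, ()))
        if len(genes) == 1:
            gene_of[probe] = next(iter(genes))
    if not gene_of:
        raise DataError("no mappable probes: every probe maps to 0 or >1 genes")
    kept = probe_values.loc[list(gene_of)]
    collapsed = kept.groupby(pd.Series(gene_of), sort=True).mean()
    collapsed.index.name = probe_values.index.name or "gene"
    return collapsed


def region_profile(
    panel: Sequence[DonorExpression],
    module_genes: Iterable[str],
) -> dict[str, float]:
    """Mean expression of a gene set per brain region, pooled over donors.

    Every (gene, sample) cell with the sample annotated to a region
    contributes equally; donors with more samples therefore carry
    proportionally more weight, matching a grand mean over all measurements.

    Raises
    ------
    DataError
        If any module gene is absent from the panel.
    """
    module_genes = sorted(set(module_genes))
    if not panel:
        raise DataError("empty expression panel")
    missing = set(module_genes) - set(panel[0].genes)
    if missing:
        raise DataError(f"module genes absent from panel: {sorted(missing)}")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for donor in panel:
        sub = donor.values.loc[module_genes]
        for region, cols in donor.regions.groupby(donor.regions).groups.items():
            block = sub[list(cols)]
            sums[region] = sums.get(region, 0.0) + float(block.to_numpy().sum())
            counts[region] = counts.get(region, 0) + block.size
    return {r: sums[r] / counts[r] for r in sorted(sums)}


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def load_expression_matrix(path: str | Path, log2: bool = False) -> pd.DataFrame:
    """Read a genes(or probes) x samples TSV: first column id, header samples."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.isna().any().any():
        raise DataError(f"{path}: missing expression values are not allowed")
    if log2:
        if (df.to_numpy() <= 0).any():
            raise DataError(f"{path}: non-positive values cannot be log2-transformed")
        df = np.log2(df)
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def load_sample_annotations(path: str | Path) -> pd.DataFrame:
    """Read sample annotations: columns sample_id, donor_id, region."""
    ann = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "donor_id", "region"}
    if not required <= set(ann.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    if ann["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicate sample ids")
    return ann


def write_sample_annotations(ann: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        ann.to_csv(fh, sep="\t", index=False)


def load_panel(
    expression_paths: Mapping[str, str | Path],
    annotation_path: str | Path,
    log2: bool = False,
) -> list[DonorExpression]:
    """Assemble a multi-donor panel from per-donor matrices + one annotation file.

    Gene sets must be identical across donors; the first donor's gene order is
    imposed on the rest.
    """
    ann = load_sample_annotations(annotation_path)
    panel: list[DonorExpression] = []
    gene_order: list[str] | None = None
    for donor_id in sorted(expression_paths):
        df = load_expression_matrix(expression_paths[donor_id], log2=log2)
        if gene_order is None:
            gene_order = list(df.index)
        elif set(df.index) != set(gene_order):
            raise DataError(f"donor {donor_id!r}: gene set differs from panel")
        df = df.loc[gene_order]
        sub = ann[ann["donor_id"] == donor_id].set_index("sample_id")
        keep = [s for s in df.columns if s in sub.index]
        if len(keep) < df.shape[1]:
            warnings.warn(
                f"donor {donor_id!r}: {df.shape[1] - len(keep)} samples lack annotations, dropped"
            )
        panel.append(DonorExpression(donor_id, df[keep], sub.loc[keep, "region"]))
    if not panel:
        raise DataError("no donors in panel")
    return panel


def write_panel(panel: Sequence[DonorExpression], outdir: str | Path, header: str | None = None) -> dict[str, Path]:
    """Write one matrix per donor plus a joint annotation table; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rows = []
    for donor in panel:
        p = outdir / f"expression_{donor.donor_id}.tsv"
        write_expression_matrix(donor.values, p, header=header)
        paths[donor.donor_id] = p
        for s in donor.samples:
            rows.append((s, donor.donor_id, donor.regions[s]))
    ann = pd.DataFrame(rows, columns=["sample_id", "donor_id", "region"])
    ann_path = outdir / "sample_annotations.tsv"
    write_sample_annotations(ann, ann_path, header=header)
    paths["annotations"] = ann_path
    return paths
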