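"""End-to-end orchestration with a reproducible configuration and manifest.

Stages run in dependency order (simulate/load -> gene association ->
co-expression -> modules -> enrichment -> seed network).  Every artifact is
written under the output directory, the configuration is serialised verbatim
next to the outputs, and the manifest records a SHA-256 checksum per file so
a re-run with the same config and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    coexpression_from_panel,
    donor_consistency,
    load_coexpression,
    save_coexpression,
)
from .enrichment import (
    build_celltype_signatures,
    celltype_enrichment,
    cluster_modules,
    export_module_gene_lists,
    module_enrichment_table,
)
from .errors import ConfigError, DataError, StageError
from .expression import load_panel, region_profile, write_panel
from .gene_assoc import gene_association_table, load_gene_models, load_snp_table
from .seed_network import annotate_network, merge_seed_networks
from .simulate import (
    CellTypeConfig,
    LdBlock,
    LdReference,
    PlantedModule,
    SimulationConfig,
    default_config,
    simulate_celltype_rpkm,
    simulate_expression,
    simulate_gwas,
)

__all__ = ["RunConfig", "run_pipeline", "sim_config_to_dict", "sim_config_from_dict"]


# ---------------------------------------------------------------------------
# Simulation config <-> plain dict (YAML-friendly)
# ---------------------------------------------------------------------------

def sim_config_to_dict(cfg: SimulationConfig) -> dict:
    return {
        "seed": cfg.seed,
        "n_donors": cfg.n_donors,
        "n_samples_per_donor": cfg.n_samples_per_donor
        if isinstance(cfg.n_samples_per_donor, int)
        else list(cfg.n_samples_per_donor),
        "region_labels": [[r, w] for r, w in cfg.region_labels],
        "n_genes": cfg.n_genes,
        "planted_modules": [
            {
                "genes": list(m.genes),
                "region_means": dict(m.region_means),
                "strength": m.strength,
            }
            for m in cfg.planted_modules
        ],
        "noise_sd": cfg.noise_sd,
        "donor_offset_sd": cfg.donor_offset_sd,
        "n_snps": cfg.n_snps,
        "ld_blocks": [[b.size, b.r] for b in cfg.ld_blocks],
        "gene_models": None
        if cfg.gene_models is None
        else cfg.gene_models.to_dict(orient="records"),
        "associated_genes": dict(cfg.associated_genes),
        "celltype_config": {
            "cell_types": list(cfg.celltype_config.cell_types),
            "meanlog": cfg.celltype_config.meanlog,
            "sdlog": cfg.celltype_config.sdlog,
            "specific": dict(cfg.celltype_config.specific),
            "fold": cfg.celltype_config.fold,
        },
    }


def sim_config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    cc = d.get("celltype_config", {})
    gm = d.get("gene_models")
    return SimulationConfig(
        seed=d.get("seed", 0),
        n_donors=d.get("n_donors", 3),
        n_samples_per_donor=d.get("n_samples_per_donor", 300),
        region_labels=tuple((r, float(w)) for r, w in d.get("region_labels", ())),
        n_genes=d.get("n_genes", 200),
        planted_modules=tuple(
            PlantedModule(tuple(m["genes"]), dict(m["region_means"]), float(m["strength"]))
            for m in d.get("planted_modules", ())
        ),
        noise_sd=d.get("noise_sd", 0.5),
        donor_offset_sd=d.get("donor_offset_sd", 0.3),
        n_snps=d.get("n_snps", 2000),
        ld_blocks=tuple(LdBlock(int(s), float(r)) for s, r in d.get("ld_blocks", ())),
        gene_models=None if gm is None else pd.DataFrame(gm),
        associated_genes=dict(d.get("associated_genes", {})),
        celltype_config=CellTypeConfig(
            cell_types=tuple(cc.get("cell_types", CellTypeConfig.cell_types)),
            meanlog=cc.get("meanlog", 1.0),
            sdlog=cc.get("sdlog", 1.0),
            specific=dict(cc.get("specific", {})),
            fold=cc.get("fold", 10.0),
        )
        if cc
        else CellTypeConfig(),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Reproducible description of one end-to-end run.

    Either ``sim`` (synthetic inputs) or ``inputs`` (paths to delimited-text
    files: per-donor expression, sample annotations, SNPs, gene models, LD
    blocks, RPKM) must be provided.
    """

    outdir: str
    seed: int = 0
    flank_bp: int = 15_000
    alpha: float = 0.05
    linkage: str = "complete"
    k: int = 18
    coexpr_threshold: float = 0.6
    celltype_fold: float = 10.0
    transform: str = "gaussian"
    sim: SimulationConfig | None = None
    inputs: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        for name in ("flank_bp", "alpha", "k", "coexpr_threshold", "celltype_fold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sim is None and self.inputs is None:
            raise ConfigError("either 'sim' or 'inputs' must be given")
        if self.sim is not None:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("sim",)
        }
        d["sim"] = None if self.sim is None else sim_config_to_dict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        if sim == "default":
            sim_cfg: SimulationConfig | None = default_config(d.get("seed", 0))
        elif isinstance(sim, Mapping):
            sim_cfg = sim_config_from_dict(sim)
        else:
            sim_cfg = None
        try:
            return cls(sim=sim_cfg, **d)
        except TypeError as exc:
            raise ConfigError(f"bad run configuration: {exc}") from None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        # the file wins over flag-style overrides; missing keys fall back
        merged = {**overrides, **d}
        return cls.from_dict(merged)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(stage: str, **kv: Any) -> None:
    fields = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"[braincoex] stage={stage} {fields}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    Stage failure raises :class:`StageError` naming the stage; artifacts
    written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, Any] = {
        "package": "braincoex",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, paths: list[Path]) -> None:
        written.extend(paths)
        manifest["stages"].append(stage)

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except (ConfigError, DataError, StageError) as exc:
            raise StageError(name, str(exc)) from exc
        _log(name, wall_s=f"{time.perf_counter() - t0:.2f}")
        return result

    # -- stage: data ---------------------------------------------------------
    def stage_data():
        data_dir = outdir / "data"
        data_dir.mkdir(exist_ok=True)
        if config.sim is not None:
            hdr = f"seed={config.seed}"
            panel = simulate_expression(config.sim)
            paths = write_panel(panel, data_dir, header=hdr)
            snps, ld = simulate_gwas(config.sim)
            snp_path = data_dir / "snps.tsv"
            with open(snp_path, "w") as fh:
                fh.write(f"# {hdr}\n")
                snps.to_csv(fh, sep="\t", index=False, float_format="%.10g")
            ld_path = data_dir / "ld_blocks.tsv"
            with open(ld_path, "w") as fh:
                fh.write(f"# {hdr}\n")
                ld.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")
            gm_path = data_dir / "gene_models.tsv"
            config.sim.gene_models.to_csv(gm_path, sep="\t", index=False)
            rpkm = simulate_celltype_rpkm(config.sim)
            rpkm_path = data_dir / "celltype_rpkm.tsv"
            with open(rpkm_path, "w") as fh:
                fh.write(f"# {hdr}\n")
                rpkm.to_csv(fh, sep="\t", float_format="%.10g")
            record("data", list(paths.values()) + [snp_path, ld_path, gm_path, rpkm_path])
            return panel, snps, ld, config.sim.gene_models, rpkm
        inp = config.inputs
        panel = load_panel(inp["expression"], inp["annotations"])
        snps = load_snp_table(inp["snps"])
        ld = LdReference.from_frame(pd.read_csv(inp["ld_blocks"], sep="\t", comment="#"))
        gm = load_gene_models(inp["gene_models"], bed_style=inp.get("bed_style", False))
        rpkm = pd.read_csv(inp["rpkm"], sep="\t", index_col=0, comment="#")
        record("data", [])
        return panel, snps, ld, gm, rpkm

    panel, snps, ld, gene_models, rpkm = run_stage("data", stage_data)

    # -- stage: gene association --------------------------------------------
    def stage_assoc():
        assoc_dir = outdir / "assoc"
        assoc_dir.mkdir(exist_ok=True)
        table = gene_association_table(
            snps, gene_models, ld,
            flank_bp=config.flank_bp, alpha=config.alpha, transform=config.transform,
        )
        path = assoc_dir / "gene_assoc.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        record("gene_assoc", [path])
        return table

    assoc = run_stage("gene_assoc", stage_assoc)

    # -- stage: co-expression ------------------------------------------------
    def stage_coexpr():
        co_dir = outdir / "coexpr"
        co_dir.mkdir(exist_ok=True)
        cm = coexpression_from_panel(panel)
        npy, sidecar = save_coexpression(cm, co_dir / "coexpression")
        paths = [npy, sidecar]
        if len(panel) >= 3:
            from .coexpression import CoexpressionMatrix, bicor_matrix

            per_donor = [
                CoexpressionMatrix(cm.genes, bicor_matrix(
                    d.values.loc[cm.genes].to_numpy()), 1)
                for d in panel
            ]
            qc = donor_consistency(per_donor)
            qc_path = co_dir / "donor_consistency.tsv"
            qc.to_csv(qc_path, sep="\t", float_format="%.10g")
            paths.append(qc_path)
        record("coexpression", paths)
        return cm

    cm = run_stage("coexpression", stage_coexpr)

    # -- stage: modules ------------------------------------------------------
    def stage_modules():
        mod_dir = outdir / "modules"
        mod_dir.mkdir(exist_ok=True)
        part = cluster_modules(cm, linkage=config.linkage, k=config.k)
        path = mod_dir / "partition.tsv"
        part.to_frame().to_csv(path, sep="\t", index=False)
        profiles = pd.DataFrame(
            {m: region_profile(panel, genes) for m, genes in part.modules().items()}
        ).T.rename_axis("module")
        prof_path = mod_dir / "region_profiles.tsv"
        profiles.to_csv(prof_path, sep="\t", float_format="%.10g")
        record("modules", [path, prof_path])
        return part

    partition = run_stage("modules", stage_modules)

    # -- stage: enrichment ---------------------------------------------------
    def stage_enrichment():
        enr_dir = outdir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        defined = assoc[assoc["gene_p"].notna()]
        candidates = set(defined.loc[defined["class"] != "none", "gene_id"])
        top_snps = dict(zip(defined["gene_id"], defined["top_snp"]))
        universe = set(partition.labels.index) & set(defined["gene_id"])
        snp_chrom = dict(zip(snps["snp_id"], snps["chrom"].astype(str)))
        table = module_enrichment_table(
            partition, candidates, universe=universe,
            top_snps=top_snps, ld=ld, snp_chrom=snp_chrom,
        )
        enr_path = enr_dir / "module_enrichment.tsv"
        table.to_csv(enr_path, sep="\t", index=False, float_format="%.10g")
        signatures = build_celltype_signatures(rpkm, fold=config.celltype_fold)
        ct = celltype_enrichment(partition.modules(), signatures, set(rpkm.index))
        ct_path = enr_dir / "celltype_enrichment.tsv"
        ct.to_csv(ct_path, sep="\t", index=False, float_format="%.10g")
        gene_p = dict(zip(defined["gene_id"], defined["gene_p"]))
        list_paths = export_module_gene_lists(partition, enr_dir / "gene_lists", gene_p)
        record("enrichment", [enr_path, ct_path] + list_paths)
        return table, signatures

    enrichment_table, signatures = run_stage("enrichment", stage_enrichment)

    # -- stage: seed network -------------------------------------------------
    def stage_seednet():
        net_dir = outdir / "seednet"
        net_dir.mkdir(exist_ok=True)
        seeds = set(assoc.loc[assoc["class"] == "high_confidence", "gene_id"])
        seeds &= set(cm.genes)
        paths = []
        if seeds:
            net = merge_seed_networks(seeds, cm, threshold=config.coexpr_threshold)
            edge_path = net_dir / "edges.tsv"
            net.write_edge_list(edge_path)
            gml_path = net_dir / "network.graphml"
            net.write_graphml(gml_path)
            mem_path = net_dir / "local_modules.tsv"
            net.membership_table().to_csv(mem_path, sep="\t", index=False)
            ann = annotate_network(net, partition, signatures,
                                   set(cm.genes) | set(rpkm.index))
            ann_path = net_dir / "annotation.tsv"
            ann.to_csv(ann_path, sep="\t", index=False, float_format="%.10g")
            paths = [edge_path, gml_path, mem_path, ann_path]
        else:
            note = net_dir / "NO_SEEDS.txt"
            note.write_text("no high-confidence genes; seed network skipped\n")
            paths = [note]
        record("seed_network", paths)

    run_stage("seed_network", stage_seednet)

    # -- manifest ------------------------------------------------------------
    config_path = outdir / "run_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    written.append(config_path)
    manifest["files"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
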