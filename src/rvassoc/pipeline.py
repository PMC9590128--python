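"""Four-stage pipeline orchestration from a single declarative config.

Stage 1 pre-filters variants with per-variant clinical association
tests; stage 2 maps the surviving variants to genes and runs gene-set
over-representation; stage 3 computes reference-population logistic
collapsing weights; stage 4 runs the gene-level variance-component
test. Each stage writes its CSV so the run is resumable/inspectable,
and a manifest records counts, the seed and stage completion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, genio, single_variant, skat, viz, weights
from .datasets import SetIdMap

log = logging.getLogger(__name__)

_VALID_METHODS = set(single_variant.METHODS)
_VALID_MODELS = set(single_variant.MODELS)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    genotype: str                      # PLINK prefix (.bed implied) or .vcf
    phenotype: str
    annotation_bed: str
    gmt: str | None = None
    maf_table: str | None = None
    outdir: str = "rvassoc_out"
    outcome: str = "outcome"
    covariates: list[str] = field(default_factory=list)
    method: str = "glm"
    model: str = "add"
    threshold: float = 0.05
    time_col: str | None = None
    event_col: str | None = None
    flank_bp: int = 0
    scheme: str = "logistic"           # logistic | beta
    w1: float = 0.07
    w2: float = 150.0
    fallback_policy: str = "sample_maf"
    out_type: str = "D"
    skat_covariates: list[str] = field(default_factory=list)
    plots: bool = True
    sig_val: float = 3.0
    geno_val: float = 5.0
    seed: int = 1234

    def validate(self) -> "PipelineConfig":
        errors = []
        if self.method not in _VALID_METHODS:
            errors.append(f"method: {self.method!r} not in {sorted(_VALID_METHODS)}")
        if self.model not in _VALID_MODELS:
            errors.append(f"model: {self.model!r} not in {sorted(_VALID_MODELS)}")
        if not 0.0 < self.threshold <= 1.0:
            errors.append(f"threshold: {self.threshold} not in (0, 1]")
        if self.scheme not in ("logistic", "beta"):
            errors.append(f"scheme: {self.scheme!r} not in ('logistic', 'beta')")
        if self.scheme == "logistic" and self.maf_table is None:
            errors.append("maf_table: required when scheme is 'logistic' (population weights)")
        if self.out_type not in ("C", "D"):
            errors.append(f"out_type: {self.out_type!r} not in ('C', 'D')")
        for name in ("phenotype", "annotation_bed"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errors.append(f"{name}: path {p} does not exist")
        geno = Path(self.genotype)
        if geno.suffix == ".vcf":
            if not geno.exists():
                errors.append(f"genotype: {geno} does not exist")
        else:
            for ext in (".bed", ".bim", ".fam"):
                if not geno.with_suffix(ext).exists():
                    errors.append(f"genotype: {geno.with_suffix(ext)} does not exist")
        for name in ("gmt", "maf_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errors.append(f"{name}: path {p} does not exist")
        if errors:
            raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
        return self


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(known)}")
    return PipelineConfig(**raw).validate()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute stages 1-4, writing per-stage CSVs, figures and a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    figdir = outdir / "figures"
    manifest: dict = {"seed": config.seed, "stages": [], "counts": {}, "warnings": []}

    # ---- load & merge -----------------------------------------------------
    geno_path = Path(config.genotype)
    if geno_path.suffix == ".vcf":
        geno = genio.read_vcf(geno_path)
    else:
        geno = genio.read_plink(geno_path.with_suffix(".bed"))
    pheno = genio.read_phenotypes(config.phenotype)
    ds = genio.merge_pheno_geno(pheno, geno)
    manifest["counts"]["samples"] = ds.n_samples
    manifest["counts"]["variants_in"] = geno.n_variants
    if ds.dropped_pheno:
        manifest["warnings"].append(f"{len(ds.dropped_pheno)} phenotype rows without genotypes")

    # ---- stage 1: single-variant pre-filter -------------------------------
    assoc = single_variant.functional_analysis(
        ds, config.method, config.outcome, config.model,
        config.covariates or None, config.threshold,
        time_col=config.time_col, event_col=config.event_col,
    )
    assoc.to_csv(outdir / "step1_assoc.csv")
    filtered = assoc.filtered
    manifest["stages"].append("functional_analysis")
    manifest["counts"]["variants_tested"] = int(len(assoc.tested))
    manifest["counts"]["variants_filtered"] = int(len(filtered))
    if config.plots:
        figdir.mkdir(exist_ok=True)
        cfg = viz.PlotConfig(sig_val=config.sig_val, geno_val=config.geno_val)
        viz.manhattan(assoc.table, figdir / "manhattan.png", cfg)
        _, _, lam = viz.qq_plot(assoc.table, figdir / "qq.png", cfg)
        manifest["counts"]["genomic_lambda"] = round(lam, 4)
        try:
            viz.ld_heatmap(ds.geno, assoc.table, figdir / "ld.png", cfg)
        except ValueError as exc:
            manifest["warnings"].append(f"ld plot skipped: {exc}")
    if filtered.empty:
        raise StageError("map_snps_to_genes", "no variants passed the stage-1 threshold")

    # ---- stage 2: gene mapping + ORA --------------------------------------
    keep_snps = set(filtered["SNP"])
    keep_idx = [j for j, rsid in enumerate(ds.geno.variants["rsid"]) if rsid in keep_snps]
    filtered_geno = ds.geno.subset_variants(keep_idx)
    intervals = annotate.read_gene_bed(config.annotation_bed)
    gene_map = annotate.map_snps_to_genes(filtered_geno.variants, intervals, config.flank_bp)
    gene_map.mapped.to_csv(outdir / "step2_genemap.csv", index=False)
    manifest["stages"].append("map_snps_to_genes")
    manifest["counts"]["variants_mapped"] = int(gene_map.mapped["SNP"].nunique())
    manifest["counts"]["variants_unmapped"] = int(len(gene_map.unmapped))
    manifest["counts"]["genes"] = len(gene_map.genes)
    if config.gmt:
        gene_sets = annotate.read_gmt(config.gmt)
        enrich = annotate.ora_test(gene_map.genes, gene_sets)
        enrich.to_csv(outdir / "step2_pathways.csv", index=False)
        manifest["counts"]["gene_sets_tested"] = int(len(enrich))

    # ---- stage 3: collapsing weights --------------------------------------
    mapped_snps = set(gene_map.mapped["SNP"])
    w_idx = [j for j, rsid in enumerate(filtered_geno.variants["rsid"]) if rsid in mapped_snps]
    weight_geno = filtered_geno.subset_variants(w_idx)
    if config.scheme == "logistic":
        maf_table = genio.read_maf_reference(config.maf_table)
        smaf = dict(zip(weight_geno.variants["rsid"], weight_geno.sample_maf()))
        wtab = weights.get_logistic_weights_maf_pop(
            weight_geno.variants, maf_table,
            weights.WeightParams(config.w1, config.w2),
            config.fallback_policy, sample_maf=smaf,
        )
        wtab.to_csv(outdir / "step3_weights.csv", index=False)
        weight_table = wtab
        manifest["counts"]["variants_weighted"] = int(len(wtab))
    else:
        weight_table = None  # stage 4 applies the Beta(1,25) default
        manifest["counts"]["variants_weighted"] = int(weight_geno.n_variants)
    manifest["stages"].append("get_logistic_weights_maf_pop")

    # ---- stage 4: gene-level association ----------------------------------
    setid = SetIdMap(gene_map.to_setid_pairs())
    outcome_col = config.outcome if config.out_type in ("C", "D") else None
    y = ds.pheno[outcome_col].to_numpy()
    covs = config.skat_covariates or config.covariates
    Z = ds.pheno[covs].to_numpy(dtype=float) if covs else None
    result = skat.skat_assoc(
        weight_geno, setid, y, Z, config.out_type, weight_table,
    )
    skat.write_skat_csv(result, outdir / "step4_skat.csv")
    manifest["stages"].append("skat_assoc")
    manifest["counts"]["genes_tested"] = int(
        (result["N.Marker.Test"] > 0).sum()
    )
    if config.plots:
        viz.gene_bar(result, figdir / "gene_bar.png",
                     viz.PlotConfig(bar_pval=1.0))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
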