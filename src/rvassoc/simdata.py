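"""Synthetic cohort generator for end-to-end testing of the pipeline.

Emulates the kind of study the pipeline targets — a small clinical
cohort (binary severity outcome with sex/age covariates) genotyped
genome-wide, with variants grouped into genes — entirely from a seeded
random generator, so every stage can be exercised without external
downloads. Genotypes are drawn under Hardy-Weinberg equilibrium
(dosage ~ Binomial(2, MAF)), independently across variants by default;
an optional block-LD mode copies alleles within blocks so that LD
visualization has structure to show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset, SetIdMap
from .genio import write_plink, write_setid, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class SimSpec:
    """Parameters of a simulated cohort.

    Defaults describe a small clinical cohort: n = 500 samples,
    m = 1000 variants in 100 genes of 10 variants each, MAF spectrum
    uniform on [0.005, 0.3] (rare through common), 1% missing genotypes,
    and a null binary outcome with a sex covariate and a centred age
    covariate. ``beta`` assigns per-variant log-odds (logistic), linear
    effects, or log hazard rates keyed by variant index.
    """

    n: int = 500
    m: int = 1000
    maf_range: tuple[float, float] = (0.005, 0.3)
    mafs: np.ndarray | None = None
    missing_rate: float = 0.01
    outcome: str = "null"            # null | logistic | linear | survival
    beta: dict[int, float] = field(default_factory=dict)
    alpha: float = 0.0               # intercept (logit / mean / log-baseline-rate)
    gamma_sex: float = 0.0
    gamma_age: float = 0.0
    sigma: float = 1.0               # linear-outcome noise SD
    censoring_rate: float = 0.3      # survival: expected fraction censored
    genes: int = 100
    variants_per_gene: int | None = None
    ld_blocks: int = 0               # >0: block size for Markov allele copying
    ld_rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.variants_per_gene is None:
            self.variants_per_gene = max(1, self.m // self.genes)


def _draw_mafs(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.mafs is not None:
        mafs = np.asarray(spec.mafs, dtype=float)
        if mafs.size != spec.m:
            raise ValueError("explicit MAF vector length must equal m")
        return mafs
    lo, hi = spec.maf_range
    return rng.uniform(lo, hi, size=spec.m)


def simulate_genotypes(spec: SimSpec) -> GenotypeDataset:
    """Draw a genotype matrix under HWE with the spec's MAF spectrum.

    Variants are laid out on chromosomes 1..22 cyclically by gene, with
    increasing positions; rsids are synthetic ("rs<index>"). The true
    simulation MAFs are stored on the variant table (column ``true_maf``).
    """
    rng = np.random.default_rng(spec.seed)
    mafs = _draw_mafs(spec, rng)

    if spec.ld_blocks > 1:
        # Markov allele copying within blocks: each haplotype allele is
        # copied from the previous variant with prob ld_rho
        H = np.empty((spec.n, 2, spec.m), dtype=np.int8)
        for j in range(spec.m):
            fresh = rng.random((spec.n, 2)) < mafs[j]
            if j % spec.ld_blocks == 0:
                H[:, :, j] = fresh
            else:
                copy = rng.random((spec.n, 2)) < spec.ld_rho
                H[:, :, j] = np.where(copy, H[:, :, j - 1], fresh)
        dosage = H.sum(axis=1).astype(np.int8)
    else:
        dosage = rng.binomial(2, mafs, size=(spec.n, spec.m)).astype(np.int8)

    if spec.missing_rate > 0:
        mask = rng.random((spec.n, spec.m)) < spec.missing_rate
        dosage[mask] = MISSING

    genes_of = np.arange(spec.m) // spec.variants_per_gene
    chroms = (genes_of % 22) + 1
    pos = np.zeros(spec.m, dtype=int)
    offset_in_chrom: dict[int, int] = {}
    gene_base: dict[int, int] = {}
    for j in range(spec.m):
        g = genes_of[j]
        c = chroms[j]
        if g not in gene_base:
            offset_in_chrom[c] = offset_in_chrom.get(c, 0) + 100_000
            gene_base[g] = offset_in_chrom[c]
        pos[j] = gene_base[g] + 100 * (j % spec.variants_per_gene) + 1

    ref_idx = rng.integers(0, 4, size=spec.m)
    alt_shift = rng.integers(1, 4, size=spec.m)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    variants = pd.DataFrame(
        {
            "chrom": chroms.astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "rsid": [f"rs{j + 1}" for j in range(spec.m)],
            "a1": alt,
            "a2": ref,
            "gene": [f"GENE{g + 1}" for g in genes_of],
            "true_maf": mafs,
        }
    )
    samples = [f"S{i + 1}" for i in range(spec.n)]
    return GenotypeDataset(samples, variants, dosage)


def simulate_phenotypes(geno: GenotypeDataset, spec: SimSpec) -> pd.DataFrame:
    """Simulate an outcome and covariates for an existing genotype dataset.

    Covariates: sex ~ Bernoulli(0.5) and age ~ Normal(50, 10) (centred
    before entering the linear predictor). Outcome models:

    - null / logistic: P(y=1) = expit(alpha + G beta + Z gamma)
    - linear: y = alpha + G beta + Z gamma + Normal(0, sigma)
    - survival: exponential times with rate exp(alpha + G beta + Z gamma),
      independent uniform censoring tuned to ``censoring_rate``.

    Missing genotypes contribute their expected dosage (2 * true MAF) to
    the linear predictor so missingness is outcome-independent.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = geno.n_samples
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.normal(50.0, 10.0, size=n)

    eta = np.full(n, spec.alpha, dtype=float)
    eta += spec.gamma_sex * sex + spec.gamma_age * (age - 50.0)
    if spec.beta:
        true_maf = geno.variants["true_maf"].to_numpy()
        for j, b in spec.beta.items():
            g = geno.dosage[:, j].astype(float)
            g[g == MISSING] = 2.0 * true_maf[j]
            eta += b * g

    pheno = pd.DataFrame({"sample_id": geno.samples, "sex": sex.astype(int),
                          "age": np.round(age, 2)})
    if spec.outcome in ("null", "logistic"):
        prob = 1.0 / (1.0 + np.exp(-eta))
        pheno["outcome"] = rng.binomial(1, prob)
    elif spec.outcome == "linear":
        pheno["outcome"] = eta + rng.normal(0.0, spec.sigma, size=n)
    elif spec.outcome == "survival":
        rate = np.exp(eta)
        t_event = rng.exponential(1.0 / rate)
        # uniform censoring window calibrated to the target censoring rate
        c_max = np.quantile(t_event, 1.0 - spec.censoring_rate / 2.0) * 2.0
        t_cens = rng.uniform(0.0, c_max, size=n)
        pheno["time"] = np.minimum(t_event, t_cens)
        pheno["event"] = (t_event <= t_cens).astype(int)
    else:
        raise ValueError(f"unknown outcome model {spec.outcome!r}")
    return pheno


def gene_intervals(geno: GenotypeDataset, pad_bp: int = 50) -> pd.DataFrame:
    """Gene intervals spanning each gene's variants (1-based inclusive)."""
    v = geno.variants
    rows = []
    for gene, grp in v.groupby("gene", sort=False):
        chrom = grp["chrom"].iloc[0]
        rows.append({"gene": gene, "chrom": chrom,
                     "start": max(1, int(grp["pos"].min()) - pad_bp),
                     "end": int(grp["pos"].max()) + pad_bp})
    return pd.DataFrame(rows)


def reference_maf_table(geno: GenotypeDataset, ref_n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Reference-population MAFs: true MAFs with binomial resampling noise.

    Emulates an external population panel of ``ref_n`` diploid samples
    whose allele counts are drawn around the true simulation MAF.
    """
    rng = np.random.default_rng(seed + 2)
    v = geno.variants
    true = v["true_maf"].to_numpy()
    counts = rng.binomial(2 * ref_n, true)
    maf = counts / (2 * ref_n)
    maf = np.minimum(maf, 1.0 - maf)
    return pd.DataFrame({"chr": v["chrom"], "pos": v["pos"], "ref": v["ref"],
                         "alt": v["alt"], "maf": maf})


def make_fixture_suite(outdir, spec: SimSpec, ref_n: int = 10_000) -> dict[str, Path]:
    """Write a coherent file bundle for a full four-stage pipeline run.

    Emits: PLINK trio + identical VCF, phenotype CSV, gene BED, a GMT
    with one set per gene plus pooled multi-gene sets, a SetID file, and
    a reference MAF TSV. Returns a name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(spec)
    pheno = simulate_phenotypes(geno, spec)

    bed, bim, fam = write_plink(geno, outdir / "geno.bed")
    vcf = write_vcf(geno, outdir / "geno.vcf")
    pheno_path = outdir / "pheno.csv"
    pheno.to_csv(pheno_path, index=False)

    intervals = gene_intervals(geno)
    bed_anno = outdir / "genes.bed"
    pd.DataFrame({
        "chrom": intervals["chrom"],
        "start": intervals["start"] - 1,  # 1-based inclusive -> 0-based half-open
        "end": intervals["end"],
        "name": intervals["gene"],
    }).to_csv(bed_anno, sep="\t", header=False, index=False)

    genes = list(intervals["gene"])
    gmt_path = outdir / "sets.gmt"
    with open(gmt_path, "w") as fh:
        for i in range(0, len(genes), 5):
            block = genes[i:i + 5]
            fh.write("\t".join([f"PATHWAY_{i // 5 + 1}", "synthetic", *block]) + "\n")

    pairs = [(row.gene, row.rsid) for row in geno.variants.itertuples()]
    setid_path = write_setid(SetIdMap(pairs), outdir / "setid.txt")

    maf_path = outdir / "maf_ref.tsv"
    reference_maf_table(geno, ref_n, spec.seed).to_csv(maf_path, sep="\t", index=False)

    return {"bed": bed, "bim": bim, "fam": fam, "vcf": vcf, "pheno": pheno_path,
            "genes_bed": bed_anno, "gmt": gmt_path, "setid": setid_path,
            "maf": maf_path}
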