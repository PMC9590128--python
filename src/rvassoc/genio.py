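"""Readers and writers for the on-disk formats the pipeline consumes.

PLINK binary trios (.bed/.bim/.fam) are decoded natively, bit-exact per
the PLINK 1.9 specification (variant-major, 2 bits per genotype). VCF is
read through cyvcf2 (GT field only) and written as plain VCF 4.2 text.
Phenotype tables, SetID files and reference-population MAF tables are
small delimited text files handled with pandas.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import (
    MISSING,
    AnalysisDataset,
    GenotypeDataset,
    SetIdMap,
    VariantKey,
    normalize_chrom,
)

log = logging.getLogger(__name__)

_BED_MAGIC = bytes((0x6C, 0x1B))
_MODE_VARIANT_MAJOR = 0x01

# PLINK 2-bit code -> dosage of allele A1: 00=hom A1 (2), 10=het (1),
# 11=hom A2 (0), 01=missing
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a .bed file violates the PLINK 1.9 binary layout."""


# ---------------------------------------------------------------------------
# PLINK binary trio
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None, recompute_a1: bool = True) -> GenotypeDataset:
    """Read a PLINK .bed/.bim/.fam trio into a :class:`GenotypeDataset`.

    ``bim_path``/``fam_path`` default to the .bed path with the extension
    swapped. Only variant-major (mode byte 0x01) files are supported;
    sample-major files are rejected rather than silently transposed.

    When ``recompute_a1`` (default) the counted allele is re-oriented to
    the in-sample minor allele after decoding.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "rsid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "rsid": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:2]!r}, expected 6c 1b"
        )
    if len(raw) < 3:
        raise PlinkFormatError(f"{bed_path}: truncated header")
    mode = raw[2]
    if mode == 0x00:
        raise PlinkFormatError(
            f"{bed_path}: sample-major (mode 0x00) .bed files are not supported"
        )
    if mode != _MODE_VARIANT_MAJOR:
        raise PlinkFormatError(f"{bed_path}: unknown mode byte {mode:#04x}")

    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: payload is {len(raw) - 3} bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit fields, least-significant pair = first sample in the byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes].T  # (n, m)

    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"].map(normalize_chrom),
            "pos": bim["pos"].astype(int),
            # .bim carries allele labels only; take A2 as ref, A1 as alt
            "ref": bim["a2"],
            "alt": bim["a1"],
            "rsid": bim["rsid"],
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    ds = GenotypeDataset(list(fam["iid"]), variants, np.ascontiguousarray(dosage))
    if recompute_a1:
        ds.recompute_minor_allele()
    return ds


def write_plink(ds: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write a dataset as a .bed/.bim/.fam trio; returns the three paths."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    n, m = ds.n_samples, ds.n_variants
    bytes_per_variant = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        lut[np.int8(dos).view(np.uint8)] = code
    codes = lut[ds.dosage.T.view(np.uint8)]  # (m, n)
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    # padding genotypes encode as 0b00 which is fine: readers ignore them
    padded[:, :n] = codes
    packed = (
        padded.reshape(m, bytes_per_variant, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint16).astype(np.uint8)

    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes((_MODE_VARIANT_MAJOR,)))
        fh.write(packed.tobytes())

    v = ds.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "rsid": v["rsid"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": ds.samples,
            "iid": ds.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, split_multiallelic: bool = False, recompute_a1: bool = True) -> GenotypeDataset:
    """Read a VCF (GT field only) into a :class:`GenotypeDataset`.

    Multi-allelic records raise by default; the alt allele is the counted
    allele unless it is the in-sample major allele, in which case the
    column is flipped so dosage counts the minor allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if split_multiallelic:
                raise NotImplementedError("multi-allelic splitting is not implemented")
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); normalize/split the VCF first"
            )
        # gts012: 0,1,2 = alt dosage, 3 = missing
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        rows.append(
            {
                "chrom": normalize_chrom(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "rsid": rec.ID if rec.ID else f"{normalize_chrom(rec.CHROM)}:{rec.POS}",
                "a1": rec.ALT[0],
                "a2": rec.REF,
            }
        )
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "rsid", "a1", "a2"])
    dosage = (
        np.column_stack(dosage_cols).astype(np.int8)
        if dosage_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    ds = GenotypeDataset(samples, variants, dosage)
    if recompute_a1:
        ds.recompute_minor_allele()
    return ds


def write_vcf(ds: GenotypeDataset, path) -> Path:
    """Write the dataset as minimal uncompressed VCF 4.2 (GT only).

    Genotypes are emitted as unphased alt-allele counts; the dosage
    matrix counts A1, so columns where A1 is the ref allele are flipped
    back to alt dosage on write.
    """
    path = Path(path)
    v = ds.variants
    alt_is_a1 = (v["a1"] == v["alt"]).to_numpy()
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: list[str] = []
        for c in v["chrom"]:
            if c not in seen:
                seen.append(c)
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for j, row in enumerate(v.itertuples()):
            col = ds.dosage[:, j]
            if not alt_is_a1[j]:
                miss = col == MISSING
                col = (2 - col).astype(np.int8)
                col[miss] = MISSING
            gts = "\t".join(gt_strings[int(x)] for x in col)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def read_phenotypes(path, id_col: str | None = None) -> pd.DataFrame:
    """Read a phenotype CSV (header row; first column = sample ID by default)."""
    df = pd.read_csv(path)
    if id_col is None:
        id_col = df.columns[0]
    df = df.rename(columns={id_col: "sample_id"})
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in phenotype file: {dups}")
    return df


def merge_pheno_geno(pheno: pd.DataFrame, geno: GenotypeDataset) -> AnalysisDataset:
    """Inner-join phenotypes and genotypes on sample ID.

    Samples present on only one side are dropped (and recorded on the
    returned object); zero overlap is a hard error. Retained order
    follows the phenotype file's row order.
    """
    geno_ids = set(geno.samples)
    pheno_ids = set(pheno["sample_id"])
    shared = [s for s in pheno["sample_id"] if s in geno_ids]
    if not shared:
        raise ValueError(
            f"no overlapping sample IDs: phenotype has {sorted(pheno_ids)[:5]}..., "
            f"genotypes have {sorted(geno_ids)[:5]}..."
        )
    dropped_pheno = sorted(pheno_ids - geno_ids)
    dropped_geno = sorted(geno_ids - pheno_ids)
    if dropped_pheno:
        warnings.warn(
            f"{len(dropped_pheno)} phenotype rows without genotypes dropped",
            stacklevel=2,
        )
    if dropped_geno:
        log.info("%d genotyped samples without phenotypes dropped", len(dropped_geno))
    pheno_kept = pheno[pheno["sample_id"].isin(geno_ids)].reset_index(drop=True)
    geno_kept = geno.subset_samples(list(pheno_kept["sample_id"]))
    return AnalysisDataset(pheno_kept, geno_kept, dropped_pheno, dropped_geno)


# ---------------------------------------------------------------------------
# SetID files
# ---------------------------------------------------------------------------

def read_setid(path) -> SetIdMap:
    """Read a two-column (set_id, variant_id) whitespace-delimited file.

    Duplicate (set, variant) lines are deduplicated with a warning.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 fields (set_id variant_id), "
                    f"got {len(fields)}: {line.strip()!r}"
                )
            pair = (fields[0], fields[1])
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    if n_dup:
        warnings.warn(f"{path}: {n_dup} duplicate (set, variant) lines ignored", stacklevel=2)
    return SetIdMap(pairs)


def write_setid(setid: SetIdMap, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for set_id, var_id in setid.pairs:
            fh.write(f"{set_id}\t{var_id}\n")
    return path


# ---------------------------------------------------------------------------
# Reference-population MAF table
# ---------------------------------------------------------------------------

def read_maf_reference(path) -> dict[VariantKey, float]:
    """Read a TSV with columns chr, pos, ref, alt, maf into a keyed lookup.

    Allele frequencies above 0.5 are folded to the minor-allele frequency
    with a warning; values outside [0, 1] and duplicate keys are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str, "ref": str, "alt": str})
    required = {"chr", "pos", "ref", "alt", "maf"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: MAF table needs columns {sorted(required)}")
    table: dict[VariantKey, float] = {}
    n_folded = 0
    for row in df.itertuples():
        maf = float(row.maf)
        if not 0.0 <= maf <= 1.0:
            raise ValueError(f"{path}: maf {maf} outside [0, 1] at {row.chr}:{row.pos}")
        if maf > 0.5:
            maf = 1.0 - maf
            n_folded += 1
        key = VariantKey(normalize_chrom(row.chr), int(row.pos), row.ref, row.alt)
        if key in table:
            raise ValueError(f"{path}: duplicate MAF entry for {key}")
        table[key] = maf
    if n_folded:
        warnings.warn(
            f"{path}: {n_folded} entries had frequency > 0.5 "
            "(allele frequency, not MAF, supplied) and were folded",
            stacklevel=2,
        )
    return table


def lookup_maf(table: Mapping[VariantKey, float], key: VariantKey) -> float | None:
    """Look up a variant's reference MAF, retrying with ref/alt swapped.

    Returns None when the variant is absent under both orientations;
    callers apply their fallback policy.
    """
    if key in table:
        return table[key]
    swapped = key.swapped()
    if swapped in table:
        return table[swapped]
    return None
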