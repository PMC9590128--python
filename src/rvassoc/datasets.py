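"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as minor-allele dosage matrices (samples x variants)
with entries in {0, 1, 2} and a dedicated missing sentinel (``MISSING``,
-1 in the int8 matrix). The counted allele A1 is always the in-sample
minor allele; readers re-orient dosages after load so downstream tests
never have to guess allele polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing genotype in the int8 dosage matrix
MISSING: int = -1

#: columns of the variant metadata frame carried by GenotypeDataset
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "rsid", "a1", "a2"]

_VALID_BASES = set("ACGT")


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr``, map M→MT."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in ("M", "m"):
        s = "MT"
    return s


@dataclass(frozen=True, order=True)
class VariantKey:
    """Exact (chrom, pos, ref, alt) identity of a biallelic variant.

    Positions are 1-based. Comparison/hash is exact on all four fields.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, both {self.ref!r}")

    def swapped(self) -> "VariantKey":
        return VariantKey(self.chrom, self.pos, self.alt, self.ref)


class GenotypeDataset:
    """Sample x variant minor-allele dosage matrix plus metadata.

    Parameters
    ----------
    samples:
        Ordered unique sample IDs.
    variants:
        DataFrame with columns ``chrom, pos, ref, alt, rsid, a1, a2``;
        ``a1`` is the counted (minor) allele of each dosage column.
    dosage:
        int8 matrix, shape (n_samples, n_variants), entries in
        {0, 1, 2, MISSING}.
    """

    def __init__(self, samples: Sequence[str], variants: pd.DataFrame, dosage: np.ndarray):
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("sample IDs must be unique")
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} != (n_samples={len(samples)}, n_variants={len(variants)})"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or the missing sentinel")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.samples = samples
        self.variants = variants.reset_index(drop=True).copy()
        self.variants["chrom"] = self.variants["chrom"].map(normalize_chrom)
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
            for row in self.variants.itertuples()
        ]

    def sample_maf(self) -> np.ndarray:
        """In-sample frequency of the counted allele A1 per variant.

        Missing entries are excluded; an all-missing column yields NaN.
        """
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def recompute_minor_allele(self) -> "GenotypeDataset":
        """Flip dosage columns so A1 is the in-sample minor allele.

        Ties (frequency exactly 0.5) keep the current orientation.
        Returns self (mutates in place).
        """
        freq = self.sample_maf()
        flip = freq > 0.5
        if flip.any():
            cols = np.where(flip)[0]
            sub = self.dosage[:, cols]
            miss = sub == MISSING
            sub = (2 - sub).astype(np.int8)
            sub[miss] = MISSING
            self.dosage[:, cols] = sub
            a1 = self.variants["a1"].to_numpy().copy()
            a2 = self.variants["a2"].to_numpy().copy()
            a1[cols], a2[cols] = a2[cols].copy(), a1[cols].copy()
            self.variants["a1"] = a1
            self.variants["a2"] = a2
        return self

    def subset_variants(self, idx: Iterable[int]) -> "GenotypeDataset":
        idx = list(idx)
        return GenotypeDataset(
            self.samples, self.variants.iloc[idx], self.dosage[:, idx].copy()
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeDataset":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        return GenotypeDataset(list(sample_ids), self.variants, self.dosage[rows, :].copy())

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.variants.reset_index(drop=True).equals(other.variants.reset_index(drop=True))
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class AnalysisDataset:
    """Inner join of a phenotype table with a genotype dataset.

    ``pheno`` rows and ``geno`` sample order both follow the phenotype
    file's row order for the retained (shared) samples.
    """

    pheno: pd.DataFrame
    geno: GenotypeDataset
    dropped_pheno: list[str] = field(default_factory=list)
    dropped_geno: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.pheno)


@dataclass
class SetIdMap:
    """Gene/unit membership of variants: ordered (set_id, variant_id) pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: dict[str, set] = {}
        for set_id, var_id in self.pairs:
            members = seen.setdefault(set_id, set())
            if var_id in members:
                raise ValueError(f"duplicate variant {var_id!r} in set {set_id!r}")
            members.add(var_id)

    @property
    def set_ids(self) -> list[str]:
        out, seen = [], set()
        for set_id, _ in self.pairs:
            if set_id not in seen:
                seen.add(set_id)
                out.append(set_id)
        return out

    def members(self, set_id: str) -> list[str]:
        return [v for s, v in self.pairs if s == set_id]

    def to_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, v in self.pairs:
            out.setdefault(s, []).append(v)
        return out
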