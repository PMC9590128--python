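"""SNP-to-gene mapping and gene-set over-representation analysis.

Filtered variants from the single-variant stage are assigned to genes by
interval overlap against a user-supplied annotation (BED or GTF), and
the resulting gene list is tested for over-representation in gene sets
(GMT collections) with the one-sided hypergeometric test, BH-adjusted
p-values and a Storey q-value estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .datasets import normalize_chrom


# ---------------------------------------------------------------------------
# Gene annotation ingest
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open on disk).

    Returns a frame with columns gene, chrom, start, end where start/end
    are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: gene BED needs at least 4 columns (chrom, start, end, name)")
    out = pd.DataFrame(
        {
            "gene": df.iloc[:, 3].astype(str),
            "chrom": df.iloc[:, 0].map(normalize_chrom),
            "start": df.iloc[:, 1].astype(int) + 1,  # 0-based -> 1-based
            "end": df.iloc[:, 2].astype(int),        # half-open end == inclusive end
        }
    )
    _check_intervals(out)
    return out


def read_gene_gtf(path, feature: str = "gene") -> pd.DataFrame:
    """Read gene intervals from a GTF (1-based inclusive on disk).

    The gene label is taken from the ``gene_name`` attribute, falling
    back to ``gene_id``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature:
                continue
            attrs = {}
            for item in fields[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            gene = attrs.get("gene_name") or attrs.get("gene_id")
            if gene is None:
                raise ValueError(f"{path}: {feature} record without gene_name/gene_id")
            rows.append({"gene": gene, "chrom": normalize_chrom(fields[0]),
                         "start": int(fields[3]), "end": int(fields[4])})
    out = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    _check_intervals(out)
    return out


def _check_intervals(df: pd.DataFrame) -> None:
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise ValueError(f"gene interval with start > end: {bad['gene']}")
    if df.duplicated(["gene", "chrom", "start", "end"]).any():
        raise ValueError("duplicate (gene, chrom, start, end) rows in annotation")


# ---------------------------------------------------------------------------
# Variant -> gene mapping
# ---------------------------------------------------------------------------

@dataclass
class GeneMap:
    """Result of mapping variants onto gene intervals."""

    mapped: pd.DataFrame    # columns SNP, Chr, Position, Ref, Alt, Gene
    unmapped: pd.DataFrame  # same minus Gene

    @property
    def genes(self) -> list[str]:
        return sorted(self.mapped["Gene"].unique())

    def to_setid_pairs(self) -> list[tuple[str, str]]:
        """(gene, variant) pairs for the gene-level association stage."""
        seen, pairs = set(), []
        for row in self.mapped.itertuples():
            pair = (row.Gene, row.SNP)
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
        return pairs


def map_snps_to_genes(variants: pd.DataFrame, intervals: pd.DataFrame, flank_bp: int = 0) -> GeneMap:
    """Assign each variant to every gene whose (flanked) interval contains it.

    ``variants`` needs columns chrom, pos, ref, alt, rsid; ``intervals``
    comes from :func:`read_gene_bed`/:func:`read_gene_gtf`. A variant in
    two overlapping genes yields two records; variants hitting no gene go
    to the ``unmapped`` frame. Chromosome labels are normalized on both
    sides so "chr1" and "1" agree.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for row in intervals.itertuples():
        chrom = normalize_chrom(row.chrom)
        lo = row.start - flank_bp
        hi = row.end + flank_bp
        # IntervalTree is half-open; store [lo, hi+1) to make hi inclusive
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi + 1, row.gene)

    mapped_rows, unmapped_rows = [], []
    for row in variants.itertuples():
        chrom = normalize_chrom(row.chrom)
        base = {"SNP": row.rsid, "Chr": chrom, "Position": int(row.pos),
                "Ref": row.ref, "Alt": row.alt}
        hits = trees[chrom][int(row.pos)] if chrom in trees else set()
        if hits:
            for iv in sorted(hits, key=lambda iv: (iv.begin, iv.end, iv.data)):
                mapped_rows.append({**base, "Gene": iv.data})
        else:
            unmapped_rows.append(base)
    mapped = pd.DataFrame(mapped_rows, columns=["SNP", "Chr", "Position", "Ref", "Alt", "Gene"])
    unmapped = pd.DataFrame(unmapped_rows, columns=["SNP", "Chr", "Position", "Ref", "Alt"])
    return GeneMap(mapped, unmapped)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT collection; duplicate members within a set are dropped."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 fields (name, description, members)"
                )
            name = fields[0]
            members, seen = [], set()
            for g in fields[2:]:
                if g and g not in seen:
                    seen.add(g)
                    members.append(g)
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def hypergeom_enrichment_p(k: int, n: int, M: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(overlap >= k) drawing n from N with M marked."""
    if not (0 < k <= n and 0 < M <= N and k <= M):
        raise ValueError(f"invalid ORA counts k={k}, n={n}, M={M}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def storey_qvalue(pvalues, lambdas=None) -> np.ndarray:
    """Storey q-values with pi0 estimated over a lambda grid (0.05..0.95).

    pi0 is taken from a cubic-spline smooth of pi0(lambda) evaluated at
    the largest lambda, clipped to (0, 1]. With few p-values the spline
    is skipped and pi0 falls back to min(1, 2 * mean(p)).
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if m < 30 or p.max() < lambdas.max():
        pi0 = min(1.0, 2.0 * float(p.mean()))
    else:
        pi0_l = np.array([(p > l).mean() / (1.0 - l) for l in lambdas])
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(lambdas, pi0_l)
        pi0 = float(spline(lambdas.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    return np.minimum(bh_adjust(p) * pi0, 1.0)


def ora_test(
    query_genes, gene_sets: dict[str, list[str]], universe=None,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Gene-set over-representation analysis of a query gene list.

    For each set, tests whether the overlap k between the query (size n,
    after intersection with the universe) and the set (size M within the
    universe of size N) exceeds chance, with the upper-tail
    hypergeometric probability. Output columns follow the conventional
    enrichment layout: ID, GeneRatio (k/n), BgRatio (M/N), pvalue,
    p.adjust (BH), qvalue (Storey), geneID ("/"-joined), Count.

    ``universe`` defaults to the union of all genes in the collection.
    """
    if universe is None:
        universe = set().union(*(set(m) for m in gene_sets.values())) if gene_sets else set()
    universe = set(universe)
    query = set(query_genes) & universe
    if not query:
        warnings.warn("no query genes in the universe; empty enrichment result", stacklevel=2)
        return pd.DataFrame(
            columns=["ID", "GeneRatio", "BgRatio", "pvalue", "p.adjust", "qvalue", "geneID", "Count"]
        )
    N, n = len(universe), len(query)
    rows = []
    for set_id, members in gene_sets.items():
        members_u = set(members) & universe
        M = len(members_u)
        overlap = sorted(query & members_u)
        k = len(overlap)
        if M == 0 or k < min_overlap:
            continue
        rows.append(
            {
                "ID": set_id,
                "GeneRatio": f"{k}/{n}",
                "BgRatio": f"{M}/{N}",
                "pvalue": hypergeom_enrichment_p(k, n, M, N),
                "geneID": "/".join(overlap),
                "Count": k,
            }
        )
    df = pd.DataFrame(rows, columns=["ID", "GeneRatio", "BgRatio", "pvalue", "geneID", "Count"])
    if len(df):
        df["p.adjust"] = bh_adjust(df["pvalue"].to_numpy())
        df["qvalue"] = storey_qvalue(df["pvalue"].to_numpy())
        df = df.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    else:
        df["p.adjust"] = []
        df["qvalue"] = []
    return df[["ID", "GeneRatio", "BgRatio", "pvalue", "p.adjust", "qvalue", "geneID", "Count"]]
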