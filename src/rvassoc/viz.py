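"""Plot functions for the pipeline's results.

Every plot writes two files: the figure itself (PNG/SVG by extension)
and a tidy CSV sidecar of the plotted coordinates, so numeric checks
run on data rather than pixels. Rendering is deterministic for fixed
input and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .datasets import MISSING, GenotypeDataset  # noqa: E402
from .single_variant import genomic_lambda  # noqa: E402

_CHROM_ORDER = [str(c) for c in range(1, 23)] + ["X", "Y", "MT"]


@dataclass
class PlotConfig:
    """Thresholds shared by the plot functions.

    ``sig_val``/``geno_val`` are -log10(p) lines on the Manhattan plot
    (3 -> p = 1e-3 suggestive, 5 -> p = 1e-5 genome-wide);
    ``ld_p_threshold`` selects variants for the LD panel; ``bar_pval``
    selects genes for the bar plot.
    """

    sig_val: float = 3.0
    geno_val: float = 5.0
    ld_p_threshold: float = 0.001
    bar_pval: float = 1e-4
    bar_width: float = 0.5
    bar_space: float = 1.0

    def __post_init__(self) -> None:
        if self.geno_val < self.sig_val:
            raise ValueError("geno_val must be >= sig_val")
        for name in ("ld_p_threshold", "bar_pval"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be a p-value in (0, 1]")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".csv")


def _chrom_sort_key(c: str) -> int:
    return _CHROM_ORDER.index(c) if c in _CHROM_ORDER else len(_CHROM_ORDER)


def manhattan(assoc: pd.DataFrame, path, cfg: PlotConfig = PlotConfig()) -> tuple[Path, Path]:
    """Manhattan plot: cumulative genomic position vs -log10(p).

    ``assoc`` needs columns CHR, BP, P (rows with missing P dropped).
    Returns (figure path, coordinates CSV path).
    """
    path = Path(path)
    df = assoc.dropna(subset=["P"]).copy()
    if df.empty:
        raise ValueError("no testable variants to plot")
    df["CHR"] = df["CHR"].astype(str)
    df["__order"] = df["CHR"].map(_chrom_sort_key)
    df = df.sort_values(["__order", "BP"], kind="mergesort")

    offset, xs, ticks = 0, [], {}
    for chrom, grp in df.groupby("CHR", sort=False):
        x = offset + grp["BP"].to_numpy()
        xs.append(x)
        ticks[chrom] = offset + (grp["BP"].min() + grp["BP"].max()) / 2
        offset = x.max() + 1
    df["x"] = np.concatenate(xs)
    df["neglog10p"] = -np.log10(df["P"])

    fig, ax = plt.subplots(figsize=(10, 4))
    for i, (chrom, grp) in enumerate(df.groupby("CHR", sort=False)):
        ax.scatter(grp["x"], grp["neglog10p"], s=8,
                   color="#4477aa" if i % 2 == 0 else "#88aacc")
    ax.axhline(cfg.sig_val, color="purple", lw=1, label=f"suggestive (1e-{cfg.sig_val:g})")
    ax.axhline(cfg.geno_val, color="red", lw=1, label=f"genome-wide (1e-{cfg.geno_val:g})")
    ax.set_xticks(list(ticks.values()))
    ax.set_xticklabels(list(ticks.keys()), fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    data = df[["CHR", "SNP", "BP", "P", "x", "neglog10p"]] if "SNP" in df else \
        df[["CHR", "BP", "P", "x", "neglog10p"]]
    data.to_csv(_sidecar(path), index=False)
    return path, _sidecar(path)


def qq_plot(assoc: pd.DataFrame, path, cfg: PlotConfig = PlotConfig()) -> tuple[Path, Path, float]:
    """Q-Q plot of observed vs expected -log10(p) with a lambda annotation.

    Expected quantiles use (i - 0.5)/n. Returns (figure path, CSV path,
    genomic inflation factor lambda).
    """
    path = Path(path)
    p = assoc["P"].dropna().to_numpy()
    lam = genomic_lambda(p)
    obs = np.sort(-np.log10(p))
    n = p.size
    exp = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(exp, obs, s=8, color="#4477aa")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    ax.annotate(f"$\\lambda$ = {lam:.4f}", xy=(0.05, 0.92), xycoords="axes fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    pd.DataFrame({"expected": exp, "observed": obs}).to_csv(_sidecar(path), index=False)
    return path, _sidecar(path), lam


def ld_r2_matrix(geno: GenotypeDataset, variant_idx) -> pd.DataFrame:
    """Pairwise r^2 (squared Pearson correlation of dosages, complete-case per pair)."""
    idx = list(variant_idx)
    rsids = [geno.variants["rsid"].iloc[j] for j in idx]
    k = len(idx)
    r2 = np.ones((k, k))
    D = geno.dosage[:, idx].astype(float)
    D[geno.dosage[:, idx] == MISSING] = np.nan
    for a in range(k):
        for b in range(a + 1, k):
            pair = D[:, [a, b]]
            keep = ~np.isnan(pair).any(axis=1)
            x, y = pair[keep, 0], pair[keep, 1]
            if x.size < 2 or x.std() == 0 or y.std() == 0:
                val = np.nan
            else:
                val = float(np.corrcoef(x, y)[0, 1]) ** 2
            r2[a, b] = r2[b, a] = val
    return pd.DataFrame(r2, index=rsids, columns=rsids)


def ld_heatmap(
    geno: GenotypeDataset, assoc: pd.DataFrame, path, cfg: PlotConfig = PlotConfig()
) -> tuple[Path, Path]:
    """LD heatmap of the variants passing the plot's p-value threshold.

    r^2 is the PLINK-style squared genotype correlation. At least two
    variants must pass ``cfg.ld_p_threshold``.
    """
    path = Path(path)
    qualifying = assoc.dropna(subset=["P"])
    qualifying = qualifying[qualifying["P"] < cfg.ld_p_threshold]
    snps = set(qualifying["SNP"])
    idx = [j for j, rsid in enumerate(geno.variants["rsid"]) if rsid in snps]
    if len(idx) < 2:
        raise ValueError(
            f"need >= 2 variants with p < {cfg.ld_p_threshold} for an LD panel, got {len(idx)}"
        )
    # genomic order
    v = geno.variants.iloc[idx]
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].map(_chrom_sort_key).to_numpy()))
    idx = [idx[i] for i in order]
    r2 = ld_r2_matrix(geno, idx)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(r2.to_numpy(), cmap="Reds", vmin=0, vmax=1)
    ax.set_xticks(range(len(r2)))
    ax.set_yticks(range(len(r2)))
    ax.set_xticklabels(r2.columns, rotation=90, fontsize=6)
    ax.set_yticklabels(r2.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=r"$r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    r2.to_csv(_sidecar(path))
    return path, _sidecar(path)


def gene_bar(skat_result: pd.DataFrame, path, cfg: PlotConfig = PlotConfig()) -> tuple[Path, Path]:
    """Bar plot of -log10(p) for genes passing the significance cutoff."""
    import warnings as _warnings

    path = Path(path)
    df = skat_result.dropna(subset=["P.value"])
    df = df[df["P.value"] < cfg.bar_pval].copy()
    if df.empty:
        _warnings.warn(f"no genes with p < {cfg.bar_pval}; writing an empty plot", stacklevel=2)
    df["neglog10p"] = -np.log10(df["P.value"]) if len(df) else []

    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(df)), 4))
    x = np.arange(len(df)) * (cfg.bar_width + cfg.bar_space)
    ax.bar(x, df["neglog10p"], width=cfg.bar_width, color="#4477aa")
    ax.set_xticks(x)
    ax.set_xticklabels(df["SetID"], rotation=45, ha="right", fontsize=8)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    df[["SetID", "P.value", "neglog10p"]].to_csv(_sidecar(path), index=False)
    return path, _sidecar(path)
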