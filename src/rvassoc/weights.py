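"""Per-variant collapsing weights from reference-population MAFs.

Rare variants carry individually small signals; gene-level kernel tests
up-weight them before aggregation. Deriving the weights from the study
sample itself introduces selection bias, so the weights here come from
an external healthy reference population's minor-allele frequencies.

The primary scheme is a logistic function of the reference MAF,

    w(maf) = sigmoid(-(maf - W1) * W2)

with defaults W1 = 0.07 (MAF units; the half-weight point) and W2 = 150
(dimensionless slope). Variants rarer than W1 get weight near 1, common
variants near 0, and w(W1) = 0.5 exactly. The Beta(1, 25) density weight
used by default in kernel association testing is provided as an
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datasets import VariantKey
from .genio import lookup_maf


@dataclass(frozen=True)
class WeightParams:
    """Logistic weight parameters: W1 = half-weight MAF, W2 = slope."""

    w1: float = 0.07
    w2: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 0.5:
            raise ValueError(f"W1 must be in [0, 0.5], got {self.w1}")
        if self.w2 <= 0:
            raise ValueError(f"W2 must be positive, got {self.w2}")


def logistic_weight(maf, params: WeightParams = WeightParams()) -> np.ndarray | float:
    """Logistic collapsing weight exp(-x1)/(1+exp(-x1)), x1 = (maf-W1)*W2.

    Evaluated through a numerically stable sigmoid, so extreme x1 maps
    to exactly 0.0/1.0 at double precision instead of overflowing.
    MAFs must already be folded into [0, 0.5].
    """
    m = np.asarray(maf, dtype=float)
    if np.any((m < 0) | (m > 0.5)):
        raise ValueError("maf must lie in [0, 0.5]; fold allele frequencies first")
    w = expit(-(m - params.w1) * params.w2)
    return float(w) if np.isscalar(maf) else w


def invert_logistic_weight(weight, params: WeightParams = WeightParams()) -> np.ndarray | float:
    """Recover the MAF from a logistic weight: W1 - ln(w/(1-w))/W2."""
    w = np.asarray(weight, dtype=float)
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("weight must lie strictly in (0, 1) to invert")
    m = params.w1 - np.log(w / (1.0 - w)) / params.w2
    return float(m) if np.isscalar(weight) else m


def beta_weight(maf, a: float = 1.0, b: float = 25.0) -> np.ndarray | float:
    """Beta(a, b) density evaluated at the MAF (the kernel-test default).

    With the default Beta(1, 25), w(maf) = 25 * (1 - maf)^24, strongly
    favouring rare variants. a = b = 1 gives flat (unweighted) analysis.
    """
    m = np.asarray(maf, dtype=float)
    if np.any((m < 0) | (m > 0.5)):
        raise ValueError("maf must lie in [0, 0.5]")
    if a < 1 and np.any(m == 0):
        raise ValueError("maf = 0 is not evaluable for a < 1 (density diverges)")
    w = stats.beta.pdf(m, a, b)
    return float(w) if np.isscalar(maf) else w


FALLBACK_POLICIES = ("sample_maf", "exclude", "unit_weight")


def get_logistic_weights_maf_pop(
    variants: pd.DataFrame,
    maf_table: Mapping[VariantKey, float],
    params: WeightParams = WeightParams(),
    fallback_policy: str = "sample_maf",
    sample_maf: Mapping[str, float] | None = None,
    scheme: str = "logistic",
) -> pd.DataFrame:
    """Look up each variant's reference MAF and compute its weight.

    ``variants`` needs columns chrom, pos, ref, alt (rsid optional).
    Lookup first matches (chrom, pos, ref, alt) exactly, then retries
    with ref/alt swapped (allele orientation differs across population
    resources). Variants absent under both orientations follow
    ``fallback_policy``:

    - ``sample_maf`` (default): use the in-sample MAF supplied via the
      ``sample_maf`` mapping (rsid -> MAF), with a warning;
    - ``exclude``: drop the variant from the output;
    - ``unit_weight``: keep it with weight 1.0.

    Returns a frame with columns chr, pos, ref, alt, snp, maf, weight,
    source — sorted by weight descending.
    """
    if fallback_policy not in FALLBACK_POLICIES:
        raise ValueError(f"fallback_policy must be one of {FALLBACK_POLICIES}")
    if scheme not in ("logistic", "beta"):
        raise ValueError(f"scheme must be 'logistic' or 'beta', got {scheme!r}")
    if len(variants) == 0:
        raise ValueError("empty variant list")

    weight_fn = (lambda m: logistic_weight(m, params)) if scheme == "logistic" else beta_weight
    rows = []
    n_fallback = 0
    for row in variants.itertuples():
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        rsid = getattr(row, "rsid", f"{key.chrom}:{key.pos}")
        maf = lookup_maf(maf_table, key)
        source = "reference"
        if maf is None:
            n_fallback += 1
            if fallback_policy == "exclude":
                continue
            if fallback_policy == "unit_weight":
                rows.append({"chr": key.chrom, "pos": key.pos, "ref": key.ref,
                             "alt": key.alt, "snp": rsid, "maf": np.nan,
                             "weight": 1.0, "source": "fallback:unit"})
                continue
            if sample_maf is None or rsid not in sample_maf:
                raise ValueError(
                    f"variant {rsid} absent from reference and no in-sample MAF supplied"
                )
            maf = float(sample_maf[rsid])
            source = "fallback:sample_maf"
        rows.append({"chr": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
                     "snp": rsid, "maf": maf, "weight": float(weight_fn(maf)),
                     "source": source})
    if n_fallback:
        warnings.warn(
            f"{n_fallback} variants missing from the reference MAF table "
            f"(policy: {fallback_policy})",
            stacklevel=2,
        )
    out = pd.DataFrame(rows, columns=["chr", "pos", "ref", "alt", "snp", "maf", "weight", "source"])
    return out.sort_values("weight", ascending=False, kind="mergesort").reset_index(drop=True)
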