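"""Stage 3: logistic collapsing weights from a reference-population MAF table.

Computes the logistic weight w = sigmoid(-(MAF - W1) * W2) for a spread
of reference MAFs and shows how rare variants receive weight near 1
while common variants are down-weighted to near 0.
"""

import numpy as np
import pandas as pd

from rvassoc import WeightParams, get_logistic_weights_maf_pop, logistic_weight
from rvassoc.datasets import VariantKey

mafs = [0.001, 0.01, 0.05, 0.07, 0.10, 0.20, 0.40]
print("reference MAF -> logistic weight (W1=0.07, W2=150):")
for m in mafs:
    print(f"  {m:6.3f} -> {logistic_weight(m):.6f}")
print("the half-weight point sits exactly at MAF = W1 = 0.07\n")

variants = pd.DataFrame({
    "chrom": ["1"] * 7, "pos": range(100, 107),
    "ref": ["A"] * 7, "alt": ["G"] * 7,
    "rsid": [f"rs{i}" for i in range(7)],
})
ref_table = {VariantKey("1", 100 + i, "A", "G"): m for i, m in enumerate(mafs)}
wtab = get_logistic_weights_maf_pop(variants, ref_table,
                                    WeightParams(w1=0.07, w2=150.0))
print("per-variant weight table (sorted by weight, rare variants first):")
print(wtab[["chr", "pos", "snp", "maf", "weight"]].to_string(index=False))
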