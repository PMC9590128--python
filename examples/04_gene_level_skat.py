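"""Stage 4: gene-level variance-component (SKAT) association test.

Simulates two genes — one carrying risk variants, one null — and runs
the weighted-kernel score test for each, printing the standard
four-column result (SetID, P.value, N.Marker.All, N.Marker.Test).
"""

import warnings

import numpy as np

from rvassoc import SetIdMap, skat_assoc
from rvassoc.datasets import GenotypeDataset
import pandas as pd

rng = np.random.default_rng(7)
n, m = 400, 12
maf = rng.uniform(0.01, 0.1, m)  # low-frequency variants: where the test shines
dosage = rng.binomial(2, maf, size=(n, m)).astype(np.int8)

# first six variants form GENE_RISK and raise disease odds; the other six
# form GENE_NULL with no effect
eta = -0.4 + dosage[:, :6].astype(float) @ np.full(6, 0.8)
y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))

variants = pd.DataFrame({
    "chrom": ["1"] * m, "pos": np.arange(1, m + 1) * 500,
    "ref": ["A"] * m, "alt": ["G"] * m,
    "rsid": [f"rs{j}" for j in range(m)],
    "a1": ["G"] * m, "a2": ["A"] * m,
})
geno = GenotypeDataset([f"S{i}" for i in range(n)], variants, dosage)
setid = SetIdMap([("GENE_RISK", f"rs{j}") for j in range(6)]
                 + [("GENE_NULL", f"rs{j}") for j in range(6, 12)])

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = skat_assoc(geno, setid, y, out_type="D")

print(result[["SetID", "P.value", "N.Marker.All", "N.Marker.Test"]]
      .to_string(index=False))
print("\nP.value is the tail probability of the weighted-kernel score")
print("statistic under its chi-square-mixture null distribution; the risk")
print("gene should fall far below the null gene. N.Marker.All counts set")
print("members found in the genotypes, N.Marker.Test those surviving QC.")
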