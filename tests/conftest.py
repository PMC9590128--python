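import warnings

import numpy as np
import pandas as pd
import pytest

from rvassoc.datasets import GenotypeDataset
from rvassoc.genio import merge_pheno_geno
from rvassoc.simdata import SimSpec, make_fixture_suite, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Small coherent file bundle: PLINK trio + VCF + phenotypes + annotation."""
    outdir = tmp_path_factory.mktemp("suite")
    spec = SimSpec(n=120, m=60, genes=12, seed=11, missing_rate=0.02)
    paths = make_fixture_suite(outdir, spec)
    return spec, paths


@pytest.fixture()
def null_binary_ds():
    """Merged dataset with a null binary outcome and sex/age covariates."""
    spec = SimSpec(n=150, m=40, genes=8, seed=23, outcome="null", missing_rate=0.02)
    geno = simulate_genotypes(spec)
    pheno = simulate_phenotypes(geno, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return merge_pheno_geno(pheno, geno)


def make_dataset(dosage, samples=None, chrom="1"):
    """Wrap a raw dosage matrix in a GenotypeDataset with synthetic metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if samples is None:
        samples = [f"S{i+1}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "rsid": [f"rs{j+1}" for j in range(m)],
            "a1": ["G"] * m,
            "a2": ["A"] * m,
        }
    )
    return GenotypeDataset(samples, variants, dosage)
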