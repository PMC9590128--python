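"""Per-variant association tests against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rvassoc.datasets import MISSING, GenotypeDataset
from rvassoc.genio import merge_pheno_geno
from rvassoc.single_variant import (
    chisq_allelic,
    encode_model,
    fisher_exact_allelic,
    functional_analysis,
    genomic_lambda,
    linear_scan,
    logistic_scan,
    survival_scan,
    trend_test,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_enumeration(tab):
    """Exact two-sided p by full enumeration of tables with fixed margins,
    summing hypergeometric probabilities <= that of the observed table."""
    a, b = tab[0]
    c, d = tab[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def chisq_longhand(tab):
    tab = np.asarray(tab, dtype=float)
    total = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    return float(((tab - expected) ** 2 / expected).sum())


def trend_chisq_textbook(n_cases, n_ctrls):
    """Armitage trend chi-square in its closed ratio form with scores 0,1,2."""
    r = np.asarray(n_cases, dtype=float)
    s = np.asarray(n_ctrls, dtype=float)
    n = r + s
    N, R = n.sum(), r.sum()
    t = np.array([0.0, 1.0, 2.0])
    num = N * (N * np.sum(t * r) - R * np.sum(t * n)) ** 2
    den = R * (N - R) * (N * np.sum(t**2 * n) - np.sum(t * n) ** 2)
    return num / den


def irls_logistic(y, X, tol=1e-10, maxiter=50):
    """Hand-rolled IRLS for logistic regression: returns (beta, se)."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        score = X.T @ (y - mu)
        info = X.T @ (X * W[:, None])
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(score)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (mu * (1 - mu))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


class FakeVariant:
    chrom, rsid, pos, a1 = "1", "rsX", 100, "G"


def _dataset_from_tables(dos, y):
    """AnalysisDataset with one variant column = dos and outcome y."""
    dosage = np.asarray(dos, dtype=np.int8)[:, None]
    ds = make_dataset(dosage)
    pheno = pd.DataFrame({"sample_id": ds.samples, "outcome": y})
    return merge_pheno_geno(pheno, ds)


# ---------------------------------------------------------------------------
# Genetic model coding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "model,expected",
    [("add", [0, 1, 2]), ("dom", [0, 1, 1]), ("rec", [0, 0, 1])],
)
def test_encode_model(model, expected):
    assert encode_model(np.array([0, 1, 2]), model).tolist() == expected


def test_encode_model_missing_passthrough():
    out = encode_model(np.array([2, MISSING, 0]), "add")
    assert out.tolist() == [2, MISSING, 0]
    out = encode_model(np.array([2, MISSING, 0]), "rec")
    assert out.tolist() == [1, MISSING, 0]


def test_encode_model_unknown_rejected():
    with pytest.raises(ValueError):
        encode_model(np.array([0]), "codominant")


# ---------------------------------------------------------------------------
# Fisher / chi-square on allele tables
# ---------------------------------------------------------------------------

def test_fisher_diagonal_table():
    # cases all hom A1, controls all hom other: allele table [[5,0],[0,5]]
    dos = np.array([2, 2, 2, 0, 0, 0], dtype=np.int8)
    # 3 cases contribute 6 A1 alleles... build the exact [[5,0],[0,5]] table
    # via a direct call on the oracle instead, and check the module against
    # scipy's convention on a genotype-built table below
    assert fisher_two_sided_enumeration([[5, 0], [0, 5]]) == pytest.approx(2 / 252)


@pytest.mark.parametrize("seed", range(6))
def test_fisher_matches_enumeration_on_genotype_tables(seed):
    rng = np.random.default_rng(seed)
    n = 10
    dos = rng.integers(0, 3, n).astype(np.int8)
    y = rng.integers(0, 2, n)
    if len(np.unique(y)) < 2:
        y[0] = 1 - y[0]
    rec = fisher_exact_allelic(dos, y, FakeVariant)
    case_a1 = int(dos[y == 1].sum())
    ctrl_a1 = int(dos[y == 0].sum())
    tab = [[case_a1, 2 * int((y == 1).sum()) - case_a1],
           [ctrl_a1, 2 * int((y == 0).sum()) - ctrl_a1]]
    assert rec["P"] == pytest.approx(fisher_two_sided_enumeration(tab), rel=1e-9)


def test_fisher_symmetric_counts_p_one():
    dos = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
    y = np.array([1, 1, 1, 0, 0, 0])
    rec = fisher_exact_allelic(dos, y, FakeVariant)
    assert rec["P"] == pytest.approx(1.0)
    assert rec["NMISS"] == 6


def test_chisq_longhand_agreement():
    rng = np.random.default_rng(3)
    for _ in range(5):
        dos = rng.integers(0, 3, 40).astype(np.int8)
        y = rng.integers(0, 2, 40)
        rec = chisq_allelic(dos, y, FakeVariant)
        case_a1 = int(dos[y == 1].sum())
        ctrl_a1 = int(dos[y == 0].sum())
        tab = [[case_a1, 2 * int((y == 1).sum()) - case_a1],
               [ctrl_a1, 2 * int((y == 0).sum()) - ctrl_a1]]
        assert rec["STAT"] == pytest.approx(chisq_longhand(tab), rel=1e-10)
        assert rec["P"] == pytest.approx(stats.chi2.sf(rec["STAT"], 1))


def test_chisq_extreme_diagonal_table_statistic():
    # [[20,0],[0,20]]: E=10 everywhere, stat = 4*10^2/10 = 40
    assert chisq_longhand([[20, 0], [0, 20]]) == pytest.approx(40.0)
    dos = np.concatenate([np.full(10, 2), np.zeros(10)]).astype(np.int8)
    y = np.concatenate([np.ones(10, int), np.zeros(10, int)])
    rec = chisq_allelic(dos, y, FakeVariant)
    assert rec["STAT"] == pytest.approx(40.0)


def test_chisq_balanced_table_p_one():
    dos = np.array([1, 1, 1, 1], dtype=np.int8)
    y = np.array([1, 1, 0, 0])
    rec = chisq_allelic(dos, y, FakeVariant)
    assert rec["STAT"] == pytest.approx(0.0)
    assert rec["P"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Cochran-Armitage trend
# ---------------------------------------------------------------------------

def test_trend_identical_distributions_stat_zero():
    dos = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
    y = np.array([1, 1, 1, 0, 0, 0])
    rec = trend_test(dos, y, FakeVariant)
    assert rec["STAT"] == pytest.approx(0.0, abs=1e-12)
    assert rec["P"] == pytest.approx(1.0)


def test_trend_matches_textbook_ratio_form():
    # cases genotype counts (1,2,7), controls (7,2,1)
    dos = np.array([0] + [1] * 2 + [2] * 7 + [0] * 7 + [1] * 2 + [2], dtype=np.int8)
    y = np.array([1] * 10 + [0] * 10)
    rec = trend_test(dos, y, FakeVariant)
    expected = trend_chisq_textbook([1, 2, 7], [7, 2, 1])
    assert rec["STAT"] == pytest.approx(expected, rel=1e-10)


def test_trend_label_swap_invariance():
    rng = np.random.default_rng(9)
    dos = rng.integers(0, 3, 50).astype(np.int8)
    y = rng.integers(0, 2, 50)
    p1 = trend_test(dos, y, FakeVariant)["P"]
    p2 = trend_test(dos, 1 - y, FakeVariant)["P"]
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_trend_monomorphic_skipped():
    rec = trend_test(np.zeros(10, dtype=np.int8), np.array([0, 1] * 5), FakeVariant)
    assert rec["SKIP_REASON"] == "monomorphic"
    assert np.isnan(rec["P"])


# ---------------------------------------------------------------------------
# Logistic / linear scans
# ---------------------------------------------------------------------------

def test_logistic_matches_hand_irls():
    rng = np.random.default_rng(12)
    n = 80
    g = rng.integers(0, 3, n).astype(np.int8)
    y = rng.binomial(1, 1 / (1 + np.exp(-(-0.3 + 0.5 * g))))
    ds = _dataset_from_tables(g, y)
    table = logistic_scan(ds, "outcome").table
    X = np.column_stack([np.ones(n), g.astype(float)])
    beta, se = irls_logistic(y.astype(float), X)
    assert np.log(table.loc[0, "OR"]) == pytest.approx(beta[1], abs=1e-7)
    assert table.loc[0, "STAT"] == pytest.approx(beta[1] / se[1], abs=1e-6)


def test_logistic_stat_p_consistency():
    rng = np.random.default_rng(4)
    dosage = rng.integers(0, 3, size=(100, 5)).astype(np.int8)
    ds = make_dataset(dosage)
    pheno = pd.DataFrame({"sample_id": ds.samples, "outcome": rng.integers(0, 2, 100)})
    merged = merge_pheno_geno(pheno, ds)
    table = logistic_scan(merged, "outcome").tested
    implied = 2 * stats.norm.sf(np.abs(table["STAT"]))
    assert np.max(np.abs(implied - table["P"])) < 1e-12


def test_logistic_constant_genotype_skipped():
    ds = _dataset_from_tables(np.ones(20, dtype=np.int8), np.array([0, 1] * 10))
    table = logistic_scan(ds, "outcome").table
    assert table.loc[0, "SKIP_REASON"] == "no genotype variance"


def test_linear_matches_normal_equations():
    rng = np.random.default_rng(7)
    n = 10
    g = rng.integers(0, 3, n).astype(np.int8)
    y = 1.0 + 0.8 * g + rng.normal(0, 0.5, n)
    ds = make_dataset(g[:, None])
    pheno = pd.DataFrame({"sample_id": ds.samples, "y": y})
    merged = merge_pheno_geno(pheno, ds)
    table = linear_scan(merged, "y").table
    X = np.column_stack([np.ones(n), g.astype(float)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - 2)
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    assert table.loc[0, "BETA"] == pytest.approx(beta[1], rel=1e-10)
    assert table.loc[0, "STAT"] == pytest.approx(t, rel=1e-10)
    assert table.loc[0, "P"] == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-10)


def test_linear_exact_fit_and_affine_invariance():
    g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=np.int8)
    ds = make_dataset(g[:, None])
    pheno = pd.DataFrame({"sample_id": ds.samples, "y": 2.0 * g})
    merged = merge_pheno_geno(pheno, ds)
    row = linear_scan(merged, "y").table.loc[0]
    assert row["BETA"] == pytest.approx(2.0)
    assert row["P"] <= 1e-50  # numerically 0-adjacent at this sample size

    rng = np.random.default_rng(2)
    y = 2.0 * g + rng.normal(0, 1, g.size)
    pheno["y"] = y
    r1 = linear_scan(merge_pheno_geno(pheno, ds), "y").table.loc[0]
    pheno["y"] = y + 100.0
    r2 = linear_scan(merge_pheno_geno(pheno, ds), "y").table.loc[0]
    assert r1["BETA"] == pytest.approx(r2["BETA"], rel=1e-9)
    assert r1["P"] == pytest.approx(r2["P"], rel=1e-9)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def _surv_dataset(g, time, event):
    ds = make_dataset(np.asarray(g, dtype=np.int8)[:, None])
    pheno = pd.DataFrame({"sample_id": ds.samples, "time": time, "event": event})
    return merge_pheno_geno(pheno, ds)


def test_survival_all_censored_skipped():
    rng = np.random.default_rng(1)
    n = 30
    merged = _surv_dataset(rng.integers(0, 3, n), rng.exponential(1, n), np.zeros(n, int))
    table = survival_scan(merged, "time", "event", "dom", "logrank").table
    assert table.loc[0, "SKIP_REASON"] == "no events"


def test_coxph_effect_direction():
    rng = np.random.default_rng(8)
    n = 200
    g = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / np.exp(1.0 * g))
    merged = _surv_dataset(g, t, np.ones(n, int))
    row = survival_scan(merged, "time", "event", "add", "coxph").table.loc[0]
    assert row["HR"] > 1.5  # strong positive hazard effect recovered
    assert row["P"] < 0.01


def test_logrank_null_is_not_significant_typically():
    rng = np.random.default_rng(3)
    n = 120
    g = rng.integers(0, 3, n)
    t = rng.exponential(1.0, n)
    e = (rng.random(n) < 0.8).astype(int)
    row = survival_scan(_surv_dataset(g, t, e), "time", "event", "add", "logrank").table.loc[0]
    assert 0 < row["P"] <= 1


# ---------------------------------------------------------------------------
# Dispatch + filtering
# ---------------------------------------------------------------------------

def test_functional_analysis_schema_and_threshold(null_binary_ds):
    assoc = functional_analysis(null_binary_ds, "glm", "outcome", "add",
                                ["sex", "age"], threshold=0.05)
    assert list(assoc.table.columns[:9]) == [
        "CHR", "SNP", "BP", "A1", "TEST", "NMISS", "OR", "STAT", "P"]
    assert (assoc.table["TEST"].dropna() == "ADD").all()
    assert (assoc.tested["NMISS"] <= null_binary_ds.n_samples).all()
    assert (assoc.filtered["P"] < 0.05).all()

    assoc.threshold = 1.0
    assert len(assoc.filtered) == len(assoc.tested)
    assoc.threshold = 0.0
    assert len(assoc.filtered) == 0


def test_functional_analysis_bad_method(null_binary_ds):
    with pytest.raises(ValueError, match="method"):
        functional_analysis(null_binary_ds, "anova", "outcome")


def test_functional_analysis_survival_needs_columns(null_binary_ds):
    with pytest.raises(ValueError, match="time_col"):
        functional_analysis(null_binary_ds, "coxph", "outcome")


def test_pvalues_invariant_under_sample_reordering(null_binary_ds):
    assoc1 = functional_analysis(null_binary_ds, "trend", "outcome")
    perm = null_binary_ds.pheno.sample(frac=1.0, random_state=0)
    ds2 = merge_pheno_geno(perm, null_binary_ds.geno)
    assoc2 = functional_analysis(ds2, "trend", "outcome")
    np.testing.assert_allclose(
        assoc1.tested["P"].to_numpy(), assoc2.tested["P"].to_numpy(), rtol=1e-12
    )


# ---------------------------------------------------------------------------
# Genomic inflation factor
# ---------------------------------------------------------------------------

def test_lambda_definitional_point():
    assert genomic_lambda([0.5] * 7) == pytest.approx(1.0)


def test_lambda_uniform_null_near_one():
    rng = np.random.default_rng(42)
    p = rng.uniform(0, 1, 10_000)
    assert 0.95 <= genomic_lambda(p) <= 1.05


def test_lambda_scale_equivariance():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.01, 1, 500)
    chi = stats.chi2.isf(p, 1)
    p_doubled = stats.chi2.sf(2 * chi, 1)
    assert genomic_lambda(p_doubled) == pytest.approx(2 * genomic_lambda(p), rel=1e-9)


def test_lambda_rejects_empty_and_invalid():
    with pytest.raises(ValueError):
        genomic_lambda([])
    with pytest.raises(ValueError):
        genomic_lambda([0.0, 0.5])
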