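"""Per-variant association tests between genotype and clinical outcome.

This is the pre-filtering stage of the pipeline: every variant is tested
individually against the outcome under a chosen genetic model, and the
variants below a p-value threshold (default 0.05) are carried forward to
gene-level analysis. Supported tests:

===========  ==========================================  ==============
method       test                                        outcome
===========  ==========================================  ==============
fisher       Fisher's exact test on 2x2 allele counts    binary
chisq        Pearson chi-square on 2x2 allele counts     binary
trend        Cochran-Armitage trend test                 binary
glm          logistic regression (Wald)                  binary
lm           linear regression (t)                       continuous
survfit      log-rank test across genotype groups        survival
coxph        Cox proportional hazards (Wald)             survival
===========  ==========================================  ==============

Allelic tests (fisher/chisq) treat each non-missing genotype as two
independent alleles (Hardy-Weinberg assumption). Missingness is handled
per variant by complete-case analysis; NMISS is the number of samples
with a non-missing genotype that entered the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MISSING, AnalysisDataset

MODELS = ("add", "dom", "rec")
METHODS = ("fisher", "chisq", "trend", "glm", "lm", "survfit", "coxph")

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_EFFECT_LABEL = {
    "fisher": "OR", "chisq": "OR", "trend": "OR",
    "glm": "OR", "lm": "BETA", "survfit": "HR", "coxph": "HR",
}


@dataclass
class AssocTable:
    """Per-variant association results plus the filtering threshold.

    ``table`` carries one row per variant with columns
    CHR, SNP, BP, A1, TEST, NMISS, <effect>, STAT, P, SKIP_REASON
    where <effect> is OR, BETA or HR depending on the test.
    """

    table: pd.DataFrame
    threshold: float = 0.05
    effect_label: str = "OR"
    method: str = "glm"

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["P"].notna()]

    @property
    def filtered(self) -> pd.DataFrame:
        """Variants with P below the significance threshold."""
        t = self.tested
        return t[t["P"] < self.threshold]

    def to_csv(self, path) -> None:
        cols = ["CHR", "SNP", "BP", "A1", "TEST", "NMISS", self.effect_label, "STAT", "P"]
        self.table[cols].to_csv(path, index=False)


def encode_model(dosages: np.ndarray, model: str) -> np.ndarray:
    """Recode A1 dosages under a genetic model; missing entries pass through.

    add -> 0/1/2 copies; dom -> any copy = 1; rec -> two copies = 1.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    d = np.asarray(dosages, dtype=np.int8).copy()
    miss = d == MISSING
    if model == "dom":
        d = np.where(d >= 1, 1, 0).astype(np.int8)
    elif model == "rec":
        d = np.where(d == 2, 1, 0).astype(np.int8)
    d[miss] = MISSING
    return d


def _binary_outcome(ds: AnalysisDataset, outcome: str) -> np.ndarray:
    y = ds.pheno[outcome].to_numpy()
    vals = set(np.unique(y).tolist())
    if not vals <= {0, 1}:
        raise ValueError(f"binary outcome {outcome!r} takes values {sorted(vals)}, expected {{0,1}}")
    return y.astype(int)


def _allele_table(dos: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """2x2 allele-count table [[case A1, case other], [ctrl A1, ctrl other]]."""
    keep = dos != MISSING
    d, yy = dos[keep].astype(int), y[keep]
    case_a1 = int(d[yy == 1].sum())
    case_tot = 2 * int((yy == 1).sum())
    ctrl_a1 = int(d[yy == 0].sum())
    ctrl_tot = 2 * int((yy == 0).sum())
    tab = np.array([[case_a1, case_tot - case_a1], [ctrl_a1, ctrl_tot - ctrl_a1]])
    return tab, int(keep.sum())


def _odds_ratio(tab: np.ndarray) -> float:
    """Sample OR; Haldane-Anscombe +0.5 applied only when a cell is zero."""
    t = tab.astype(float)
    if (t == 0).any():
        t = t + 0.5
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def _record(variant, test, nmiss, effect, stat, p, skip=None) -> dict:
    return {
        "CHR": variant.chrom, "SNP": variant.rsid, "BP": int(variant.pos),
        "A1": variant.a1, "TEST": test, "NMISS": nmiss,
        "EFFECT": effect, "STAT": stat, "P": p, "SKIP_REASON": skip,
    }


def fisher_exact_allelic(dos: np.ndarray, y: np.ndarray, variant) -> dict:
    """Two-sided Fisher exact test on the 2x2 allele-count table.

    Two-sidedness follows the point-probability rule (sum of all tables
    with fixed margins whose probability does not exceed the observed).
    """
    tab, nmiss = _allele_table(dos, y)
    if nmiss == 0:
        return _record(variant, "ALLELIC", 0, np.nan, np.nan, np.nan, "all genotypes missing")
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return _record(variant, "ALLELIC", nmiss, _odds_ratio(tab), np.nan, float(p))


def chisq_allelic(dos: np.ndarray, y: np.ndarray, variant) -> dict:
    """Pearson chi-square (df=1, no continuity correction) on allele counts."""
    tab, nmiss = _allele_table(dos, y)
    if nmiss == 0:
        return _record(variant, "ALLELIC", 0, np.nan, np.nan, np.nan, "all genotypes missing")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return _record(variant, "ALLELIC", nmiss, np.nan, np.nan, np.nan, "zero margin")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return _record(variant, "ALLELIC", nmiss, _odds_ratio(tab), float(chi2), float(p))


def trend_test(dos: np.ndarray, y: np.ndarray, variant) -> dict:
    """Cochran-Armitage trend test with scores (0, 1, 2).

    Score-test form: T = sum_i s_i (r_i - n_i R/N) with variance
    p(1-p) [sum n_i s_i^2 - (sum n_i s_i)^2 / N], p = R/N, conditioning
    on the genotype column totals; Z^2 ~ chi-square(1).
    """
    keep = dos != MISSING
    d, yy = dos[keep].astype(int), y[keep]
    nmiss = int(keep.sum())
    if nmiss == 0:
        return _record(variant, "TREND", 0, np.nan, np.nan, np.nan, "all genotypes missing")
    scores = np.array([0.0, 1.0, 2.0])
    n_i = np.array([(d == g).sum() for g in (0, 1, 2)], dtype=float)
    r_i = np.array([yy[d == g].sum() for g in (0, 1, 2)], dtype=float)
    N, R = n_i.sum(), r_i.sum()
    if (n_i > 0).sum() < 2:
        return _record(variant, "TREND", nmiss, np.nan, np.nan, np.nan, "monomorphic")
    if R == 0 or R == N:
        return _record(variant, "TREND", nmiss, np.nan, np.nan, np.nan, "single outcome class")
    p_bar = R / N
    T = float(np.sum(scores * (r_i - n_i * p_bar)))
    var_T = p_bar * (1 - p_bar) * (np.sum(n_i * scores**2) - np.sum(n_i * scores) ** 2 / N)
    if var_T <= 0:
        return _record(variant, "TREND", nmiss, np.nan, np.nan, np.nan, "degenerate variance")
    z2 = T * T / var_T
    p = float(stats.chi2.sf(z2, 1))
    tab, _ = _allele_table(dos, y)
    return _record(variant, "TREND", nmiss, _odds_ratio(tab), float(z2), p)


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        res = model.fit(method="newton", maxiter=50, tol=1e-10, disp=0)
    return res


def logistic_scan(
    ds: AnalysisDataset, outcome: str, model: str = "add",
    covariates: list[str] | None = None, test_label: str | None = None,
) -> AssocTable:
    """Univariate logistic regression of the outcome on each variant.

    Per variant: outcome ~ coded genotype + covariates; effect is the
    odds ratio exp(beta), STAT the Wald z, P = 2*Phi(-|z|). Samples with
    a missing genotype are dropped per variant (complete-case).
    """
    y = _binary_outcome(ds, outcome)
    covariates = covariates or []
    Z = ds.pheno[covariates].to_numpy(dtype=float) if covariates else np.zeros((len(y), 0))
    label = test_label or model.upper()
    rows = []
    for j, variant in enumerate(ds.geno.variants.itertuples()):
        g = encode_model(ds.geno.dosage[:, j], model).astype(float)
        keep = g != MISSING
        gk, yk, Zk = g[keep], y[keep], Z[keep]
        nmiss = int(keep.sum())
        if nmiss == 0 or np.ptp(gk) == 0:
            rows.append(_record(variant, label, nmiss, np.nan, np.nan, np.nan, "no genotype variance"))
            continue
        X = np.column_stack([np.ones(nmiss), gk, Zk])
        try:
            res = _fit_logistic(yk, X)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            beta, se = res.params[1], res.bse[1]
            if not np.isfinite(se) or se > 1e4:
                raise RuntimeError("unstable fit (separation)")
        except Exception as exc:  # separation / non-convergence
            rows.append(_record(variant, label, nmiss, np.nan, np.nan, np.nan, f"fit failed: {exc}"))
            continue
        z = beta / se
        rows.append(_record(variant, label, nmiss, float(np.exp(beta)), float(z),
                            float(2 * stats.norm.sf(abs(z)))))
    return AssocTable(_finalize(rows, "OR"), effect_label="OR", method="glm")


def linear_scan(
    ds: AnalysisDataset, outcome: str, model: str = "add",
    covariates: list[str] | None = None,
) -> AssocTable:
    """Per-variant ordinary least squares for a continuous outcome."""
    import statsmodels.api as sm

    y = ds.pheno[outcome].to_numpy(dtype=float)
    covariates = covariates or []
    Z = ds.pheno[covariates].to_numpy(dtype=float) if covariates else np.zeros((len(y), 0))
    label = model.upper()
    rows = []
    for j, variant in enumerate(ds.geno.variants.itertuples()):
        g = encode_model(ds.geno.dosage[:, j], model).astype(float)
        keep = g != MISSING
        gk, yk, Zk = g[keep], y[keep], Z[keep]
        nmiss = int(keep.sum())
        if nmiss == 0 or np.ptp(gk) == 0:
            rows.append(_record(variant, label, nmiss, np.nan, np.nan, np.nan, "no genotype variance"))
            continue
        X = np.column_stack([np.ones(nmiss), gk, Zk])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append(_record(variant, label, nmiss, np.nan, np.nan, np.nan, "rank-deficient design"))
            continue
        res = sm.OLS(yk, X).fit()
        beta, t, p = res.params[1], res.tvalues[1], res.pvalues[1]
        rows.append(_record(variant, label, nmiss, float(beta), float(t), float(max(p, 5e-324))))
    return AssocTable(_finalize(rows, "BETA"), effect_label="BETA", method="lm")


def survival_scan(
    ds: AnalysisDataset, time_col: str, event_col: str, model: str = "dom",
    method: str = "coxph", covariates: list[str] | None = None,
) -> AssocTable:
    """Per-variant survival analysis: log-rank across genotype groups or Cox PH.

    Log-rank compares 2 genotype groups under dom/rec coding or up to 3
    under add; Cox fits a proportional-hazards model (Breslow ties) on
    the coded genotype plus covariates.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import multivariate_logrank_test

    time = ds.pheno[time_col].to_numpy(dtype=float)
    event = ds.pheno[event_col].to_numpy(dtype=int)
    if (time <= 0).any():
        raise ValueError("survival times must be strictly positive")
    covariates = covariates or []
    label = model.upper()
    rows = []
    for j, variant in enumerate(ds.geno.variants.itertuples()):
        g = encode_model(ds.geno.dosage[:, j], model).astype(float)
        keep = g != MISSING
        gk, tk, ek = g[keep], time[keep], event[keep]
        nmiss = int(keep.sum())
        if nmiss == 0 or np.ptp(gk) == 0:
            rows.append(_record(variant, label, nmiss, np.nan, np.nan, np.nan, "no genotype variance"))
            continue
        if ek.sum() == 0:
            rows.append(_record(variant, label, nmiss, np.nan, np.nan, np.nan, "no events"))
            continue
        if method == "logrank":
            lr = multivariate_logrank_test(tk, gk, ek)
            rows.append(_record(variant, label, nmiss, np.nan,
                                float(lr.test_statistic), float(lr.p_value)))
        elif method == "coxph":
            df = pd.DataFrame({"time": tk, "event": ek, "geno": gk})
            for c in covariates:
                df[c] = ds.pheno[c].to_numpy(dtype=float)[keep]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph = CoxPHFitter()
                    cph.fit(df, duration_col="time", event_col="event")
                beta = float(cph.params_["geno"])
                se = float(cph.standard_errors_["geno"])
                z = beta / se
                rows.append(_record(variant, label, nmiss, float(np.exp(beta)), float(z),
                                    float(2 * stats.norm.sf(abs(z)))))
            except Exception as exc:
                rows.append(_record(variant, label, nmiss, np.nan, np.nan, np.nan,
                                    f"fit failed: {exc}"))
        else:
            raise ValueError(f"survival method must be 'logrank' or 'coxph', got {method!r}")
    return AssocTable(_finalize(rows, "HR"), effect_label="HR", method=method)


def _finalize(rows: list[dict], effect_label: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["CHR", "SNP", "BP", "A1", "TEST", "NMISS",
                                     "EFFECT", "STAT", "P", "SKIP_REASON"])
    return df.rename(columns={"EFFECT": effect_label})


def functional_analysis(
    ds: AnalysisDataset, method: str, outcome: str, model: str = "add",
    covariates: list[str] | None = None, threshold: float = 0.05,
    time_col: str | None = None, event_col: str | None = None,
) -> AssocTable:
    """Dispatch to the per-variant test matching ``method``.

    Returns an :class:`AssocTable` whose ``filtered`` property is the
    subset of variants with P below ``threshold``. The threshold is the
    user's call; 0.05 is the default pre-filter.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")

    if method in ("fisher", "chisq", "trend"):
        y = _binary_outcome(ds, outcome)
        fn = {"fisher": fisher_exact_allelic, "chisq": chisq_allelic, "trend": trend_test}[method]
        rows = [fn(ds.geno.dosage[:, j], y, variant)
                for j, variant in enumerate(ds.geno.variants.itertuples())]
        out = AssocTable(_finalize(rows, "OR"), effect_label="OR", method=method)
    elif method == "glm":
        out = logistic_scan(ds, outcome, model, covariates)
    elif method == "lm":
        out = linear_scan(ds, outcome, model, covariates)
    else:  # survfit / coxph
        if time_col is None or event_col is None:
            raise ValueError(f"method {method!r} needs time_col and event_col")
        surv_method = "logrank" if method == "survfit" else "coxph"
        out = survival_scan(ds, time_col, event_col, model, surv_method, covariates)
    out.threshold = threshold
    out.method = method
    return out


def genomic_lambda(pvalues) -> float:
    """Genomic inflation factor lambda.

    Median of the 1-df chi-square quantile transform of the p-values,
    divided by the null median 0.4549364. Lambda near 1 indicates no
    systematic inflation of the test statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("genomic_lambda needs at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(p, 1)
    return float(np.median(chi2_obs) / CHI2_1_MEDIAN)
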