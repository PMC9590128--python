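"""Gene-level variance-component association testing (SKAT).

For a gene unit with genotype submatrix G (n samples x m variants) and
per-variant weights w, the score statistic is

    Q = r' G W^2 G' r,    W = diag(w),

where r are residuals from the null model of the outcome on covariates
only (logistic for a dichotomous outcome, least squares for a continuous
one; for the continuous case Q is divided by the residual variance).
Under the null, Q follows a mixture of 1-df chi-squares with mixture
weights equal to the eigenvalues of W G' P0 G W, where P0 is the
null-model projection:

    dichotomous:  P0 = V - V X (X'V X)^-1 X' V,   V = diag(mu(1-mu))
    continuous:   P0 = I - X (X'X)^-1 X'

Tail probabilities are evaluated by numerical inversion of the mixture's
characteristic function ("davies" engine), with the Liu four-moment
chi-square approximation as automatic fallback, and Monte-Carlo and
permutation oracles for validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .datasets import MISSING, AnalysisDataset, GenotypeDataset, SetIdMap
from .weights import beta_weight


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Fitted covariate-only model for the outcome.

    Holds what the score test needs: fitted means, residuals, the design
    X (with intercept), per-sample variances (dichotomous) or the
    residual variance estimate (continuous).
    """

    out_type: str                 # "D" dichotomous | "C" continuous
    mu: np.ndarray
    resid: np.ndarray
    X: np.ndarray
    v: np.ndarray | None = None   # dichotomous: mu*(1-mu)
    sigma2: float | None = None   # continuous: RSS/(n-p)


def fit_null_model(outcome, covariates=None, out_type: str = "D") -> NullModel:
    """Fit the covariate-only null model.

    out_type "D": logistic regression of the dichotomous outcome on the
    covariates (intercept always included). out_type "C": ordinary least
    squares with sigma^2 = RSS/(n-p).
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank-deficient")

    if out_type == "D":
        vals = set(np.unique(y).tolist())
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"dichotomous outcome takes values {sorted(vals)}, expected {{0,1}}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10, maxiter=100)
        if not res.converged:
            raise RuntimeError("null logistic model did not converge")
        mu = np.asarray(res.fittedvalues)
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            raise RuntimeError("null logistic model is separated (fitted means at 0/1)")
        return NullModel("D", mu, y - mu, X, v=mu * (1 - mu))
    if out_type == "C":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu = X @ beta
        r = y - mu
        dof = n - X.shape[1]
        if dof <= 0:
            raise ValueError("not enough samples for the covariate design")
        return NullModel("C", mu, r, X, sigma2=float(r @ r / dof))
    raise ValueError(f"out_type must be 'D' or 'C', got {out_type!r}")


# ---------------------------------------------------------------------------
# Gene unit QC
# ---------------------------------------------------------------------------

@dataclass
class GeneUnit:
    """QC'd genotype submatrix and weights for one gene/set."""

    set_id: str
    G: np.ndarray                 # (n, m_tested) float, missing imputed
    w: np.ndarray                 # (m_tested,) positive weights
    markers_all: int
    markers_tested: int
    dropped: list[str] = field(default_factory=list)


def gene_qc(G, weights, set_id: str = "", impute_policy: str = "mean",
            variant_ids=None) -> GeneUnit:
    """Impute missing dosages and drop monomorphic variants.

    ``mean`` imputation replaces a missing dosage with 2 * in-sample MAF
    of that variant; ``complete`` drops samples is not offered here —
    instead ``none`` requires complete data. Variants with zero variance
    after imputation are removed (they carry no information).
    """
    G = np.asarray(G, dtype=float)
    w = np.asarray(weights, dtype=float)
    m_all = G.shape[1]
    if w.size != m_all:
        raise ValueError("one weight per variant required")
    if variant_ids is None:
        variant_ids = [str(j) for j in range(m_all)]
    miss = G == MISSING
    if miss.any():
        if impute_policy == "mean":
            G = G.copy()
            for j in np.where(miss.any(axis=0))[0]:
                col = G[:, j]
                obs = col[~miss[:, j]]
                if obs.size == 0:
                    col[:] = np.nan
                else:
                    col[miss[:, j]] = obs.mean()  # = 2 * in-sample MAF
        elif impute_policy == "none":
            raise ValueError("missing genotypes present with impute_policy='none'")
        else:
            raise ValueError(f"unknown impute_policy {impute_policy!r}")
    variances = np.nanvar(G, axis=0)
    keep = np.isfinite(variances) & (variances > 0) & (w > 0)
    dropped = [variant_ids[j] for j in np.where(~keep)[0]]
    return GeneUnit(set_id, G[:, keep], w[keep], m_all, int(keep.sum()), dropped)


# ---------------------------------------------------------------------------
# Score statistic and its null distribution
# ---------------------------------------------------------------------------

def skat_statistic(unit: GeneUnit, null: NullModel) -> float:
    """Q = r' G W^2 G' r (divided by sigma^2 for a continuous outcome)."""
    A = unit.G * unit.w  # columns scaled: A = G W
    s = A.T @ null.resid
    q = float(s @ s)
    if null.out_type == "C":
        q /= null.sigma2
    return q


def mixture_lambdas(unit: GeneUnit, null: NullModel) -> np.ndarray:
    """Eigenvalues of W G' P0 G W — the 1-df chi-square mixture weights.

    Negative eigenvalues from round-off (below 1e-10 of the largest) are
    clipped to zero.
    """
    A = unit.G * unit.w
    X = null.X
    if null.out_type == "D":
        V = null.v
        VA = A * V[:, None]
        XtVX = X.T @ (X * V[:, None])
        XtVA = X.T @ VA
        B = A.T @ VA - XtVA.T @ np.linalg.solve(XtVX, XtVA)
    else:
        XtX = X.T @ X
        XtA = X.T @ A
        B = A.T @ A - XtA.T @ np.linalg.solve(XtX, XtA)
    lam = np.linalg.eigvalsh((B + B.T) / 2.0)
    if lam.size:
        lam[lam < 1e-10 * max(lam.max(), 1e-300)] = 0.0
    return np.sort(lam)[::-1]


# ---------------------------------------------------------------------------
# Tail of a weighted chi-square mixture
# ---------------------------------------------------------------------------

def _cf_inversion_tail(lam: np.ndarray, q: float) -> tuple[float, bool]:
    """P(sum lam_j chi2_1 > q) by numerical characteristic-function inversion.

    Inversion-integral form: p = 1/2 + (1/pi) * int_0^inf
    sin(theta(u)) / (u * rho(u)) du with theta = (sum atan(lam u) - q u)/2
    and rho = prod (1 + lam^2 u^2)^(1/4).

    A single eigenvalue reduces exactly to a scaled 1-df chi-square. For
    m >= 2 the integral is split at U0 (past the arctan transition):
    adaptive quadrature on [0, U0], then sin(theta) is expanded as
    sin(phi)cos(qu/2) - cos(phi)sin(qu/2) with phi = sum atan(lam u)/2
    slowly varying, and each tail piece is handled by QUADPACK's
    oscillatory Fourier integrator. Returns (p, ok); callers fall back
    to the moment approximation when ok is False.
    """
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1)), True

    def phi_rho(u):
        return 0.5 * np.sum(np.arctan(lam * u)), np.exp(
            0.25 * np.sum(np.log1p((lam * u) ** 2))
        )

    def integrand(u):
        phi, rho = phi_rho(u)
        return np.sin(phi - 0.5 * q * u) / (u * rho)

    def f_cos(u):
        phi, rho = phi_rho(u)
        return np.sin(phi) / (u * rho)

    def f_sin(u):
        phi, rho = phi_rho(u)
        return np.cos(phi) / (u * rho)

    u0 = min(30.0 / lam.min(), max(2e3 / q, 200.0 / lam.max()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            v0, e0 = integrate.quad(integrand, 0.0, u0, epsabs=1e-13,
                                    epsrel=1e-11, limit=4000)
            v1, e1 = integrate.quad(f_cos, u0, np.inf, weight="cos",
                                    wvar=0.5 * q, limit=2000)
            v2, e2 = integrate.quad(f_sin, u0, np.inf, weight="sin",
                                    wvar=0.5 * q, limit=2000)
        except Exception:
            return np.nan, False
    p = 0.5 + (v0 + v1 - v2) / np.pi
    ok = bool(np.isfinite(p) and (e0 + e1 + e2) < 1e-6 and 0.0 < p <= 1.0)
    return p, ok


def _liu_tail(lam: np.ndarray, q: float) -> float:
    """Liu et al. four-moment chi-square approximation of the mixture tail."""
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    c4 = float(np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        ell = a**2 - 2 * delta
    else:
        delta = 0.0
        ell = 1.0 / s2
    mu_x = ell + delta
    sigma_x = np.sqrt(2 * (ell + 2 * delta))
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, ell, delta))


def quadform_tail(lambdas, q: float, engine: str = "davies",
                  n_mc: int = 1_000_000, rng=None) -> tuple[float, str]:
    """Upper-tail probability P(sum lam_j chi2_1,j > q).

    Engines: ``davies`` (characteristic-function inversion; falls back
    to ``liu`` when the inversion fails or leaves (0, 1], recording the
    method actually used), ``liu`` (four-moment matching), and
    ``montecarlo`` (empirical tail from ``n_mc`` draws; oracle use).
    Returns (p, method_used).
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all mixture eigenvalues are zero: degenerate null distribution")
    if q < 0:
        raise ValueError("the quadratic form statistic must be nonnegative")
    if q == 0:
        return 1.0, engine
    if engine == "davies":
        p, ok = _cf_inversion_tail(lam, q)
        if ok:
            return max(p, 5e-324), "davies"
        return max(_liu_tail(lam, q), 5e-324), "liu_fallback"
    if engine == "liu":
        return max(_liu_tail(lam, q), 5e-324), "liu"
    if engine == "montecarlo":
        rng = np.random.default_rng(rng)
        draws = rng.chisquare(1.0, size=(n_mc, lam.size)) @ lam
        return float((1 + np.sum(draws > q)) / (n_mc + 1)), "montecarlo"
    raise ValueError(f"engine must be davies, liu or montecarlo, got {engine!r}")


def permutation_pvalue(unit: GeneUnit, null: NullModel, B: int = 1999,
                       rng=None) -> float:
    """Permutation p-value for Q under outcome exchangeability.

    Only valid for an intercept-only null model (with covariates the
    outcome is not exchangeable); refuses otherwise. p_hat =
    (1 + #{Q_perm >= Q_obs}) / (B + 1).
    """
    if null.X.shape[1] != 1:
        raise ValueError("permutation p-values require an intercept-only null model")
    rng = np.random.default_rng(rng)
    A = unit.G * unit.w
    q_obs = skat_statistic(unit, null)
    r = null.resid
    n = r.size
    perm_idx = np.argsort(rng.random((B, n)), axis=1)
    R = r[perm_idx]                      # (B, n) permuted residual vectors
    S = R @ A                            # (B, m)
    q_perm = np.einsum("bm,bm->b", S, S)
    if null.out_type == "C":
        q_perm = q_perm / null.sigma2
    return float((1 + np.sum(q_perm >= q_obs)) / (B + 1))


# ---------------------------------------------------------------------------
# Per-set association driver
# ---------------------------------------------------------------------------

def skat_test_unit(unit: GeneUnit, null: NullModel, engine: str = "davies"):
    """Run the variance-component test on one QC'd unit.

    Returns (p, Q, method_used); (nan, nan, reason) when no markers
    survive QC.
    """
    if unit.markers_tested == 0:
        return np.nan, np.nan, "no testable markers"
    q = skat_statistic(unit, null)
    lam = mixture_lambdas(unit, null)
    if not np.any(lam > 0):
        return np.nan, np.nan, "degenerate unit (zero eigenvalues)"
    p, used = quadform_tail(lam, q, engine=engine)
    return p, q, used


def skat_assoc(
    geno: GenotypeDataset,
    setid: SetIdMap,
    outcome,
    covariates=None,
    out_type: str = "D",
    weight_table: pd.DataFrame | None = None,
    engine: str = "davies",
    add_bh: bool = False,
) -> pd.DataFrame:
    """Gene-level association for every set in ``setid``.

    ``outcome``/``covariates`` are aligned to ``geno.samples``. Weights
    come from ``weight_table`` (columns snp, weight — the output of the
    reference-MAF weighting stage); set members absent from the table
    get the default Beta(1, 25) weight of their in-sample MAF, which is
    also used for every variant when no table is given. Set members
    absent from the genotype data are logged and excluded from
    N.Marker.All.

    Returns a frame with columns SetID, P.value, N.Marker.All,
    N.Marker.Test (plus Q, Method; optional P.adjust), sorted by
    P.value.
    """
    null = fit_null_model(outcome, covariates, out_type)
    rsid_to_col = {rsid: j for j, rsid in enumerate(geno.variants["rsid"])}
    sample_maf = geno.sample_maf()

    weight_by_snp: dict[str, float] = {}
    if weight_table is not None:
        weight_by_snp = dict(zip(weight_table["snp"], weight_table["weight"]))

    rows = []
    for set_id, members in setid.to_dict().items():
        cols, w = [], []
        missing_members = []
        for var_id in members:
            j = rsid_to_col.get(var_id)
            if j is None:
                missing_members.append(var_id)
                continue
            cols.append(j)
            if var_id in weight_by_snp:
                w.append(float(weight_by_snp[var_id]))
            else:
                maf = sample_maf[j]
                maf = 0.0 if not np.isfinite(maf) else min(maf, 0.5)
                w.append(float(beta_weight(maf, 1.0, 25.0)))
        if missing_members:
            warnings.warn(
                f"set {set_id}: {len(missing_members)} members absent from genotype data",
                stacklevel=2,
            )
        if not cols:
            rows.append({"SetID": set_id, "P.value": np.nan, "N.Marker.All": 0,
                         "N.Marker.Test": 0, "Q": np.nan, "Method": "no markers"})
            continue
        unit = gene_qc(
            geno.dosage[:, cols].astype(float), np.asarray(w), set_id,
            variant_ids=[geno.variants["rsid"].iloc[j] for j in cols],
        )
        p, q, used = skat_test_unit(unit, null, engine)
        rows.append({"SetID": set_id, "P.value": p, "N.Marker.All": unit.markers_all,
                     "N.Marker.Test": unit.markers_tested, "Q": q, "Method": used})
    out = pd.DataFrame(rows, columns=["SetID", "P.value", "N.Marker.All",
                                      "N.Marker.Test", "Q", "Method"])
    out = out.sort_values("P.value", kind="mergesort", na_position="last").reset_index(drop=True)
    if add_bh:
        from .annotate import bh_adjust

        mask = out["P.value"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = bh_adjust(out.loc[mask, "P.value"].to_numpy())
        out["P.adjust"] = adj
    return out


def write_skat_csv(result: pd.DataFrame, path) -> None:
    """Write the canonical 4-column gene-level result CSV."""
    result[["SetID", "P.value", "N.Marker.All", "N.Marker.Test"]].to_csv(path, index=False)
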