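"""Exploratory moderated-regression stage.

For each SNP the standard interaction specification is

    Y = A0 + A1*PE + A2*T + A3*(PE x T) + A4*Age + A5*Sex + E

with T the additive risk dosage (0/1/2 entered as a numeric covariate), and
analogously for the cumulative genetic score X2 in place of T.  Evidence for
G×E is the increase in R² when the product term is added (Model 1 without,
Model 2 with), tested by the nested F

    F = (dR² / dk) / ((1 - R²_full) / df_resid_full).

Across a panel of m retained SNPs the interaction p-values are
Bonferroni-controlled at alpha/m.  A gate statistic F > 1.0 on the CGS
interaction licenses the confirmatory crossover stage.

Information criteria are computed on the least-squares scale,
AIC = n ln(RSS/n) + 2k and BIC = n ln(RSS/n) + k ln(n) with k = number of
mean parameters + 1 (the residual variance), so that differences between
models fitted to the same data are well defined across implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from gxecross.cohort import Cohort

__all__ = [
    "LinearFitResult",
    "ComparisonResult",
    "ScanResult",
    "CgsInteractionResult",
    "fit_ols",
    "nested_f_test",
    "fit_snp_models",
    "run_snp_scan",
    "fit_cgs_interaction",
    "simple_slopes",
    "snp_design",
    "cgs_design",
]


def ls_information_criteria(rss: float, n: int, k_mean: int) -> tuple[float, float]:
    """(AIC, BIC) on the least-squares scale; k = k_mean + 1 for sigma²."""
    k = k_mean + 1
    base = n * np.log(rss / n)
    return float(base + 2 * k), float(base + k * np.log(n))


@dataclass
class LinearFitResult:
    """OLS fit summary for one exploratory model."""

    terms: list[str]  # regressor names, including "const"
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    pvalues: pd.Series
    r2: float
    f_overall: float
    f_p: float
    df: tuple[int, int]  # (model df, residual df)
    rss: float
    n: int
    aic: float
    bic: float
    loglik: float
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def df_model(self) -> int:
        return self.df[0]

    @property
    def df_resid(self) -> int:
        return self.df[1]


def fit_ols(y, X: pd.DataFrame, add_const: bool = True) -> LinearFitResult:
    """Ordinary least squares with the package's fit summary.

    ``X`` columns name the design terms; a constant is prepended unless
    already present.  Raises on rank-deficient designs, naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if add_const and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="raise")
    if len(X) != len(y):
        raise ValueError("y and X must have equal length")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by pivoted QR on the scaled design
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    k_mean = X.shape[1]
    aic, bic = ls_information_criteria(float(res.ssr), len(y), k_mean)
    return LinearFitResult(
        terms=list(X.columns),
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        f_overall=float(res.fvalue),
        f_p=float(res.f_pvalue),
        df=(int(res.df_model), int(res.df_resid)),
        rss=float(res.ssr),
        n=len(y),
        aic=aic,
        bic=bic,
        loglik=float(res.llf),
        fitted=np.asarray(res.fittedvalues),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Nested-model comparison: change in R² and its F test."""

    delta_r2: float
    f: float
    df: tuple[int, int]
    p: float


def nested_f_test(reduced: LinearFitResult, full: LinearFitResult) -> ComparisonResult:
    """F test of the R² increase from ``reduced`` to ``full``.

    Requires the reduced model's terms to be a strict subset of the full
    model's, fitted to the same observations.
    """
    if reduced.n != full.n:
        raise ValueError("fits use different sample sizes")
    if not set(reduced.terms) < set(full.terms):
        raise ValueError("models are not nested (reduced terms must be a strict subset)")
    dk = len(full.terms) - len(reduced.terms)
    df_resid = full.df_resid
    f = ((reduced.rss - full.rss) / dk) / (full.rss / df_resid)
    p = float(stats.f.sf(f, dk, df_resid))
    return ComparisonResult(
        delta_r2=float(full.r2 - reduced.r2), f=float(f), df=(dk, df_resid), p=p
    )


def snp_design(cohort: Cohort, snp_id: str, include_product: bool) -> pd.DataFrame:
    """Design frame pe / t / (pe_x_t) / age / sex for one SNP."""
    t = cohort.dosage(snp_id)
    cols = {"pe": cohort.pe, "t": t}
    if include_product:
        cols["pe_x_t"] = cohort.pe * t
    cols["age"] = cohort.age
    cols["sex"] = cohort.sex
    return pd.DataFrame(cols)


def cgs_design(cohort: Cohort, include_product: bool, cgs=None) -> pd.DataFrame:
    """Design frame pe / cgs / (pe_x_cgs) / age / sex."""
    x2 = np.asarray(cohort.cgs if cgs is None else cgs, dtype=float)
    cols = {"pe": cohort.pe, "cgs": x2}
    if include_product:
        cols["pe_x_cgs"] = cohort.pe * x2
    cols["age"] = cohort.age
    cols["sex"] = cohort.sex
    return pd.DataFrame(cols)


def fit_snp_models(cohort: Cohort, snp_id: str):
    """Fit Model 1 (main effects) and Model 2 (+product) for one SNP.

    Returns (model1, model2, comparison).
    """
    m1 = fit_ols(cohort.phenotype, snp_design(cohort, snp_id, include_product=False))
    m2 = fit_ols(cohort.phenotype, snp_design(cohort, snp_id, include_product=True))
    return m1, m2, nested_f_test(m1, m2)


@dataclass
class ScanResult:
    """Panel-wide exploratory scan with Bonferroni control."""

    table: pd.DataFrame  # one row per tested SNP
    m: int  # number of tests (retained panel size)
    alpha: float
    threshold: float  # per-test alpha / m
    significant: list[str]
    fits: dict  # snp_id -> (model1, model2, comparison)


def run_snp_scan(
    cohort: Cohort, snp_ids=None, alpha: float = 0.05, m_override: int | None = None
) -> ScanResult:
    """Interaction scan across SNPs with Bonferroni-corrected verdicts.

    For each SNP fits the main-effects and interaction models, tests the
    product term by nested F, and compares each raw p against alpha/m with
    m the number of SNPs actually tested (``m_override`` replaces m when
    given).  Monomorphic SNPs are skipped with a warning (they carry no
    interaction information).
    """
    snp_ids = list(snp_ids) if snp_ids is not None else cohort.snp_ids
    rows, fits = [], {}
    for snp in snp_ids:
        t = cohort.dosage(snp)
        if np.std(t) == 0.0:
            warnings.warn(f"{snp} is monomorphic in this sample; skipped", stacklevel=2)
            continue
        m1, m2, comp = fit_snp_models(cohort, snp)
        fits[snp] = (m1, m2, comp)
        rows.append(
            dict(
                snp_id=snp,
                a3=float(m2.params["pe_x_t"]),
                a3_se=float(m2.bse["pe_x_t"]),
                delta_r2=comp.delta_r2,
                f=comp.f,
                p=comp.p,
            )
        )
    if not rows:
        raise ValueError("no polymorphic SNPs to scan")
    table = pd.DataFrame(rows).set_index("snp_id", drop=False)
    m = m_override if m_override is not None else len(table)
    if m < 1:
        raise ValueError("Bonferroni m must be >= 1")
    threshold = alpha / m
    table["bonferroni_significant"] = table["p"] < threshold
    significant = list(table.index[table["bonferroni_significant"]])
    return ScanResult(
        table=table, m=m, alpha=alpha, threshold=threshold,
        significant=significant, fits=fits,
    )


@dataclass
class CgsInteractionResult:
    """CGS x environment exploratory pair with the confirmatory gate."""

    main: LinearFitResult
    interaction: LinearFitResult
    comparison: ComparisonResult
    gate_passed: bool  # interaction F ratio > 1.0


def fit_cgs_interaction(cohort: Cohort, cgs=None) -> CgsInteractionResult:
    """Main-effects and interaction fits for the CGS, plus the F > 1 gate.

    The gate flag (nested interaction F ratio above 1.0) is the licence to
    evaluate the competing confirmatory crossover models.
    """
    x2 = np.asarray(cohort.cgs if cgs is None else cgs, dtype=float)
    if np.std(x2) == 0.0:
        raise ValueError("CGS has zero variance; interaction model unidentified")
    m1 = fit_ols(cohort.phenotype, cgs_design(cohort, False, cgs=x2))
    m2 = fit_ols(cohort.phenotype, cgs_design(cohort, True, cgs=x2))
    comp = nested_f_test(m1, m2)
    return CgsInteractionResult(
        main=m1, interaction=m2, comparison=comp, gate_passed=bool(comp.f > 1.0)
    )


def simple_slopes(
    fit: LinearFitResult,
    moderator_levels,
    env_term: str = "pe",
    product_term: str | None = None,
) -> pd.DataFrame:
    """Environment slope at fixed moderator levels, with delta-method SEs.

    For the fit Y = ... + A1*env + A3*(env x mod) + ..., the simple slope
    at moderator level t is A1 + A3*t with variance
    Var(A1) + t² Var(A3) + 2t Cov(A1, A3).
    """
    if product_term is None:
        candidates = [c for c in fit.terms if c.startswith(f"{env_term}_x_")]
        if len(candidates) != 1:
            raise ValueError("fit does not contain a unique product term")
        product_term = candidates[0]
    if product_term not in fit.terms:
        raise ValueError(f"fit lacks the product term {product_term!r}")
    a1 = float(fit.params[env_term])
    a3 = float(fit.params[product_term])
    v11 = float(fit.cov.loc[env_term, env_term])
    v33 = float(fit.cov.loc[product_term, product_term])
    v13 = float(fit.cov.loc[env_term, product_term])
    rows = []
    for t in np.atleast_1d(moderator_levels):
        slope = a1 + a3 * t
        se = float(np.sqrt(v11 + t**2 * v33 + 2 * t * v13))
        z = slope / se if se > 0 else np.nan
        p = float(stats.t.sf(abs(z), fit.df_resid) * 2) if se > 0 else np.nan
        rows.append(dict(level=float(t), slope=float(slope), se=se, t=z, p=p))
    return pd.DataFrame(rows)
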