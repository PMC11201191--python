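"""Confirmatory re-parameterized crossover regression.

The moderated regression of the exploratory stage is re-expressed around
the crossover point C — the environment value at which all genotype groups
have equal expected phenotype:

    genotype groups (risk dosage T of one SNP):
        T=0:  Y = A0 + A1*(X1 - C) + A_age*Age + A_sex*Sex + E
        T=1:  Y = A0 + A2*(X1 - C) + ...
        T=2:  Y = A0 + A3*(X1 - C) + ...

    linear-by-linear (CGS X2):
        Y = A0 + A1*(X1 - C) + A2*((X1 - C) x X2) + A_age*Age + A_sex*Sex + E

Six model variants arbitrate between the two theoretical interaction
families.  3a/3b estimate C freely (strong fixes the reference slope A1=0,
weak leaves it free): a crossover inside the observed environment range is
a disordinal interaction, the differential-susceptibility signature.
3c/3d fix C at the top of the environment scale, mean(X1) + 3 SD(X1)
(optionally the observed maximum): an ordinal interaction, the
diathesis-stress signature.  3e/3f are the free-C and fixed-C versions of
the linear-by-linear form.

Given C the mean structure is linear, so free-C models are fitted by
profiling: the RSS is minimized over C by a coarse grid sweep followed by
bounded 1-D refinement, with the linear coefficients solved exactly at each
candidate C.  This removes the initialization and convergence pathologies
of joint gradient-based nonlinear least squares.  Standard errors
(including SE(C)) come from the Gauss-Newton covariance sigma² (J'J)^-1 at
the optimum, whose C-block equals the curvature of the profiled objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gxecross.cohort import Cohort
from gxecross.exploratory import LinearFitResult, ls_information_criteria

__all__ = [
    "ReparamFitResult",
    "Classification",
    "wald_ci",
    "fixed_c_value",
    "fit_crossover_groups",
    "fit_crossover_linear",
    "fit_group_family",
    "fit_cgs_family",
    "nested_f_reparam",
    "compare_models",
    "predicted_surface",
    "linear_to_crossover",
    "CommonCrossover",
]

#: Relative RSS variation across the profile grid below which C is
#: declared unidentified (flat profile).
FLAT_PROFILE_TOL = 1e-10

_Z975 = 1.959963984540054


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval estimate ± z(level)*se, z(0.95) = 1.959964."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return (estimate - z * se, estimate + z * se)


def fixed_c_value(pe, rule: str = "mean_plus_3sd") -> float:
    """Fixed crossover for diathesis-stress models.

    ``mean_plus_3sd`` (default) places C at mean(PE) + 3*SD(PE), the
    conventional proxy for the top of the environment scale;
    ``observed_max`` uses max(PE) of the sample.
    """
    pe = np.asarray(pe, dtype=float)
    if rule == "mean_plus_3sd":
        return float(np.mean(pe) + 3.0 * np.std(pe, ddof=1))
    if rule == "observed_max":
        return float(np.max(pe))
    raise ValueError("rule must be 'mean_plus_3sd' or 'observed_max'")


# ---------------------------------------------------------------------------
# linear kernel


def _design_groups(pe, t, age, sex, c, strong):
    cols, names = [np.ones(len(pe))], ["a0"]
    for g in (0, 1, 2):
        if strong and g == 0:
            continue
        cols.append((t == g) * (pe - c))
        names.append(f"slope{g}")
    cols += [age, sex]
    names += ["age", "sex"]
    return np.column_stack(cols), names


def _design_linear(pe, x2, age, sex, c):
    cols = [np.ones(len(pe)), pe - c, (pe - c) * x2, age, sex]
    return np.column_stack(cols), ["a0", "a1", "a2", "age", "sex"]


def _ls(y, X):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class ReparamFitResult:
    """One fitted crossover model."""

    model_id: str  # "3a".."3f" or "custom"
    form: str  # "groups" | "linear"
    strong: bool
    c_hat: float
    c_fixed: bool
    c_se: float | None
    c_ci: tuple[float, float] | None
    params: pd.Series  # linear coefficients at the fitted C
    bse: pd.Series
    r2: float
    rss: float
    aic: float
    bic: float
    df: tuple[int, int]  # (model df, residual df)
    n: int
    n_mean_params: int  # linear coefficients + (1 if C free)
    identified: bool = True
    c_ci_profile: tuple[float, float] | None = None
    group_sizes: dict | None = None
    profile: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    @property
    def df_resid(self) -> int:
        return self.df[1]

    def slope_at(self, gene) -> np.ndarray:
        """Per-individual environment slope implied by the fitted model."""
        gene = np.asarray(gene, dtype=float)
        if self.form == "groups":
            slopes = np.array(
                [float(self.params.get(f"slope{g}", 0.0)) for g in (0, 1, 2)]
            )
            return slopes[gene.astype(int)]
        return float(self.params["a1"]) + float(self.params["a2"]) * gene

    def predict(self, pe, gene, age, sex) -> np.ndarray:
        """Model mean at the given environment, genotype and covariates."""
        pe = np.asarray(pe, dtype=float)
        return (
            float(self.params["a0"])
            + self.slope_at(gene) * (pe - self.c_hat)
            + float(self.params["age"]) * np.asarray(age, dtype=float)
            + float(self.params["sex"]) * np.asarray(sex, dtype=float)
        )


def _finish_fit(
    model_id, form, strong, y, pe, gene, age, sex, c, c_fixed, beta, names, rss,
    profile=None, identified=True, level=0.95,
):
    n = len(y)
    k_lin = len(beta)
    k_mean = k_lin + (0 if c_fixed else 1)
    df_resid = n - k_mean
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    X, _ = (
        _design_groups(pe, gene, age, sex, c, strong)
        if form == "groups"
        else _design_linear(pe, gene, age, sex, c)
    )
    if c_fixed or not identified:
        cov = sigma2 * np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.diag(cov))
        c_se, c_ci = None, None
    else:
        # Gauss-Newton Jacobian: linear columns plus d(mean)/dC = -slope_i
        if form == "groups":
            slopes = np.zeros(3)
            for g in (0, 1, 2):
                if f"slope{g}" in names:
                    slopes[g] = beta[names.index(f"slope{g}")]
            dfdc = -slopes[gene.astype(int)]
        else:
            dfdc = -(beta[names.index("a1")] + beta[names.index("a2")] * gene)
        J = np.column_stack([X, dfdc])
        cov_full = sigma2 * np.linalg.inv(J.T @ J)
        bse = np.sqrt(np.diag(cov_full[:k_lin, :k_lin]))
        c_se = float(np.sqrt(cov_full[-1, -1]))
        c_ci = wald_ci(c, c_se, level)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    aic, bic = ls_information_criteria(rss, n, k_mean)
    gs = None
    if form == "groups":
        gene_i = gene.astype(int)
        gs = {g: int(np.sum(gene_i == g)) for g in (0, 1, 2)}
    return ReparamFitResult(
        model_id=model_id,
        form=form,
        strong=strong,
        c_hat=float(c),
        c_fixed=c_fixed,
        c_se=c_se,
        c_ci=c_ci,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        r2=r2,
        rss=rss,
        aic=aic,
        bic=bic,
        df=(k_mean - 1, df_resid),
        n=n,
        n_mean_params=k_mean,
        identified=identified,
        group_sizes=gs,
        profile=profile,
    )


def _profile_c(rss_of_c, pe, grid_step: float = 0.05):
    """Coarse grid sweep over C followed by bounded scalar refinement.

    The search window is [min(PE) - 2 SD, max(PE) + 2 SD].  Returns
    (c_hat, grid, rss_grid, flat) where ``flat`` marks an unidentified
    (constant to within FLAT_PROFILE_TOL) profile.
    """
    sd = float(np.std(pe, ddof=1))
    lo, hi = float(np.min(pe)) - 2 * sd, float(np.max(pe)) + 2 * sd
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    rss_grid = np.array([rss_of_c(c) for c in grid])
    spread = rss_grid.max() - rss_grid.min()
    if spread <= FLAT_PROFILE_TOL * max(rss_grid.max(), 1.0):
        return np.nan, grid, rss_grid, True
    i = int(np.argmin(rss_grid))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        rss_of_c, bounds=(b_lo, b_hi), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), grid, rss_grid, False


def _profile_ci(rss_of_c, c_hat, rss_min, df_resid, grid, rss_grid, level=0.95):
    """Profile-likelihood CI by inverting the 1-df F test on the RSS ratio."""
    thresh = rss_min * (1.0 + stats.f.ppf(level, 1, df_resid) / df_resid)

    def crossing(a, b):
        try:
            return float(optimize.brentq(lambda c: rss_of_c(c) - thresh, a, b, xtol=1e-6))
        except ValueError:
            return None

    below = grid[grid < c_hat]
    lo = None
    outside = below[np.array([rss_of_c(c) for c in below]) > thresh] if len(below) else []
    if len(outside):
        lo = crossing(float(outside[-1]), c_hat)
    above = grid[grid > c_hat]
    hi = None
    outside = above[np.array([rss_of_c(c) for c in above]) > thresh] if len(above) else []
    if len(outside):
        hi = crossing(c_hat, float(outside[0]))
    if lo is None or hi is None:
        return None
    return (lo, hi)


# ---------------------------------------------------------------------------
# public fits


def fit_crossover_groups(
    cohort: Cohort,
    snp_id: str | None = None,
    dosage=None,
    c_mode: str = "free",
    c_value: float | None = None,
    strong: bool = False,
    model_id: str | None = None,
    profile_ci: bool = False,
) -> ReparamFitResult:
    """Fit the genotype-group crossover model for one SNP.

    ``c_mode="free"`` profiles C; ``c_mode="fixed"`` requires ``c_value``
    (e.g. from :func:`fixed_c_value`).  ``strong=True`` constrains the
    zero-risk-allele group's slope to 0.  Every genotype group must be
    represented in the sample.
    """
    t = cohort.dosage(snp_id) if dosage is None else np.asarray(dosage, dtype=float)
    sizes = {g: int(np.sum(t == g)) for g in (0, 1, 2)}
    if min(sizes.values()) == 0:
        raise ValueError(f"empty genotype group; group sizes {sizes}")
    y, pe, age, sex = cohort.phenotype, cohort.pe, cohort.age, cohort.sex
    if model_id is None:
        model_id = {
            ("free", True): "3a", ("free", False): "3b",
            ("fixed", True): "3c", ("fixed", False): "3d",
        }[(c_mode, strong)]

    if c_mode == "fixed":
        if c_value is None:
            raise ValueError("c_mode='fixed' requires c_value")
        X, names = _design_groups(pe, t, age, sex, c_value, strong)
        beta, rss = _ls(y, X)
        return _finish_fit(model_id, "groups", strong, y, pe, t, age, sex,
                           c_value, True, beta, names, rss)
    if c_mode != "free":
        raise ValueError("c_mode must be 'free' or 'fixed'")

    def rss_of_c(c):
        X, _ = _design_groups(pe, t, age, sex, c, strong)
        return _ls(y, X)[1]

    c_hat, grid, rss_grid, flat = _profile_c(rss_of_c, pe)
    if flat:
        X, names = _design_groups(pe, t, age, sex, float(np.mean(pe)), strong)
        beta, rss = _ls(y, X)
        return _finish_fit(model_id, "groups", strong, y, pe, t, age, sex,
                           float(np.mean(pe)), False, beta, names, rss,
                           profile=(grid, rss_grid), identified=False)
    X, names = _design_groups(pe, t, age, sex, c_hat, strong)
    beta, rss = _ls(y, X)
    fit = _finish_fit(model_id, "groups", strong, y, pe, t, age, sex,
                      c_hat, False, beta, names, rss, profile=(grid, rss_grid))
    if profile_ci:
        fit.c_ci_profile = _profile_ci(rss_of_c, c_hat, rss, fit.df_resid, grid, rss_grid)
    return fit


def fit_crossover_linear(
    cohort: Cohort,
    c_mode: str = "free",
    c_value: float | None = None,
    cgs=None,
    model_id: str | None = None,
    profile_ci: bool = False,
) -> ReparamFitResult:
    """Fit the linear-by-linear (CGS) crossover model.

    The environment slope is A1 + A2*X2 on (X1 - C).  Same profiling
    contract as the group model; a flat profile (A2 ~ 0, crossover
    unidentified) is detected and flagged.
    """
    x2 = np.asarray(cohort.cgs if cgs is None else cgs, dtype=float)
    if np.std(x2) == 0.0:
        raise ValueError("CGS has zero variance; crossover model unidentified")
    y, pe, age, sex = cohort.phenotype, cohort.pe, cohort.age, cohort.sex
    if model_id is None:
        model_id = "3e" if c_mode == "free" else "3f"

    if c_mode == "fixed":
        if c_value is None:
            raise ValueError("c_mode='fixed' requires c_value")
        X, names = _design_linear(pe, x2, age, sex, c_value)
        beta, rss = _ls(y, X)
        return _finish_fit(model_id, "linear", False, y, pe, x2, age, sex,
                           c_value, True, beta, names, rss)
    if c_mode != "free":
        raise ValueError("c_mode must be 'free' or 'fixed'")

    def rss_of_c(c):
        X, _ = _design_linear(pe, x2, age, sex, c)
        return _ls(y, X)[1]

    c_hat, grid, rss_grid, flat = _profile_c(rss_of_c, pe)
    if flat:
        X, names = _design_linear(pe, x2, age, sex, float(np.mean(pe)))
        beta, rss = _ls(y, X)
        return _finish_fit(model_id, "linear", False, y, pe, x2, age, sex,
                           float(np.mean(pe)), False, beta, names, rss,
                           profile=(grid, rss_grid), identified=False)
    X, names = _design_linear(pe, x2, age, sex, c_hat)
    beta, rss = _ls(y, X)
    fit = _finish_fit(model_id, "linear", False, y, pe, x2, age, sex,
                      c_hat, False, beta, names, rss, profile=(grid, rss_grid))
    if profile_ci:
        fit.c_ci_profile = _profile_ci(rss_of_c, c_hat, rss, fit.df_resid, grid, rss_grid)
    return fit


def fit_group_family(
    cohort: Cohort, snp_id: str, fixed_c_rule: str = "mean_plus_3sd"
) -> dict[str, ReparamFitResult]:
    """All four genotype-group models 3a-3d for one SNP."""
    c_fix = fixed_c_value(cohort.pe, fixed_c_rule)
    return {
        "3a": fit_crossover_groups(cohort, snp_id, c_mode="free", strong=True),
        "3b": fit_crossover_groups(cohort, snp_id, c_mode="free", strong=False),
        "3c": fit_crossover_groups(cohort, snp_id, c_mode="fixed", c_value=c_fix, strong=True),
        "3d": fit_crossover_groups(cohort, snp_id, c_mode="fixed", c_value=c_fix, strong=False),
    }


def fit_cgs_family(
    cohort: Cohort, cgs=None, fixed_c_rule: str = "mean_plus_3sd"
) -> dict[str, ReparamFitResult]:
    """Both linear-by-linear models 3e (free C) and 3f (fixed C)."""
    c_fix = fixed_c_value(cohort.pe, fixed_c_rule)
    return {
        "3e": fit_crossover_linear(cohort, c_mode="free", cgs=cgs),
        "3f": fit_crossover_linear(cohort, c_mode="fixed", c_value=c_fix, cgs=cgs),
    }


def nested_f_reparam(reduced: ReparamFitResult, full: ReparamFitResult):
    """Nested F test between two crossover fits on the same data.

    Returns (delta_r2, f, (dk, df_resid_full), p).
    """
    if reduced.n != full.n:
        raise ValueError("fits use different sample sizes")
    dk = full.n_mean_params - reduced.n_mean_params
    if dk <= 0:
        raise ValueError("full model must have more parameters than reduced")
    df_resid = full.df_resid
    f = max(reduced.rss - full.rss, 0.0) / dk / (full.rss / df_resid)
    p = float(stats.f.sf(f, dk, df_resid))
    return float(full.r2 - reduced.r2), float(f), (dk, df_resid), p


# ---------------------------------------------------------------------------
# model arbitration


@dataclass
class Classification:
    """Outcome of the confirmatory model comparison."""

    selected_model: str | None
    family: str  # differential_susceptibility | diathesis_stress | none
    strength: str  # strong | weak | n/a
    shape: str  # disordinal | ordinal | n/a
    evidence: list[dict]
    gate_passed: bool


def _ci_inside(c_hat, ci, pe_range) -> bool:
    lo, hi = pe_range
    return ci is not None and lo < ci[0] and ci[1] < hi and lo < c_hat < hi


def compare_models(
    fits: dict[str, ReparamFitResult],
    gate_passed: bool,
    pe_range: tuple[float, float],
    alpha: float = 0.05,
) -> Classification:
    """Arbitrate among the fitted crossover models.

    Group branch (fits 3a-3d): within the free-C pair the strong model 3a
    is kept unless freeing the reference slope (3b) is significant at
    ``alpha``; likewise 3c vs 3d within the fixed-C pair.  The two
    finalists — which may share the same parameter count and hence cannot
    be F-tested — are compared by AIC and BIC jointly; if the criteria
    disagree the verdict is indeterminate (family "none").  The theoretical
    family then follows the winner: a fixed-C winner is an ordinal
    interaction (diathesis-stress); a free-C winner is disordinal
    (differential susceptibility) only when the crossover estimate and its
    entire CI lie inside the observed environment range, and ordinal
    otherwise.

    CGS branch (fits 3e, 3f): the free-C model 3e is accepted over 3f iff
    the nested F for freeing C has p < ``alpha``; shape and family follow
    the same rules.

    The whole procedure requires the exploratory gate (interaction
    F ratio > 1.0); with the gate failed no model is selected.
    """
    evidence: list[dict] = []
    if not gate_passed:
        return Classification(
            selected_model=None, family="none", strength="n/a", shape="n/a",
            evidence=[{"comparison": "gate", "statistic": None,
                       "decision": "interaction F ratio <= 1.0: no model evaluated"}],
            gate_passed=False,
        )

    if {"3a", "3b", "3c", "3d"} <= set(fits):
        dr2, f_ab, df_ab, p_ab = nested_f_reparam(fits["3a"], fits["3b"])
        free_finalist = "3b" if p_ab < alpha else "3a"
        evidence.append({"comparison": "3a_vs_3b", "delta_r2": dr2, "f": f_ab,
                         "df": df_ab, "p": p_ab, "decision": free_finalist})
        dr2, f_cd, df_cd, p_cd = nested_f_reparam(fits["3c"], fits["3d"])
        fixed_finalist = "3d" if p_cd < alpha else "3c"
        evidence.append({"comparison": "3c_vs_3d", "delta_r2": dr2, "f": f_cd,
                         "df": df_cd, "p": p_cd, "decision": fixed_finalist})
        a, b = fits[free_finalist], fits[fixed_finalist]
        aic_pick = free_finalist if a.aic < b.aic else fixed_finalist
        bic_pick = free_finalist if a.bic < b.bic else fixed_finalist
        evidence.append({"comparison": f"{free_finalist}_vs_{fixed_finalist}_aic",
                         "statistic": (a.aic, b.aic), "decision": aic_pick})
        evidence.append({"comparison": f"{free_finalist}_vs_{fixed_finalist}_bic",
                         "statistic": (a.bic, b.bic), "decision": bic_pick})
        if aic_pick != bic_pick:
            return Classification(
                selected_model=None, family="none", strength="n/a", shape="n/a",
                evidence=evidence + [{"comparison": "final",
                                      "decision": "indeterminate: AIC and BIC disagree"}],
                gate_passed=True,
            )
        winner = aic_pick
        strength = "strong" if fits[winner].strong else "weak"
    elif {"3e", "3f"} <= set(fits):
        dr2, f_ef, df_ef, p_ef = nested_f_reparam(fits["3f"], fits["3e"])
        winner = "3e" if p_ef < alpha else "3f"
        evidence.append({"comparison": "3e_vs_3f", "delta_r2": dr2, "f": f_ef,
                         "df": df_ef, "p": p_ef, "decision": winner})
        strength = "n/a"
    else:
        raise ValueError("fits must contain {3a,3b,3c,3d} or {3e,3f}")

    w = fits[winner]
    if w.c_fixed:
        shape = "ordinal"
    elif not w.identified:
        shape = "n/a"
    else:
        shape = "disordinal" if _ci_inside(w.c_hat, w.c_ci, pe_range) else "ordinal"
    if shape == "disordinal":
        family = "differential_susceptibility"
    elif shape == "ordinal":
        family = "diathesis_stress"
    else:
        family = "none"
    evidence.append({"comparison": "shape", "statistic": (w.c_hat, w.c_ci),
                     "pe_range": pe_range, "decision": shape})
    return Classification(
        selected_model=winner, family=family, strength=strength,
        shape=shape, evidence=evidence, gate_passed=True,
    )


def predicted_surface(
    fit: ReparamFitResult,
    pe_grid,
    gene_levels=(0, 1, 2),
    age: float = 116.34,
    sex: float = 0.5,
) -> pd.DataFrame:
    """Predicted phenotype across the environment grid per genotype level.

    At PE = C all levels predict the same value (the definition of the
    crossover); for disordinal fits the ordering of levels below C is the
    reverse of the ordering above it.
    """
    rows = []
    for g in gene_levels:
        pe = np.asarray(pe_grid, dtype=float)
        pred = fit.predict(pe, np.full(len(pe), g), np.full(len(pe), age),
                           np.full(len(pe), sex))
        for x, yhat in zip(pe, pred):
            rows.append(dict(pe=float(x), level=float(g), predicted=float(yhat)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# re-parameterization identity with the exploratory linear model


@dataclass(frozen=True)
class CommonCrossover:
    """Crossover form of a product-term linear fit.

    The linear interaction model a0 + a1*X1 + a2*T + a3*(X1 x T) (+covars)
    with numeric T is exactly a common-crossover model whose group slopes
    are equally spaced (a1, a1+a3, a1+2a3) and whose crossover is
    C = -a2/a3.
    """

    c: float
    a0: float
    slopes: tuple[float, float, float]
    age_slope: float
    sex_slope: float

    def predict(self, pe, t, age, sex) -> np.ndarray:
        pe = np.asarray(pe, dtype=float)
        slope = np.asarray(self.slopes)[np.asarray(t, dtype=int)]
        return (
            self.a0
            + slope * (pe - self.c)
            + self.age_slope * np.asarray(age, dtype=float)
            + self.sex_slope * np.asarray(sex, dtype=float)
        )


def linear_to_crossover(
    fit: LinearFitResult, gene_term: str = "t", product_term: str = "pe_x_t"
) -> CommonCrossover:
    """Map an exploratory interaction fit to its common-crossover form."""
    a0 = float(fit.params["const"])
    a1 = float(fit.params["pe"])
    a2 = float(fit.params[gene_term])
    a3 = float(fit.params[product_term])
    if a3 == 0.0:
        raise ValueError("zero product coefficient: crossover undefined")
    c = -a2 / a3
    return CommonCrossover(
        c=c,
        a0=a0 + a1 * c,
        slopes=(a1, a1 + a3, a1 + 2 * a3),
        age_slope=float(fit.params.get("age", 0.0)),
        sex_slope=float(fit.params.get("sex", 0.0)),
    )
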