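"""Synthetic cohort generator for G×E crossover analyses.

Generates cohorts with the statistical structure the downstream analysis
assumes: biallelic genotypes in Hardy-Weinberg equilibrium at given minor
allele frequencies, parental education (PE) as the mean of two integer 1-8
parent levels, age in months, balanced sex, and a phenotype produced by any
of the competing theoretical G×E models:

``strong_ds`` / ``weak_ds``
    differential susceptibility — genotype-group regression lines cross at
    an environment value C inside the observed PE range; the strong variant
    pins the zero-risk-allele group's slope at 0;
``strong_dis`` / ``weak_dis``
    diathesis-stress — the crossover is pushed to the top of the
    environment scale, C = mean(PE) + 3*SD(PE);
``null``
    no interaction — every group shares the same environment slope.

Default generative coefficients mirror the published strong
differential-susceptibility fit for rs281238 (intercept -0.90, group slopes
0 / 2.49 / 3.27, crossover 3.21, age slope 0.91, sex slope -2.53), and the
default residual SD is calibrated so that the correctly specified model
explains R² ≈ 0.26 of the phenotype at n = 1477.

An optional gene-environment correlation (rGE) of a chosen level can be
injected into one SNP via a Gaussian copula that leaves both marginal
distributions (HWE genotype proportions, the PE grid law) exactly intact.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gxecross.cohort import Cohort
from gxecross.datasets import dyslexia_snp_panel
from gxecross.qc import compute_cgs

__all__ = [
    "GenParams",
    "SimConfig",
    "MODEL_IDS",
    "calibrate_parent_probs",
    "default_parent_probs",
    "calibrate_sigma",
    "gen_genotypes",
    "gen_environment",
    "gen_ages",
    "gen_phenotype",
    "gen_cohort",
]

MODEL_IDS = ("strong_ds", "weak_ds", "strong_dis", "weak_dis", "null")

#: Study-cohort anchors: PE mean and SD (the SD implied by the fixed
#: diathesis-stress crossover mean+3SD = 6.85 with mean 3.21).
PE_MEAN = 3.21
PE_SD = (6.85 - 3.21) / 3.0

#: Default residual SD, calibrated (see :func:`calibrate_sigma`) so that the
#: correctly specified strong differential-susceptibility fit reaches
#: R² ≈ 0.257 at n = 1477 under the default coefficients below.
DEFAULT_SIGMA = 19.4

#: Default risk-allele frequencies for the nine-SNP panel; rs281238 is set
#: to its study-cohort value 0.398, the others to plausible common-variant
#: frequencies (all well above the 0.02 MAF QC floor).
DEFAULT_MAFS = (0.25, 0.398, 0.31, 0.18, 0.22, 0.35, 0.28, 0.40, 0.15)

_AGE_BOUNDS = (84.0, 156.0)  # months; grades 3-6 plausibility window


@dataclass(frozen=True)
class GenParams:
    """Generative coefficients of the crossover mean structure.

    The phenotype is Y = intercept + slope_i * (PE_i - C)
    + age_slope * Age_i + sex_slope * Sex_i + eps_i, where for the
    genotype-group form slope_i = group_slopes[T_i] (T = risk dosage of the
    target SNP) and for the linear-by-linear form slope_i =
    linear_slopes[0] + linear_slopes[1] * CGS_i.
    """

    intercept: float = -0.90
    group_slopes: tuple[float, float, float] = (0.0, 2.49, 3.27)
    linear_slopes: tuple[float, float] = (0.0, 0.52)
    crossover: float = 3.21
    age_slope: float = 0.91
    sex_slope: float = -2.53


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort."""

    n: int = 1477
    mafs: tuple[float, ...] = DEFAULT_MAFS
    snp_ids: tuple[str, ...] = tuple(dyslexia_snp_panel()["snp_id"])
    pe_parent_probs: tuple[float, ...] | None = None  # None -> calibrated default
    age_mean_months: float = 116.34
    age_sd_months: float = 12.14
    sex_balance: float = 0.5  # fraction coded 1 (female); 0 = male
    model_id: str = "strong_ds"
    form: str = "groups"  # "groups" (single-SNP Tx) or "linear" (CGS)
    target_snp: str = "rs281238"
    params: GenParams = field(default_factory=GenParams)
    sigma: float = DEFAULT_SIGMA
    rge_r: float = 0.0
    rge_snp: str | None = None  # defaults to target_snp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.mafs) != len(self.snp_ids):
            raise ValueError("mafs and snp_ids must have equal length")
        for m in self.mafs:
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"maf {m} outside [0, 1]")
        if self.pe_parent_probs is not None:
            p = np.asarray(self.pe_parent_probs, dtype=float)
            if p.shape != (8,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("pe_parent_probs must be 8 nonnegative values summing to 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if self.form not in ("groups", "linear"):
            raise ValueError("form must be 'groups' or 'linear'")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must lie in [0, 1]")
        if not -1.0 < self.rge_r < 1.0:
            raise ValueError("rge_r must lie in (-1, 1)")
        if self.target_snp not in self.snp_ids:
            raise ValueError(f"target_snp {self.target_snp!r} not in snp_ids")

    @property
    def parent_probs(self) -> np.ndarray:
        if self.pe_parent_probs is not None:
            return np.asarray(self.pe_parent_probs, dtype=float)
        return default_parent_probs()


# ---------------------------------------------------------------------------
# marginal generators


def gen_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """Draw n additive dosages i.i.d. from Hardy-Weinberg proportions.

    P(2) = maf², P(1) = 2 maf (1-maf), P(0) = (1-maf)² — i.e. each dosage is
    Binomial(2, maf).  ``seed`` may be an int or a numpy Generator.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf {maf} outside [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(2, maf, size=n).astype(float)


@functools.lru_cache(maxsize=16)
def _calibrated_probs_cached(mean: float, sd: float) -> tuple[float, ...]:
    levels = np.arange(1, 9, dtype=float)
    target_var = sd**2

    def natural_params_to_probs(ab):
        a, b = ab
        logw = a * levels + b * levels**2
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def moments_gap(ab):
        p = natural_params_to_probs(ab)
        mu = float(p @ levels)
        var = float(p @ (levels - mu) ** 2)
        return [mu - mean, var - target_var]

    sol = optimize.root(moments_gap, x0=[0.0, -0.05], method="hybr")
    if not sol.success:
        raise RuntimeError(f"parent-level calibration failed: {sol.message}")
    probs = natural_params_to_probs(sol.x)
    return tuple(float(x) for x in probs)


def calibrate_parent_probs(pe_mean: float = PE_MEAN, pe_sd: float = PE_SD) -> np.ndarray:
    """Probability vector over parent education levels 1-8, moment-matched.

    Returns the maximum-entropy distribution (exponential family in level
    and level²) whose single-parent mean is ``pe_mean`` and whose
    single-parent SD is ``pe_sd * sqrt(2)``, so that the mean of two
    independent parents has mean ``pe_mean`` and SD ``pe_sd``.
    """
    return np.asarray(_calibrated_probs_cached(float(pe_mean), float(pe_sd * np.sqrt(2.0))))


def default_parent_probs() -> np.ndarray:
    """Default parent-level distribution (PE mean 3.21, PE SD 1.213)."""
    return calibrate_parent_probs()


def gen_environment(n: int, pe_parent_probs=None, seed=0, return_parents: bool = False):
    """Parental education as the mean of two independent 1-8 parent levels.

    Values therefore lie on the 0.5-step grid in [1, 8].  With
    ``return_parents=True`` also returns the father/mother level vectors.
    """
    probs = (
        np.asarray(pe_parent_probs, dtype=float)
        if pe_parent_probs is not None
        else default_parent_probs()
    )
    if probs.shape != (8,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("pe_parent_probs must be 8 nonnegative values summing to 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    levels = np.arange(1, 9)
    father = rng.choice(levels, size=n, p=probs)
    mother = rng.choice(levels, size=n, p=probs)
    pe = (father + mother) / 2.0
    if return_parents:
        return pe, father, mother
    return pe


def gen_ages(n: int, mean: float = 116.34, sd: float = 12.14, seed=0) -> np.ndarray:
    """Age in months, normal truncated to the grades-3-6 window [84, 156]."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = _AGE_BOUNDS
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# gene-environment correlation injection (Gaussian copula)


def _pe_pmf(parent_probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PMF of PE = mean of two i.i.d. parent levels, on the 0.5-step grid."""
    conv = np.convolve(parent_probs, parent_probs)  # sums 2..16
    values = np.arange(2, 17) / 2.0
    keep = conv > 0
    return values[keep], conv[keep]


def _copula_corr(rho: float, x_vals, x_probs, y_vals, y_probs) -> float:
    """Pearson correlation of two discrete margins coupled by a Gaussian copula."""
    zx = np.concatenate(([-9.0], stats.norm.ppf(np.cumsum(x_probs)[:-1]), [9.0]))
    zy = np.concatenate(([-9.0], stats.norm.ppf(np.cumsum(y_probs)[:-1]), [9.0]))
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    pts = np.array([[x, y] for x in zx for y in zy])
    F = mvn.cdf(pts).reshape(len(zx), len(zy))
    cells = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    exy = float(np.einsum("i,j,ij->", x_vals, y_vals, cells))
    mx = float(x_vals @ x_probs)
    my = float(y_vals @ y_probs)
    sx = float(np.sqrt(x_probs @ (x_vals - mx) ** 2))
    sy = float(np.sqrt(y_probs @ (y_vals - my) ** 2))
    return (exy - mx * my) / (sx * sy)


@functools.lru_cache(maxsize=32)
def _latent_rho_cached(target_r: float, maf: float, probs_key: tuple) -> float:
    parent_probs = np.asarray(probs_key)
    q = 1.0 - maf
    x_vals = np.array([0.0, 1.0, 2.0])
    x_probs = np.array([q**2, 2 * maf * q, maf**2])
    y_vals, y_probs = _pe_pmf(parent_probs)

    def gap(rho):
        return _copula_corr(rho, x_vals, x_probs, y_vals, y_probs) - target_r

    return float(optimize.brentq(gap, -0.9995, 0.9995, xtol=1e-6))


def _split_pe_into_parents(pe: np.ndarray, parent_probs: np.ndarray, rng) -> tuple:
    """Sample (father, mother) levels conditional on their observed mean."""
    levels = np.arange(1, 9)
    father = np.empty(len(pe), dtype=int)
    totals = np.round(pe * 2).astype(int)
    for total in np.unique(totals):
        fs = levels[(levels >= total - 8) & (levels <= total - 1) & (levels <= 8)]
        fs = fs[(total - fs >= 1) & (total - fs <= 8)]
        w = parent_probs[fs - 1] * parent_probs[total - fs - 1]
        if w.sum() <= 0:
            raise ValueError(f"PE total {total} impossible under parent_probs")
        w = w / w.sum()
        mask = totals == total
        father[mask] = rng.choice(fs, size=mask.sum(), p=w)
    mother = totals - father
    return father, mother


def _gen_correlated_snp_pe(n, maf, parent_probs, target_r, rng):
    """Jointly draw one SNP's dosages and PE at Pearson correlation target_r.

    Latent bivariate-normal thresholding: both marginals are exact (HWE
    genotype law, PE grid law); the latent correlation is pre-attenuated so
    the realized discrete-scale Pearson correlation matches the target.
    """
    rho = _latent_rho_cached(float(target_r), float(maf), tuple(parent_probs))
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    u = stats.norm.cdf(z)
    q = 1.0 - maf
    x_cuts = np.cumsum([q**2, 2 * maf * q])
    dosage = np.searchsorted(x_cuts, u[:, 0]).astype(float)
    y_vals, y_probs = _pe_pmf(parent_probs)
    y_cuts = np.cumsum(y_probs)[:-1]
    pe = y_vals[np.searchsorted(y_cuts, u[:, 1])]
    return dosage, pe


# ---------------------------------------------------------------------------
# phenotype


def true_structure(config: SimConfig, pe: np.ndarray, gene: np.ndarray):
    """Per-individual environment slope and the crossover C implied by config.

    ``gene`` is the target-SNP dosage (groups form) or the CGS (linear
    form).  Diathesis-stress models place C at mean(PE) + 3*SD(PE) of the
    realized sample; the others use ``params.crossover``.
    """
    p = config.params
    if config.model_id.endswith("_dis"):
        c = float(np.mean(pe) + 3.0 * np.std(pe, ddof=1))
    else:
        c = float(p.crossover)
    if config.form == "groups":
        slopes = np.array(p.group_slopes, dtype=float)
        if config.model_id.startswith("strong"):
            slopes[0] = 0.0
        if config.model_id == "null":
            slopes[:] = slopes[1]
        slope_i = slopes[gene.astype(int)]
    else:
        a1, a2 = (float(x) for x in p.linear_slopes)
        if config.model_id.startswith("strong"):
            a1 = 0.0
        if config.model_id == "null":
            a2 = 0.0
        slope_i = a1 + a2 * gene
    return slope_i, c


def gen_phenotype(cohort: Cohort, config: SimConfig, rng=None) -> np.ndarray:
    """Phenotype under the configured generative model.

    Y = A0 + slope(gene) * (PE - C) + A_age*Age + A_sex*Sex + eps,
    eps ~ Normal(0, sigma²).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    gene = cohort.dosage(config.target_snp) if config.form == "groups" else np.asarray(cohort.cgs)
    slope_i, c = true_structure(config, cohort.pe, gene)
    p = config.params
    signal = (
        p.intercept
        + slope_i * (cohort.pe - c)
        + p.age_slope * cohort.age
        + p.sex_slope * cohort.sex
    )
    return signal + rng.normal(0.0, config.sigma, size=cohort.n)


# ---------------------------------------------------------------------------
# full cohort


def gen_cohort(config: SimConfig, out_dir=None) -> Cohort:
    """Assemble a full synthetic cohort; deterministic under ``config.seed``.

    Genotypes, environment, age/sex and residual noise use independent
    substreams spawned from the single seed, so any stage can be
    regenerated in isolation.  When ``out_dir`` is given, the phenotype CSV
    and the additive dosage table are written there (see
    :mod:`gxecross.io`).
    """
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_env, r_agesex, r_noise = (np.random.default_rng(s) for s in ss.spawn(4))
    n = config.n
    parent_probs = config.parent_probs

    rge_snp = config.rge_snp or config.target_snp
    dosage_cols = {}
    if config.rge_r != 0.0:
        maf = config.mafs[config.snp_ids.index(rge_snp)]
        corr_dosage, pe = _gen_correlated_snp_pe(n, maf, parent_probs, config.rge_r, r_env)
        father, mother = _split_pe_into_parents(pe, parent_probs, r_env)
        dosage_cols[rge_snp] = corr_dosage
    else:
        pe, father, mother = gen_environment(n, parent_probs, r_env, return_parents=True)

    for snp, maf in zip(config.snp_ids, config.mafs):
        if snp not in dosage_cols:
            dosage_cols[snp] = gen_genotypes(n, maf, r_geno)
    dosages = pd.DataFrame({snp: dosage_cols[snp] for snp in config.snp_ids})

    age = gen_ages(n, config.age_mean_months, config.age_sd_months, r_agesex)
    sex = (r_agesex.random(n) < config.sex_balance).astype(int)
    ids = np.array([f"S{i + 1:06d}" for i in range(n)])

    cohort = Cohort(
        ids=ids,
        phenotype=np.zeros(n),
        pe=pe,
        age=age,
        sex=sex,
        dosages=dosages,
        cgs=compute_cgs(dosages),
        pe_father=father,
        pe_mother=mother,
    )
    cohort.phenotype = gen_phenotype(cohort, config, r_noise)

    gene = cohort.dosage(config.target_snp) if config.form == "groups" else np.asarray(cohort.cgs)
    _, c_true = true_structure(config, pe, gene)
    cohort.meta = {
        "model_id": config.model_id,
        "form": config.form,
        "target_snp": config.target_snp,
        "true_crossover": c_true,
        "sigma": config.sigma,
        "seed": config.seed,
    }

    if out_dir is not None:
        from gxecross import io

        io.write_cohort(cohort, out_dir, dyslexia_snp_panel())
    return cohort


# ---------------------------------------------------------------------------
# noise calibration


def calibrate_sigma(
    config: SimConfig,
    target_r2: float = 0.2567,
    n_probe: int = 20000,
    method: str = "bisect",
    tol: float = 1e-3,
) -> float:
    """Residual SD such that the correctly specified fit reaches ``target_r2``.

    ``method="moment"`` uses the closed form sigma² = Var(signal) *
    (1/R² - 1) with the signal variance measured on one large noiseless
    probe cohort.  ``method="bisect"`` refines that value by bisection on
    the fitted R² of the true-design OLS fit at fixed latent draws, which
    is monotone in sigma and therefore converges.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must lie in (0, 1)")
    probe_cfg = replace(config, n=n_probe, sigma=0.0)
    cohort = gen_cohort(probe_cfg)
    signal = cohort.phenotype  # sigma=0: phenotype is the pure signal
    var_sig = float(np.var(signal, ddof=1))
    sigma0 = float(np.sqrt(var_sig * (1.0 / target_r2 - 1.0)))
    if method == "moment":
        return sigma0
    if method != "bisect":
        raise ValueError("method must be 'moment' or 'bisect'")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    eps = rng.standard_normal(n_probe)
    gene = (
        cohort.dosage(config.target_snp) if config.form == "groups" else np.asarray(cohort.cgs)
    )
    slope_i, c = true_structure(config, cohort.pe, gene)
    # true-design regressors (group indicators x centred PE, or linear form)
    cols = [np.ones(n_probe)]
    if config.form == "groups":
        for t in (0, 1, 2):
            cols.append((gene == t) * (cohort.pe - c))
    else:
        cols.append(cohort.pe - c)
        cols.append((cohort.pe - c) * gene)
    cols += [cohort.age, cohort.sex]
    X = np.column_stack(cols)

    def fitted_r2(sigma):
        y = signal + sigma * eps
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    lo, hi = sigma0 / 4.0, sigma0 * 4.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if fitted_r2(mid) > target_r2:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
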