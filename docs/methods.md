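# Methods

## The statistical problem

A quantitative phenotype Y (a reading score on a 0–150 count scale) is
modelled as a function of an environment score X1 (parental education, PE:
the mean of two integer 1–8 parent levels, so a 0.5-step grid in [1, 8]),
a genetic variable — either the additive risk-allele dosage T ∈ {0, 1, 2}
of one SNP or a cumulative genetic score X2 (unweighted sum of risk
dosages over a panel) — and the covariates age (months) and sex (0 = male,
1 = female). Two questions are asked in sequence:

1. *Is there an interaction at all?* Exploratory moderated regression with
   a product term, tested by the nested-F on ΔR².
2. *What shape does it take?* Confirmatory crossover regression, which
   re-parameterizes the interaction in terms of the environment value C at
   which all genotype groups are expected to score equally.

The two competing theories make sharply different predictions about C.
Under **differential susceptibility**, susceptible genotypes are worse off
than non-carriers in poor environments and better off in rich ones: the
group regression lines cross *inside* the observed environment range
(disordinal interaction). Under **diathesis–stress**, risk carriers are
harmed by poor environments but never overtake non-carriers: the lines
cross at or beyond the top of the environment scale (ordinal interaction).
*Strong* variants of either theory constrain the zero-risk-allele group's
environment slope to zero (non-carriers unaffected by environment); *weak*
variants leave it free.

## Model taxonomy and decision procedure

Six crossover models are fitted:

| model | form | C | reference slope |
|---|---|---|---|
| 3a | genotype groups | free | fixed at 0 (strong) |
| 3b | genotype groups | free | free (weak) |
| 3c | genotype groups | fixed at mean+3SD | fixed at 0 (strong) |
| 3d | genotype groups | fixed at mean+3SD | free (weak) |
| 3e | linear-by-linear (CGS) | free | — |
| 3f | linear-by-linear (CGS) | fixed at mean+3SD | — |

The decision procedure (`compare_models`) is gated by the exploratory
interaction F ratio exceeding 1.0 — with less evidence than that, no
theoretical model is evaluated. Within the free-C pair the strong model is
kept unless freeing the reference slope is significant at α = 0.05 (nested
F, 1 df); likewise within the fixed-C pair. The two finalists often have
equal parameter counts and cannot be F-tested; they are compared by AIC
and BIC jointly, and if the two criteria disagree the verdict is reported
as indeterminate rather than silently resolved (the implementation never
breaks such a tie). The theoretical family then follows the winner: a
fixed-C winner is ordinal (diathesis–stress) by construction; a free-C
winner is disordinal (differential susceptibility) only when the estimate
Ĉ *and its entire 95% CI* lie strictly inside the observed environment
range [min X1, max X1] — a CI touching either end is classified ordinal.
For the CGS branch, the free-C model 3e is accepted over 3f iff the 1-df
nested F for freeing C has p < 0.05.

## Estimation

Given C every model is linear, so free-C models are estimated by
**profiling**: RSS(C) is evaluated on a coarse grid (step 0.05) spanning
[min(X1) − 2·SD, max(X1) + 2·SD], and the best grid point is refined by
bounded scalar minimization to an absolute tolerance of 1e-8. At each
candidate C the linear coefficients are the exact least-squares solution,
which removes the initialization sensitivity and convergence failures of
joint gradient-based NLS. The profile is declared *flat* — C unidentified,
as happens when the gene-by-environment slope term is zero — when the
relative RSS variation across the grid is below 1e-10; the fit is then
returned flagged, without a standard error for C.

Standard errors come from the Gauss–Newton covariance σ̂²(JᵀJ)⁻¹ at the
optimum, where J appends to the design the derivative of the mean with
respect to C (−slopeᵢ per individual) and σ̂² = RSS/(n − p) with p counting
C when free. The C-block of this matrix is algebraically the inverse
curvature of the profiled objective (a Schur complement), so it equals the
numeric profile Hessian without finite-difference noise. 95% CIs are Wald,
Ĉ ± 1.959964·SE. Because Wald intervals are fragile near flat profiles, a
profile-likelihood CI (inverting the 1-df F test on the RSS ratio) is
available via `profile_ci=True`.

Degrees of freedom: model df excludes the intercept and counts C when
free; e.g. at n = 1477 model 3a has df (5, 1471) and 3c has (4, 1472).

Information criteria use the least-squares forms AIC = n·ln(RSS/n) + 2k
and BIC = n·ln(RSS/n) + k·ln(n) with k = mean parameters + 1 (residual
variance). Absolute values are therefore not comparable to
likelihood-based AICs from other software, but differences and rankings —
the only things the procedure uses — are well defined, and for models with
equal k both criteria rank exactly by RSS.

An exact identity ties the two stages together: the exploratory model with
numeric T and a product term is itself a common-crossover model with
equally spaced slopes (A1, A1+A3, A1+2A3) and C = −A2/A3
(`linear_to_crossover`); the test suite verifies the fitted values agree
to 1e-8, and that profiling matches an exhaustive 0.001-step grid search.

## Supporting stages

**HWE test.** χ² goodness of fit of the three genotype counts against
(q², 2pq, p²) at the sample allele frequency. The default reference
distribution uses df = 1 (one df spent on the estimated frequency), the
statistically standard choice; a df = 2 "paper mode" treats the three
categories as a plain multinomial fit, which is how the published p-values
for this panel were produced. QC thresholds: call rate ≥ 0.95, MAF ≥ 0.02,
HWE p ≥ 1e-5; flags are non-destructive.

**CGS.** Unweighted sum of risk dosages; published betas (including the
one negative-beta SNP, rs764255) are metadata and never weight the score.
SNPs with negative source betas are coded by their printed risk allele
as-is.

**rGE screen.** Two-sided Pearson test of each SNP (and the CGS) against
X1; SNPs with p < 0.05 are excluded and the CGS is recomputed on the
retained panel. Constant inputs are flagged "undefined" rather than
raised, so panel screening is robust to degenerate columns.

**Bonferroni.** Applied to the interaction-term p-values only, with m the
number of SNPs surviving the screen.

## The synthetic-cohort generator

The generator reproduces the *assumed* statistical structure of the study
data; its defaults are the study's own printed anchors:

- **Genotypes:** i.i.d. Binomial(2, MAF) — exact HWE sampling. Default
  panel: the nine reading/dyslexia SNPs, with rs281238 at its observed
  risk-allele frequency 0.398 and plausible common-variant frequencies for
  the rest.
- **Environment:** each parent's level drawn from a maximum-entropy
  distribution on {1..8} moment-matched so that PE = (father+mother)/2 has
  mean 3.21 and SD 1.2133 (the SD implied by the study's fixed
  diathesis–stress crossover mean+3SD = 6.85). The true parent-level
  histogram is unpublished; only these two moments are matched.
- **Age:** Normal(116.34, 12.14) months truncated to [84, 156] (grades
  3–6 plausibility). **Sex:** Bernoulli(0.5).
- **Phenotype:** Y = A0 + slope(gene)·(X1 − C) + 0.91·Age − 2.53·Sex + ε
  with ε ~ N(0, σ²). Defaults mirror the published strong-DS fit:
  A0 = −0.90, group slopes (0, 2.49, 3.27), C = 3.21. Diathesis–stress
  model ids move C to mean(X1)+3·SD(X1) of the realized sample; the null
  model gives every group the middle-group slope (2.49), i.e. an
  environment main effect with zero interaction. The default residual
  σ = 19.4 was fixed once by the bisection calibrator
  (`calibrate_sigma`) so that the correctly specified model reaches
  R² ≈ 0.257 at n = 1477 — the study's only printed noise anchor.
- **rGE injection:** a Gaussian copula couples one SNP's dosage with PE at
  a requested Pearson correlation: correlated latent normals are
  thresholded through the exact marginal quantile functions, so both
  marginal laws (HWE proportions, the PE grid pmf) are preserved exactly,
  and the latent correlation is pre-attenuated by exact bivariate-normal
  cell-probability calibration so the realized discrete-scale correlation
  hits the target. Parent levels are then drawn conditional on their
  realized mean.

What the generator does **not** emulate: genotyping error, missingness
patterns, linkage disequilibrium between panel SNPs, floor/ceiling effects
of the 0–150 instrument, non-normal residuals, and any structural (active
or evocative) rGE mechanism. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the assumed
model, not robustness to those real-data features.

## Reproducibility and numerical conventions

A single seed feeds a `SeedSequence` whose spawned substreams drive
genotypes, environment, age/sex and residual noise separately, so stages
can be regenerated in isolation; pipeline outputs are byte-identical under
identical configuration and seed. Validation sample sizes were chosen to
keep the full suite within a few minutes on one CPU: n = 300–400 for
algebraic-identity and oracle checks (which hold at any n), and the study
scale n = 1477 for operating characteristics (500-replicate recovery,
2000-replicate type-I, 200-replicate selection consistency).

## Known limitations

- SE(C) is a large-sample Wald quantity; for weakly identified crossovers
  (small interaction effects) the profile-likelihood CI should be
  preferred.
- The fixed-C rule mean+3SD is a convention for "top of scale"; the
  observed maximum is available as an alternative (`observed_max`) and the
  two can disagree when the environment distribution is short-tailed.
- No robust/clustered standard errors, no mixed models, no exact
  (Wigginton-type) HWE test, no bootstrap CIs, and no quadratic-in-E
  extensions of the crossover framework.
- The decision procedure controls each pairwise comparison at α but makes
  no claim of family-wise error control over the whole model-selection
  path; the selection-consistency simulations quantify its behaviour under
  the two generative truths instead.
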