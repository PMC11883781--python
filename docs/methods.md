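# Methods

`latentgen` implements an individual-level pipeline for studying the shared
architecture of co-occurring symptom domains — here eating-disorder symptom
scores (AN, BN, BED) and three suicidal-ideation items (TAF1–3) — from
questionnaire items through latent-variable models to genome-wide variance
components. This note records the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Phenotype preparation

Symptom scores are sums of item responses (higher = more/more severe
symptoms). By default a score is missing whenever any of its items is
missing; proration (mean of observed items × item count) is available but
off, since summation behaviour for partial responses is a survey-design
choice, not a statistical one. Every analysis variable is residualized on
an intercept plus age, sex, genotyping batch and 10 ancestry principal
components *before* any latent modelling or genetic analysis; downstream
stages therefore fit intercept-only fixed-effect structures. Residualization
is ordinary least squares per column; rows with missing covariates are
excluded from fitting and flagged. The EFA/CFA split is a simple seeded
random partition (default 70/30) without stratification.

## Latent models

All confirmatory models are covariance-structure models
`Sigma = Lambda Phi Lambda' + Theta` with saturated (free) means and
unit-variance identification for every latent, including the second-order
factor — so free factor covariances are correlations and standardized
solutions are comparable across the model zoo:

- **two_factor** — correlated ED and SI factors (df = 8 on six
  indicators).
- **hierarchical** — ED and SI load on a second-order general
  susceptibility factor. With two first-order factors the second-order
  loadings are not separately identified (two loadings for one covariance
  moment), so they are constrained equal; the model then spans the same
  covariance structures as `two_factor` restricted to a non-negative
  factor correlation.
- **residual** — a bifactor model: one general factor over all six
  indicators plus ED-specific and SI-specific factors, all mutually
  orthogonal (df = 3). An optional equality constraint on each specific
  factor's loadings exists (off by default) because three-indicator
  specific factors can be empirically under-identified; non-convergence is
  reported, never silently repaired.
- **four_factor** — restricting, purging, bingeing and SI factors, all
  correlated (6 free correlations). AN/BN/BED are single-indicator
  factors, identified by fixing their residual variances to zero (the
  factor is the observed score up to scale).

Each structure exists with and without depression (PHQ8) and anxiety
(GAD7) sum scores: `replace_general` loads them on the general or SI
factor (turning it into a broad psychopathology factor), and
`separate_factor` gives them their own factor (tied loadings when that
factor would otherwise be under-identified with two indicators).

**Estimation.** The default estimator is full-information maximum
likelihood: the casewise normal log-likelihood over each observation's
observed indicator subset, valid under MAR missingness. Observations
sharing a missingness pattern share sufficient statistics, so one
likelihood evaluation costs O(#patterns) regardless of n. Optimization is
L-BFGS-B on the free parameters with analytic gradients (verified against
finite differences in the test suite); starting values are moment-based
(loadings scaled to ~55% of each indicator's SD, factor correlations 0.2,
residuals at half the variance). If the implied covariance goes indefinite
during the search a minimal ridge is applied together with a penalty term
whose gradient steers the optimizer back into the PD cone; a ridge active
at the optimum is flagged. Convergence requires a per-case gradient
max-norm below 1e-5. Binary TAF items are modelled as continuous
endogenous variables under FIML — a deliberate approximation (categorical
FIML is out of scope) whose main effect is attenuation of TAF loadings
relative to a liability-scale analysis.

The likelihood-ratio statistic is `chi2 = 2(l_sat − l_model)`, where the
saturated mean/covariance MLE under missingness comes from EM (closed-form
E and M steps on pattern statistics; with complete data it reduces to the
sample moments in one step), clamped at zero if numerically negative. Fit
indices: RMSEA `sqrt(max(chi2−df,0)/(df(n−1)))` (0 and flagged when
df = 0), CFI and TLI against the independence baseline (whose FIML MLE
factorizes to per-variable observed-case moments), and SRMR as the RMS
standardized residual between the saturated and implied covariances,
diagonal included. A complete-case covariance-ML route (minimizing
`log|Sigma| + tr(S Sigma^{-1}) − log|S| − p` with a numeric gradient)
exists as an independent cross-check; with complete data the two routes
agree to 1e-6.

**EFA.** Maximum-likelihood extraction profiles the loadings out via the
eigenstructure of `Psi^{-1/2} R Psi^{-1/2}` and optimizes the uniquenesses
(bounded below at 0.005; hitting the bound flags a Heywood case, never a
crash), followed by oblique gradient-projection rotation with the oblimin
(quartimin) criterion. Factors are ordered by explained variance with
positive loading sums. The number of factors is user-chosen; Horn's
parallel analysis is provided as a seeded helper but never auto-selects.

**Factor scores.** Regression (Thomson) scores
`F = Phi Lambda' Sigma^{-1}(y − mu)` are computed per missingness pattern
on each case's observed subset (the default; Bartlett scores are the
documented alternative). Per-latent determinacy
`sqrt((Phi Lambda' Sigma^{-1} Lambda Phi)_jj / Phi_jj)` is reported
because it governs everything downstream: a GWAS of the scores sees SNP
effects attenuated by roughly the determinacy, and score-level SNP
heritability is attenuated by its square (times the share of score
variance attributable to the targeted latent).

## Genomic stages

**GRM.** `A_jk = (1/m) sum_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))`
with in-sample allele frequencies (no external reference panel). SNPs
failing MAF or missingness filters are excluded; missing dosages are
mean-imputed (contributing zero to a pair's numerator) and each pair is
averaged over the SNPs observed in both members. No relatedness pruning by
default (simulated samples are unrelated); GCTA-triad binary I/O is
provided for interoperability.

**AI-REML.** Univariate `V = A sg² + I se²` and bivariate
(six-component) REML maximize
`−½[log|V| + log|X'V^{-1}X| + y'Py]` with X an intercept (phenotypes
arrive residualized). The schedule is one EM step (univariate) or a damped
first update (bivariate), then average-information updates
`theta += AI^{-1} score` with step-halving on likelihood decrease,
variance floors at 1e-6·var(y), and an active-set rule: a component pinned
at its floor whose score points further down is frozen for that update so
the remaining components can still move. Convergence is declared at
|Δ logL| < 1e-6 — tighter than the 1e-4 a GCTA-style default would use, so
that estimates are sharp enough to compare against a brute-force grid
search at 0.005 resolution. Because every V in these models is a
polynomial in the single GRM, all solves run in the eigenbasis of A: one
O(n³) eigendecomposition, then O(n) per iteration (2×2 blocks per
eigenvalue in the bivariate case). SEs come from the inverse AI matrix;
h² and rG get delta-method SEs; |rG| > 1 is clamped and flagged. The
bivariate fit requires complete trait overlap (rows missing either trait
are dropped with their GRM rows); missing-one-trait support is future
work.

**GWAS.** Per-SNP OLS of the (residualized) score on A1 dosage with an
intercept and a two-sided t test, vectorized over SNPs; missing dosages
are mean-imputed per SNP by default (matching the GRM convention) or
dropped per SNP. Monomorphic SNPs are skipped with reason codes. The
genomic inflation factor is the median association χ² over 0.4549,
refused below 100 tests. Output mirrors the PLINK 2 `--glm` additive
layout. No mixed-model association and no multiple-testing machinery
beyond reporting.

**Power.** The power of bivariate GREML to detect a genetic correlation
uses the closed-form sampling variance for two quantitative traits on the
same n unrelated individuals,

    var(rG) = [(1 − rG·rP)² + (rG − rP)²] / (n² · v · h²₁ · h²₂),

with v the variance of the off-diagonal GRM entries (default 2e-5 for
conventionally unrelated samples), and
`power = P(chi²₁(ncp = rG²/var(rG)) > chi²₁ critical at alpha)`. The
expression is the exact delta-method collapse of the Haseman–Elston/GREML
asymptotics (the heritability-error and covariance terms combine into the
numerator shown), and the test suite verifies it against the empirical
sampling variance of REML estimates on a synthetic near-identity GRM
(agreement within a few percent). Two caveats follow from the derivation:
the formula is an A ≈ I asymptotic, so with dense desk-scale GRMs
(n comparable to m) the true sampling variance exceeds it; and at
n ≈ 20,000 with h² ≈ 0.07 it implies se(rG) ≈ 0.12 — consistent with the
empirical rG standard errors such studies report — which places the power
to detect rG = 0.5 near 1. A published claim of only a few percent power
at those inputs is not reproducible from this (or any variance-consistent)
closed form; the package reports what the formula yields.

## The synthetic-data generator

The generator is the ground-truth side of every test. It emulates:

- biallelic genotypes in Hardy–Weinberg proportions, MAF ~ U(0.05, 0.5),
  SNPs independent (no LD) — GREML with the standardized GRM is unbiased
  under this design and it keeps simulation desk-scale;
- per-SNP causal effects drawn multivariate-normally across latent genetic
  components with a specified genetic correlation matrix (all SNPs causal
  by default, so the GRM SNP set equals the causal set and the GREML
  estimand equals the generative h²); each latent's genetic value is
  rescaled to have empirical variance exactly h², its environmental
  complement exactly 1 − h², with the environmental correlation chosen to
  hit the target *phenotypic* factor correlation given the genetic one;
- continuous indicators `y = Lambda f + e` with residual variance
  1 − (row communality); AN/BN/BED (and PHQ8/GAD7) indicators are further
  decomposed into item columns that sum exactly to the score; TAF items
  are dichotomized at prevalence-matched liability thresholds
  (default prevalences 0.45/0.30/0.25, chosen once as plausible for a
  mental-health-enriched volunteer cohort; configurable);
- covariates: age ~ N(49.3, 17.56²), 71% female, a binary batch — matching
  the emulated cohort's descriptives — with small additive effects
  (standardized betas 0.10/0.15/0.05) injected into the indicators so
  residualization is testable; ancestry PCs are the top 10 PCs of the
  simulated genotypes, not independent noise;
- MCAR missingness (default 20%) applied at the questionnaire-score level,
  with item columns blanked alongside their score.

Default latent structures mirror the model zoo. The bifactor defaults use
deliberately *heterogeneous* loadings (general 0.65/0.55/0.45/0.70/0.60/
0.50; specifics 0.45–0.55): with uniform loadings a two-factor model
reproduces bifactor-generated covariances exactly and the model-selection
ordering would be untestable. The bifactor genetic correlations default to
0 between general and specifics and −0.40 between the two specific
factors' genetic components, mirroring the negative residual-factor
genetic correlation the emulated study reports.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium and MAF-dependent
architecture; ascertainment and case oversampling; ordinal/Likert item
scales (items are continuous decompositions); MNAR missingness; population
structure beyond PC plumbing; genotyping error. Recovery results here
certify the estimators, not the robustness of the study design to those
features.

## Problem sizes used in the checks

Recovery checks run at n = 2,000 individuals × 5,000 SNPs (variance
components; 25 replicates), n = 20,000 cases (factor models; 25
replicates), and n = 1,200 with a synthetic near-identity GRM for the
power-formula cross-check — sizes at which Monte-Carlo error is small
relative to the tolerances while a full run stays in the minutes range on
a single CPU. Heritabilities in the genetic-correlation check are set to
0.30 (rather than the study-scale ~0.09) so each replicate's rG estimate
has usable precision at n = 2,000; the rG recovery target itself is
unchanged.

## Known limitations

- Categorical endogenous variables are treated as continuous under FIML.
- The bivariate REML requires complete trait overlap and supports exactly
  two traits; there is no multi-component (MAF/LD-stratified) GREML, no
  unconstrained mode, and no BLUP.
- Factor-score GWAS is OLS, not a mixed model; with related samples or
  structure beyond the residualized PCs, lambda_GC will drift from 1.
- The EFA operates on the complete-case correlation matrix (FIML EFA is
  not implemented); with 20% MCAR across eight variables this can discard
  a substantial fraction of rows — the CFA stage, not the EFA, is the
  missing-data-aware estimator.
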