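# Methods

## Models

`megamet` compares three estimators of the standardized patient–control
difference in a continuous brain measure across K cohorts.

**Two-stage random-effects pooling (`meta_re`).** Within each eligible
cohort i, ordinary least squares of the outcome on an intercept, the
diagnosis indicator (control = 0, patient = 1) and the covariates gives
the diagnosis t-statistic tᵢ with dfᵢ = nᵢ − p residual degrees of
freedom. This is converted to Cohen's d by

    dᵢ = tᵢ (n₁ᵢ+n₂ᵢ) / (√(n₁ᵢ n₂ᵢ) √dfᵢ),

with the conventional large-sample variance

    vᵢ = (n₁ᵢ+n₂ᵢ)/(n₁ᵢ n₂ᵢ) + dᵢ²/(2(n₁ᵢ+n₂ᵢ−2)).

The source of the conversion prints only the t-to-d form; the vᵢ formula
is the standard companion and is stated here explicitly because the
pooling weights require it. Pooling is inverse-variance with weights
wᵢ = 1/(vᵢ + τ²); τ² maximizes the restricted log-likelihood

    ℓ_R(τ²) = −½ [ Σ ln(vᵢ+τ²) + ln Σ(vᵢ+τ²)⁻¹ + Σ wᵢ(dᵢ−μ̂)² ],

by the standard Fisher-scoring fixed point (convergence |Δτ²| < 1e-8,
cap 100 iterations, truncation at 0; a bounded scalar maximization is
the fallback if the iteration cycles). The pooled SE is (Σwᵢ)^(−1/2) and
the 95% CI is the Wald interval μ̂ ± 1.96·SE — no small-sample (e.g.
Knapp–Hartung) adjustment, matching the plain reporting convention of the
consortium analyses this mirrors. Agreement with R's `metafor`
(`method="REML"`) was verified to 7 decimals during development; the test
suite uses an independent dense grid search instead.

**One-stage pooled regression (`mega_lr`).** OLS of the outcome on
intercept + diagnosis + covariates + (K−1) cohort dummies (reference:
first cohort by sorted label; the diagnosis estimate is invariant to the
choice, which is tested). d uses the same conversion with n₁, n₂ the
total group counts and df = n − p. BIC uses the Gaussian ML
log-likelihood with k = p + 1 (coefficients plus residual variance).

**One-stage mixed model (`mega_lmm_ri`, `mega_lmm_ris`).** y = Xβ + Zu + ε
with a cohort random intercept (one variance parameter σ_u²) and
optionally a cohort random slope on diagnosis (unstructured 2×2
covariance), fitted by REML. For the random-intercept model the package
uses its own exact fitter: β and σ_e² have closed forms given the
variance ratio λ = σ_u²/σ_e², so the REML criterion is profiled to a 1-D
function of λ and maximized by bounded scalar search (xatol 1e-12, upper
bound extended ×100 when the optimum nears it, explicit λ = 0 boundary
check). This is numerically stable precisely where general-purpose
mixed-model optimizers struggle — small samples whose REML optimum sits
on the σ_u² = 0 boundary. The random-slope model is fitted with
statsmodels `MixedLM`; its non-convergence is an expected *result state*
(converged=False with estimates absent), not an exception, reflecting how
often such models fail to converge on real multi-site data. The two
likelihood normalizations agree exactly (verified to 1e-13), so REML
log-likelihoods from both paths are comparable in the LRT.

**Effect-size SE for one-stage models.** With d = c·t and
c = (n₁+n₂)/(√(n₁n₂)√df), the t-statistic has unit dispersion under the
model, so SE(d) = c and the CI is d ± 1.96c. df is n_obs − n_fixed for
the mixed model; the published analyses cite a conversion whose exact
form is not printed, so this choice is documented and isolated in
`lmm_to_fitresult`/`t_to_d` for a one-line swap (e.g. to Satterthwaite
df). At the packaged adult sample sizes (1,498/1,436) this yields one-
stage SEs of ≈ 0.037, the magnitude reported in comparable analyses.

**BIC across model classes.** BIC(LMM) counts fixed effects + variance
components + residual variance and evaluates the REML log-likelihood;
BIC(LR) uses the ML log-likelihood. The two criteria are not strictly
commensurable (the published comparison does not state how it bridged
them); the package reproduces the comparison as reported and records the
caveat here. Within the mixed-model class the comparison is standard.

**Random-structure strategy.** `select_random_structure` runs: (1)
random-intercept fit; (2) random-intercept + slope fit; (3) REML
likelihood-ratio test (identical fixed effects, so REML LRT is valid for
nested random structures). Because the slope variance is tested on the
boundary of its space, the null is the 50:50 mixture of χ²(1) and χ²(2)
(the naive χ²(2) is available behind a flag); α defaults to 0.05. A
non-converging slope model falls back to the intercept model with the
reason recorded in the decision trace.

## Covariate policy and eligibility

Thickness models adjust for age and sex; surface-area models also for
intracranial volume. Missing data are handled by complete-case deletion
per ROI × analysis (no imputation), with every dropped row logged. A
cohort enters the two-stage arm only if both diagnostic groups are
present, residual df ≥ 1 after covariates, and n ≥ `min_cohort_n`
(default 10 — a floor against degenerate per-cohort fits; no published
value exists). Cohorts failing these checks remain in the one-stage
subset if they have ≥ 1 complete row, making the frameworks' asymmetric
sensitivity to missing data explicit. Sex must arrive as 0/1 or via an
explicit `sex_map`; no silent recoding. Significance uses the fixed
p < 0.001 reporting threshold (strict inequality, configurable); no
further multiplicity adjustment, by design fidelity to the reporting
convention it reproduces.

## Synthetic cohorts

The generator draws, per cohort i, an intercept uᵢ ~ N(0, σ_u²) and a
diagnosis-effect deviation bᵢ ~ N(0, σ_slope²), then

    y = grand_mean + uᵢ + (β_dx + bᵢ)·dx + β_age·age + β_sex·sex
        + β_icv·icv + e,   e ~ N(0, σ_e,i²),

with exact group counts per cohort, ages uniform within the pediatric
(8–18) or adult (18–65) range according to the cohort's pediatric
proportion, sex ~ Bernoulli(0.5) and ICV ~ N(1.5×10⁶ mm³, SD 1.5×10⁵)
truncated positive. No published covariate distributions exist for the
emulated sample; these are plausible field values and configurable.
σ_slope = 0 with a common σ_e constructs the classical regime in which
two-stage and one-stage fixed-effects analyses are equivalent; the
realized uᵢ, bᵢ, σ_e,i are exposed on the returned dataset (`ds.truth`)
so tests can verify the generating structure directly. One root seed;
per-cohort substreams are spawned deterministically, so extending a
configuration with new cohorts never perturbs earlier ones. When several
ROI columns are generated they share the cohort effects and differ only
in residual draws — adequate for studying the estimators, not a model of
inter-regional covariance.

The packaged default configuration has 38 cohorts (10 pediatric-only,
28 adult-only) whose four strata match the published composition exactly
(407/1,498 pediatric/adult patients, 324/1,436 controls; 3,665 total;
70 registered cortical measures — 34 parcels per hemisphere plus two
hemisphere means). Only the totals are published; per-cohort sizes use
even integer division with the remainder to the first cohorts. Outcome
defaults emulate cortical thickness: grand mean 2.5 mm, σ_e 0.15 mm,
σ_u 0.05 mm (moderate site variation), β_dx = −0.02 mm (standardized
≈ −0.13, the magnitude typical of adult case–control cortical effects),
age slope −0.005 mm/yr, sex difference 0.01 mm.

The true standardized effect used for bias and coverage is
β_dx/σ_e (RMS σ_e under heteroscedasticity) — the estimand the t-to-d
conversion targets in the homoscedastic, common-effect case.

What passing simulations do **not** show about real data: the generator
has Gaussian residuals, no scanner effects beyond an additive intercept,
no covariate–diagnosis interactions, no outcome-dependent missingness
and no clinical covariates; conclusions about method ordering transfer
to real cohorts only insofar as those assumptions are tolerable.

## Simulation harness

`run_simulation` executes generate → validate → fit for every scenario ×
replicate × method, with per-replicate seeds drawn from one root
`SeedSequence` (fully deterministic given the seed; all derived seeds
< 2³¹). Non-converged fits are excluded replicate-wise from the affected
summaries with the exclusion rate reported — never imputed. Summaries
(mean bias, empirical SD, mean model SE, CI coverage and width, SE
orderings, BIC preference, meta-vs-mega |Δd|) each carry a Monte-Carlo
SE. Shipped presets: `equivalence` (10 × 200+200, common σ_e),
`intercept-heterogeneity` (the 38-cohort default with σ_u = 0.3σ_e),
`slope-heterogeneity` (30 × 50+50, σ_slope = 0.5σ_e), `heteroscedastic`
(σ_e spanning 0.08–0.24 across cohorts), `small-cohorts` (38 × 15+15).
Replicate counts in the packaged checks (200–1,000 depending on the
quantity) were chosen so Monte-Carlo SEs are small relative to the
margins being tested.

## Numerical choices

- REML τ²: fixed-point tolerance 1e-8, 100 iterations, truncation at 0;
  fallback bounded search xatol 1e-10.
- Profiled random-intercept REML: scalar search xatol 1e-12; residual
  quadratic form floored at 1e-300 to avoid log(0) in degenerate cases.
- Rank checks name the first collinear design column; a cohort whose
  dummy is absorbed by a constant outcome surfaces as an estimation
  error rather than a silent drop.
- CSV I/O: comma/tab by extension, UTF-8, header required, "NA"/empty as
  the only missing markers, `float_precision="round_trip"` so datasets
  survive write→read bit-exactly.
- Ties/boundaries: p exactly equal to the threshold is not flagged
  (strict inequality); LRT statistic floored at 0; λ = 0 compared
  explicitly against the interior optimum.

## Known limitations

- The between-study variance gets no confidence interval, and no
  heterogeneity diagnostics (Q, I²) are reported.
- The fitted mixed model is homoscedastic across cohorts even when the
  generator is not; this is deliberate (it is the model practitioners
  fit) and is what makes the heteroscedastic preset informative.
- No crossed or nested random effects beyond cohort, no Bayesian
  estimation, no site-harmonization preprocessing.
- Cohen's d is not bias-corrected (no Hedges g); at the packaged sample
  sizes the correction factor is < 0.2%.
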