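# Methods

`twingxe` studies how the effect of a polygenic index (PGI) for educational
attainment on attained education varies across birth cohorts and by
socioeconomic background, using the twin-registry triangulation of
between-family and within-family estimators. Because the registry data such
designs run on are access-restricted, the package pairs the estimators with
a synthetic registry generator that encodes exactly the confounding
mechanisms the within-family design exists to remove. Every estimator
property is then verifiable against generative truth.

## Generative model

One generation of parents and twins, fully vectorised, single RNG stream.

**Parents.** Latent genetic values `(g_m, g_f)` are bivariate standard
normal with correlation `r_am` (assortative mating). Parental education
decile is the within-population decile of `λ·g + √(1−λ²)·z` with
independent `z` and genetic loading `λ` (`parent_edu_loading`, default
0.3) — enough to produce the familiar PGI–SES correlation without
committing to a particular intergenerational model.

**Transmission.** Each DZ twin draws
`g = (g_m+g_f)/2 + s`, `s ~ N(0, (1−r_am)/2)`,
so offspring variance is 1 for any `r_am` (single-generation equilibrium
approximation) and the DZ co-twin correlation is `(1+r_am)/2`. MZ co-twins
share one segregation deviation, hence identical genomes. Multi-generation
assortative-mating dynamics are out of scope.

**Observed PGI.**
`pgi = g + u_pair + u_twin + Σ_k λ_k·pc_k + shift[batch]`,
with pair-shared error `u_pair` (SD `sigma_meas_shared`, default 0.3),
twin-unique error `u_twin` (SD `sigma_meas_unique`, default 0.7 — together
implying reliability ≈ 0.63, in the range implied by current
education-GWAS predictors), ancestry principal components `pc_k` drawn at
the family level, and additive genotyping-batch offsets. Batch is drawn
per pair from a decade-specific mix: one older array dominates cohorts
born before 1950, two newer arrays split the later cohorts — so batch is
confounded with birth year unless handled.

**Outcome.**
`edu_latent = β(t)·g + γ(decade)·g·parent_high + δ·(g_m+g_f)
 + ses_main·parent_edu_scaled + Σ_k λ_k·pc_k + ε`

* `β(t) = β0 + β_trend·(t − reference_year)` — the cohort drift of the
  direct effect (defaults 0.15 + 0.0025/yr from 1920, roughly doubling
  over the century).
* `γ(decade)` — Scarr-Rowe-type enhancement, multiplying the *true*
  genetic value for twins with above-median parental education
  (measurement error is layered after the mechanism, since enhancement
  concerns propensities, not scores). Default schedule: 0.15 through the
  1940s, 0.05 in the 1950s, 0 afterwards — enhancement confined to
  cohorts schooled before the comprehensive reforms.
* `δ·(g_m+g_f)` — genetic nurture (default δ=0.05): parental genotype
  affecting the offspring through the environment. Together with
  assortative mating it inflates the between-family slope by `δ(1+r_am)`
  while cancelling exactly in co-twin differences.
* `ε` is scaled so the latent variance is ≈1 at the reference
  configuration (computed from the realised systematic component with β
  and γ at their reference values; floor 0.05 on the variance).

Binary degrees cut `edu_latent` at per-decade thresholds whose default
schedules push upper-secondary prevalence from ~0.5 to ~0.95 and
university prevalence from ~0.1 to ~0.35 across the century — the raw
material for floor/ceiling artifacts. GPA and income channels are noisy
linear functions of the education latent (loadings 0.7 and 0.5).

**Deciles and ascertainment.** Education/GPA/income deciles are ranked
against the *pre-ascertainment* population within (birth year, sex),
mimicking full-population register referencing. Pairs are then retained
with probability ∝ `exp(a·pair-mean latent)`, with `a` solved (Brent) so
the retained mean exceeds the population mean by
`ascertain_edu_bias / years_per_sd` latent SD (defaults 0.4 years / 3
years-per-SD ≈ 0.133 SD — the over-representation of educated twins that
registry volunteers show). Parental education is blanked for cohorts born
before 1940, as in registers where parental linkage fails for the oldest
cohorts.

**Determinism.** One `numpy` Generator; draw order is birth years,
zygosity, batch, sex, parents, segregation, PCs, PGI errors, outcome
noise, supplementary noise, ascertainment uniforms. Identical
`(params, seed)` reproduce the registry bit-for-bit. Changing `n_pairs`
reorders draws; only full-run reproducibility is guaranteed.

## Variable constructions

* **Decile reference**: per (birth year, sex) the 10th..90th empirical
  percentiles with linear ("type 7") interpolation; groups need ≥10
  values. A value's decile is 1 + the number of boundaries *strictly*
  below it, so boundary ties fall downward and the top decile is never
  inflated.
* **PGI standardization**: mean 0, SD 1 (ddof=1) within birth year ×
  genotyping batch, which removes additive batch offsets by construction.
  Singleton strata either merge with the nearest year in the same batch
  (default) or have the PGI blanked; both warn.
* **Parental education**: dominance principle (max of the non-missing
  parents). **Median split** on the pooled analysis sample (a per-decade
  split is a config option, not the default); ties at the median count as
  low.

## Estimators

* **Between-family**: OLS of the outcome on the PGI across all twins,
  covariates = 20 ancestry PCs, sex, batch dummies; CR1 cluster-robust
  sandwich on twin pair — `(G/(G−1))·((N−1)/(N−K))` small-sample factor,
  t reference with G−1 df. With singleton clusters this is exactly HC1
  (tested against statsmodels).
* **Within-family**: co-twin differences (smaller twin id minus larger)
  within complete DZ pairs with concordant batch; covariates = pair sex
  difference and batch dummies; heteroskedasticity-robust errors (the
  pair is the unit; no nesting). The no-intercept difference regression
  is algebraically the pair fixed-effects estimator; with an intercept it
  equals fixed effects plus a within-pair order dummy (the standard
  two-period first-difference identity). Both identities are enforced to
  1e-8 in tests. The intercept is kept by default.
* **Keller expansion**: with moderators present, every covariate also
  enters interacted with the exposure and with each moderator
  (covariate×covariate terms are not included — that is the Keller (2014)
  prescription; a full pairwise expansion was considered and rejected as
  it adds ~250 columns of pure noise at default settings).
* **Trend models** center birth year at the sample mean before
  interacting; the interaction coefficient is per calendar year.
* **GLM variants**: statsmodels Logit / OrderedModel (logit link),
  cluster-robust on pair; coefficients are reported on the untransformed
  log-odds scale. Separation raises with a diagnostic rather than
  returning runaway estimates.
* **Collinearity**: greedy left-to-right rank filter; later duplicates are
  dropped and logged, never silently.
* **Outcome scale**: registry fits run on the 1–10 decile outcome as
  reported in this literature. Generative-truth comparisons use the
  latent outcome, where the closed forms hold; `deciles_per_latent_sd`
  estimates the Jacobian (≈2.4 under the defaults) for converting between
  the two scales.

## Measurement-error correction

For a unit-variance PGI and outcome, every PGI-containing coefficient and
SE is multiplied by `sqrt(h²_SNP / R²_PGI)`. Under classical error
`PGI = G + u` the standardized-exposure slope attenuates by
`1/√(1+σ_u²)` and the observed R² is `h²/(1+σ_u²)`, so the factor exactly
undoes the attenuation (verified by simulation). Defaults h²=0.16,
R²=0.04 give factor 2: raw interaction estimates are roughly halved
lower bounds. Caveats, asserted directionally in tests: the correction is
calibrated on the population R², so it *over*-corrects the within-family
estimate when part of the error is pair-shared (shared error cancels in
differences); scaling SEs by the same factor ignores sampling error in h²
and R² themselves. Estimating h² from data (GREML/LDSC) is out of scope.

## Floor/ceiling diagnostics

Dichotomizing a latent outcome at cut `c` gives a linear-probability
slope ≈ `β·f(c)` for latent density `f`, so prevalence drift across
strata manufactures "interactions" on the linear scale; under logistic
latent errors the log-odds slope is cut-invariant. `threshold_sweep`
measures both slopes across cuts; `scale_sensitivity` compares the
cross-stratum trend of the two scales and returns **discordant** when the
trend signs differ or either trend's 95% CI excludes the other's point
estimate (fewer than 3 strata: **insufficient**). The decision rule is a
deliberate operationalisation — the practice this check comes from is
usually qualitative — and is deterministic given the fitted summaries.

## Verification scale

The verification battery and the reproduction script run the scenarios at
the sizes their tolerances require: 100k pairs for sibling correlations
(±0.01 on a correlation), 50k pairs for closed-form slope recovery
(±0.02–0.03), 200 replicates at 20k twins/stratum for the
enhancement-decay power check, 100 replicates at 5k pairs for
within-trend CI coverage, 200k observations for the density-ratio probes.
The full battery completes in a few minutes on one CPU.

## What the generator does not emulate

No SNP-level genotypes or LD structure (the PGI is an abstract score), no
GWAS finite-sample weight error beyond the classical/shared error
decomposition, no multi-generation assortative-mating equilibrium, no
cohort-varying GWAS portability (the possibility that the discovery
sample's birth-year profile tilts PGI predictiveness across cohorts is
real but deliberately unmodelled), no sibling interaction effects, no
mortality/attrition structure beyond the single education-linked
ascertainment tilt. Passing tests therefore certify the estimators and
the design's confound-removal algebra under the stated mechanisms — not
that any real registry satisfies those mechanisms.
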