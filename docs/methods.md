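# Methods

`lipidmr` implements a complete Mendelian-randomization (MR) workflow for
estimating causal effects of blood lipids (LDL cholesterol, HDL
cholesterol, triglycerides) on left-ventricular (LV) imaging phenotypes
(end-diastolic volume, ejection fraction, mass), together with the
observational comparators the MR results are contrasted against and a
synthetic-data generator that makes every estimator verifiable by
parameter recovery.

## Measurement model and preprocessing

Lipid concentrations are handled in mg/dl internally. Conversion factors
are 38.67 mg/dl per mmol/l for cholesterol (molar mass 386.65 g/mol) and
88.57 for triglycerides; conversions are exact and unrounded, with a
separate half-up presentation-rounding helper for table display (so
1 mmol/l cholesterol prints as 39 mg/dl, 0.87 mmol/l as 34, 0.38 as 15,
and 1.0/1.02 mmol/l triglycerides as 89/90).

Where a direct LDL assay is missing, LDL is derived by the Friedewald
equation `LDL = TC − HDL − TG/5`, valid only while triglycerides are at
or below a ceiling of 155 mg/dl (configurable). A negative Friedewald
result is returned as missing rather than clamped: an impossible
concentration should not silently enter a regression. Statin users'
LDL is multiplied by 1.43 to approximate the untreated lifetime
exposure; HDL and triglycerides are never adjusted. Systolic blood
pressure gains +15 mm Hg for participants on antihypertensives. BSA uses
the Du Bois formula. BMI, HbA1c and physical activity (MET-min/week) are
log-transformed; MET uses `log(x + 1)` because zeros are legitimate
(the offset is configurable; the choice is a convention, not a fit).

Every resolved LDL value carries a provenance label
(`direct` / `friedewald` / `missing`) and flags recording whether statin
and SBP adjustments were applied.

## Generative model of the synthetic cohort

The generator draws an n×m dosage matrix under Hardy-Weinberg
equilibrium, `g_ij ~ Binomial(2, MAF_j)` with MAFs uniform on
[0.05, 0.5], and builds

    X = G γ + a_x U + ε_x          (exposure)
    Y = β X + a_y U + G α + ε_y    (outcome)

with a single standard-normal confounder `U` — the minimal structure
sufficient to produce confounded observational estimates — and per-variant
pleiotropic effects `α_j` nonzero only for a configured invalid fraction.
The per-variant effects `γ` are rescaled so that the true weighted score
explains a target fraction of `var(X)`; the defaults mirror the setting
the generator emulates: n = 17,000 individuals, 101 variants, score
R² = 0.108 for the LDL instrument (0.073 and 0.050 are the HDL and
triglyceride analogues), causal effect β = 0.5.

The default confounder loadings are (a_x, a_y) = (1.5, −1.5). By the
omitted-variable identity `β_OLS = β + a_x a_y var(U)/var(X)` this puts
the observational bias at about −0.62, which exceeds the causal effect in
magnitude and flips the observational sign — the qualitative discordance
between observational and MR estimates that the downstream analyses are
designed to expose. (Loadings of ±1.0 would give a bias of only −0.45 and
no sign flip at β = 0.5.)

Statin use is assigned by a logistic model on the standardized true
score (intercept −1.7, slope 0.5: roughly a 15% base rate rising with
genetic LDL, the pattern seen in population cohorts), and statin users'
*measured* exposure is the true exposure divided by 1.43, so the
preprocessing adjustment is its exact inverse. Real-world heterogeneity
in statin response is deliberately out of scope; this construction exists
so the statin-by-score interaction analysis has a testable analogue with
a known sign.

Two-sample summary statistics come from two cohorts drawn independently
of each other (and of the one-sample cohort) that share the variant
panel; per-variant betas and SEs are marginal regressions of trait on
dosage. Default sample sizes are asymmetric — 188,577 for the exposure
GWAS and 16,923 for the outcome GWAS — matching the consortium setting
emulated. This matters: at equal ~17k/17k sizes the noise in the
per-variant exposure effects induces visible regression-dilution
(weak-instrument) bias of ~5–10% toward the null in IVW; at the default
sizes it is negligible. An analytic mode suppresses sampling noise
entirely (betas equal their generative expectations with a nominal SE of
1e-8) for noiseless identity tests. A `simulate_summary_stats` shortcut
draws already-harmonized summary sets directly, for calibration studies
where the genotype layer is irrelevant.

All randomness flows from one integer seed through numpy `SeedSequence`
spawning; the variant panel is a deterministic function of the seed so a
cohort and a two-sample design built from the same parameters share
instruments. Cohorts serialize to CSV with a JSON truth sidecar that
round-trips exactly.

What the generator does *not* emulate: linkage disequilibrium (variants
are independent, so LD clumping is exercised through explicit LD
matrices), ancestry structure (the five "genetic PCs" are pure noise
covariates), assay error models, and time gaps between exposure and
outcome assessment. Passing tests therefore demonstrate estimator
correctness under the stated structural model, not robustness to those
real-data features.

## Instruments

GRS construction filters variants at genome-wide significance
(p < 5×10⁻⁸), applies greedy LD clumping at r² < 0.01 (most significant
variant kept as index, ties on p broken lexicographically by id so the
selection is order-invariant), and scores individuals by
`Σ_j weight_j × dosage_ij` with the variant-exposure betas as weights.
Missing dosages are mean-imputed per variant (standard polygenic-score
practice; complete-case is available). Instrument strength is the simple
regression R² of the measured exposure on the score with
`F = (n−2) R²/(1−R²)`; F ≤ 10 flags a weak instrument. A restricted
score drops a supplied exclusion list of potentially pleiotropic
variants (erroring below 2 remaining).

## One-sample MR

Two-stage least squares with the score as the single instrument and
covariates in both stages, in the just-identified general form (k
exposures, k instruments) so the multi-exposure adjustment including all
three lipid scores is the same code path. SEs use the conventional 2SLS
residual definition — residual variance at the point estimate from the
*observed* exposure, coefficient covariance from the first-stage fitted
values — under homoskedasticity, matching the standard implementations
of this estimator family; confidence intervals use normal quantiles
(β ∓ 1.95996·se). Endogeneity is tested by the Durbin–Wu–Hausman
augmented regression: the squared t statistic on the first-stage
residual term referred to χ²(1). The statin analysis regresses the
*unadjusted* measured exposure on score, statin, score×statin and
covariates and reports the product term.

Power uses the closed form for a continuous outcome,
`β_std = (z_{1−α/2} + z_{power}) / √(n·R²)`, returned in natural units
via the outcome/exposure SD ratio, with the exact inverse
`power_at_effect` provided.

## Two-sample MR

Harmonization aligns outcome summary statistics to the exposure's effect
alleles: swapped alleles flip the beta sign and complement the EAF,
strand mismatches are resolved by base complementation, palindromic
(A/T, C/G) variants are aligned by allele-frequency concordance and
dropped when either EAF is within 0.5 ± 0.08 (the window is
configurable; the convention follows standard harmonization practice).
Unreconcilable variants are excluded individually, never fatally.

Estimators operate on the per-variant Wald ratios `Γ_j/γ_j` with
delta-method SEs `σ_Γj/|γ_j|`:

- **IVW** — weighted regression of Γ on γ through the origin, weights
  1/σ_Γ². Multiplicative random effects scale the SE by
  `max(1, √(Q/(J−1)))`. The *penalized* variant down-weights variants by
  `min(1, 20·q_j)` where q_j is the χ²(1) upper-tail probability of the
  variant's heterogeneity contribution; the *robust* variant replaces
  least squares with Tukey-bisquare M-estimation (tuning 4.685, iterated
  to 1e-8). The constants follow the robust-penalized methodology this
  estimator family descends from and are exposed as configuration.
- **MR-Egger** — weighted regression *with* intercept after orienting
  every variant to γ_j > 0 (required for identifiability); the intercept
  estimates average directional pleiotropy and its test at p < 0.10
  raises the pleiotropy flag.
- **Weighted median** — inverse-variance-weighted 0.5-quantile with
  linear interpolation; identical ratio values are aggregated first so
  the estimate depends only on the normalized weight distribution
  (duplication-invariant). SE by parametric bootstrap of the summary
  statistics (default 1,000 draws, seeded).
- **Weighted mode** — argmax of a Gaussian kernel density over the
  ratios with inverse-variance weights; bandwidth is a configurable
  multiple of the modified Silverman rule, density evaluated on a
  512-point grid spanning the ratios ± 3 bandwidths; bootstrap SE as for
  the median.
- **Multivariable MR** — weighted multiple regression of Γ on the k
  columns of exposure betas without intercept; with k = 1 it reduces
  exactly to fixed-effect IVW.
- **MR-PRESSO** — global test compares the observed residual sum of
  squares (each variant against its leave-one-out IVW slope) to a
  parametric null obtained by redrawing both betas under the fitted
  no-pleiotropy model (default 1,000 draws); per-variant outlier
  p-values are Bonferroni-corrected; the distortion test compares the
  relative estimate change after outlier removal with that from removing
  equally many random variants. Empirical p-values use the (1+k)/(1+N)
  convention so they are never exactly zero.
- **MR-Steiger** — instruments' variance explained in exposure vs
  outcome via `Σ 2·eaf(1−eaf)·beta²/var`, direction supported when
  R²(G,X) > R²(G,Y), p from the difference of Fisher-transformed
  correlations with variance `1/(n_exp−3) + 1/(n_out−3)`.

All estimators return a uniform result record and are invariant to
variant input order; two-sided normal p-values are used throughout.

## Observational comparators and trend tests

The observational estimate is the OLS coefficient on the measured
exposure with the full covariate set, normal-theory inference (t vs z is
immaterial at n ≈ 17,000). Percentile grouping uses empirical percentile
ranks with right-closed bins (default edges 50/75/90/95, giving groups
0–50/51–75/76–90/91–95/96–100%); group sizes always sum to n. Trend
across ordered groups uses Cuzick's rank test (midranks under ties, tie
correction in the null variance, two-sided normal p) for continuous
variables and the Cochran–Armitage χ²(1) statistic for proportions.

## Pipeline and significance rule

The pipeline runs simulate → score → one-sample MR → observational →
two-sample suite per lipid-phenotype pair, each stage seeded
deterministically from the master seed, and flags an effect significant
only when *both* the one-sample and two-sample MR p-values are strictly
below 0.05. Thresholds (5×10⁻⁸ significance, r² < 0.01 clumping, 0.10
Egger alpha, 0.05 joint alpha, F > 10) live in one serializable
configuration object; the same configuration always produces
byte-identical outputs.

## Numerical choices and problem sizes

- Degenerate inputs raise typed errors (zero-variance instrument,
  rank-deficient designs, constant statin stratum, all-tied trend data)
  rather than returning NaNs.
- A perfect score-exposure fit reports an infinite-F sentinel once
  1 − R² falls below 1e-12.
- Bisquare iteration stops on a 1e-8 estimate change or when the
  residual MAD collapses to zero (exact consensus).
- Calibration and robustness checks in the test suite and acceptance
  script run at reduced problem sizes (cohorts of 1,000–5,000, panels of
  15–25 variants, 150–600 replicates), chosen as the smallest sizes at
  which the asymptotic properties under test are expected to hold;
  headline recovery runs use the full reference conditions.

## Known limitations

- The weighted median's majority-valid guarantee is asymptotic in
  instrument precision: with 45% invalid variants it sits at the
  0.5/0.55 quantile of the valid-ratio distribution, a structural bias
  of ≈1.34 ratio-noise SDs, and when the invalid *weight* share reaches
  one half (possible by chance with variable weights) it breaks down —
  the robustness tests assert rates, not certainties.
- One-sample 2SLS with weights estimated from an external GWAS inherits
  the weights' sampling noise; at the default discovery size this is
  negligible but visible if both samples are small.
- No LD-aware (correlated-instrument) IVW, contamination-mixture,
  MR-RAPS or bidirectional MR; heteroskedasticity-robust 2SLS SEs are
  available but not default.
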