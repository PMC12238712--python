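# Methods

`odontofa` implements a complete analysis chain for dental fluctuating
asymmetry (FA) in bilateral metric traits — molar intercuspal distances
in the motivating application — from raw left/right measurements to
sex-stratified tests of association between high FA and latent
early-life dimensions. This note documents the statistical procedures,
the defaults and why they were chosen, what the synthetic cohort
generator does and does not emulate, and the numerical conventions.

## 1. Trait screening battery (`odontofa.qc`)

FA is the variance of random, non-directional deviations from bilateral
symmetry. Before a composite index can be read as developmental
instability, each trait is screened for the classical confounders:

- **Replicate bias** — a paired two-sided t-test of second-session
  against first-session measurements on the replicate subset, pairing
  per-individual side means. Sides are averaged first because
  session-level error components are shared by the two sides of a
  trait; treating L and R as independent pairs double-counts them and
  inflates the test's type-I error well above nominal. Systematic
  intra-observer bias excludes the trait.
- **Error versus asymmetry** — a trait is excluded when the mean
  between-session measurement error `mean(|m2 − m1|)` strictly exceeds
  the mean unsigned asymmetry `mean(|R − L|)` of the full sample. With
  error of that size, apparent asymmetry is mostly noise.
- **Outliers** — iterative two-sided Grubbs scan on signed `d = R − L`
  at α = 0.05, critical value from the Student-t quantile formula.
  Confirmed outliers are removed cell-wise (that individual's value for
  that trait only), not as whole individuals, since a gross value
  usually reflects a local cast or landmark problem.
- **Directional asymmetry (DA)** — one-sample two-sided t-test of
  `mean(d) = 0`.
- **Antisymmetry** — bimodality of `d` manifests as platykurtosis; the
  screen uses the moment-based kurtosis test plus an omnibus normality
  test, flagging only when the kurtosis test is significant *and* the
  sample excess kurtosis is negative. The direction is taken from the
  sample excess kurtosis itself because the z-statistic's normalizing
  transform misbehaves near the platykurtic boundary (excess kurtosis
  → −2), where it can return a large statistic of the wrong sign.
- **Size dependence** — Spearman correlation (average ranks) of
  `|R − L|` with trait size `(R + L)/2`, pooled and within each sex;
  groups under 5 observations are skipped with a reason code.

p-values are Holm-adjusted (step-down sequential Bonferroni) across
traits **within each test family**, at family α = 0.05. The family
definition and α are configurable; one family per test kind across
traits is the natural unit here because each kind asks one question of
the whole battery.

By default only the error screens and a low-presence rule (trait
observed in fewer than 25% of individuals) force exclusion; the
distributional screens (DA, antisymmetry, size dependence) are reported
and can be made exclusionary via `ScreenConfig(distributional_exclusions
=True)`. Rationale: DA or antisymmetry in a trait is a property of the
biology, and whether it disqualifies the trait is an analyst decision;
error screens are unambiguous.

## 2. Composite FA index (`odontofa.fa`)

Per trait, unsigned asymmetries `|d|` are z-standardized over **all**
individuals observed for that trait (sexes pooled, sample sd with n − 1
denominator). Each individual's composite is the mean of their observed
per-trait z-scores. Individuals with fewer than `ceil(n_traits / 2)`
observed traits are excluded — a composite averaged over a handful of
traits has inflated variance and would dominate the tails. The
composite is then z-standardized across the included individuals, and
**high FA** is the strict dichotomy `composite_z > 1` (a value exactly
at the cutoff is low/average). With an approximately Gaussian
composite, the expected high-FA share is P(Z > 1) ≈ 15.9%.

The threshold, cutoff and trait battery are parameters, so alternate
batteries (e.g. 15-trait deciduous mesiodistal/buccolingual or
gestational-window sets) reuse the same code path with no changes.

## 3. Factor analysis of mixed data (`odontofa.famd`)

FAMD is implemented from its SVD definition. Quantitative columns are
standardized with the population (n-denominator) sd; each category k of
a qualitative variable enters as `indicator/√p_k`, centered, where
`p_k` is the category proportion. Rows carry weight 1/n. Under this
encoding:

- a quantitative variable contributes 1 to total inertia; a
  qualitative variable with K levels contributes K − 1, so total
  inertia is `Q + Σ_j (K_j − 1)`;
- with only quantitative columns the eigenvalues equal those of
  correlation-matrix PCA exactly;
- with only qualitative columns they equal MCA eigenvalues in the
  indicator-matrix convention (J × the correspondence-analysis
  eigenvalues of the indicator table).

The n-denominator (not n − 1) makes both limit identities exact, which
is why it is the encoding convention here. Eigenvalues are squared
singular values of `(1/√n)·X`; individual coordinates are `√n·U·Σ`
(dimension ℓ has variance λ_ℓ); column contributions are `100·v²`,
summed over category columns for per-variable contributions. Each
dimension's sign is fixed by making its largest-magnitude column
loading positive; where loadings are symmetric to machine precision the
sign is still a convention, not an invariant, and downstream use must
not depend on it (see §6 on alignment). The number of retained
dimensions is always an explicit user argument — scree inspection is an
analyst decision, never automated silently.

## 4. Regularized iterative FAMD imputation (`odontofa.impute`)

Missing mixed-data cells are filled by an EM-like loop: initialize
missing quantitative cells at column means and missing categorical
cells at observed category proportions (fuzzy memberships); then
repeatedly (i) re-encode with freshly computed sds and proportions,
(ii) take the SVD and reconstruct with `ncp` components using shrunken
singular values `(d_ℓ² − σ̂²)/d_ℓ`, where `σ̂²` is the mean of the
discarded eigenvalues, (iii) back-transform and overwrite the
originally missing cells only. Iteration stops when the sum of squared
changes in the imputed cells, relative to the previous iteration, falls
below `tol` (default 1e-6; `max_iter` 1000, non-convergence is flagged
with a warning, not fatal). The shrinkage prevents the loop from
fitting noise as `ncp` approaches the rank; `ncp = 0` degrades to plain
mean/proportion imputation with no iteration.

Defaults: `ncp = 5`. A K-fold cell-deletion selector
(`select_ncp_kfold`) is available but off the default path — rank
selection by cross-validation is expensive and rarely changes the
downstream dimensions materially at these missingness levels (<5% per
variable).

Fuzzy categorical memberships feed the downstream FAMD directly
(`FAMD.from_completed`); a hard argmax level is exported alongside for
human inspection. Because the encoding's centering vector lies in the
null space of every row that sums to one, reconstructed memberships sum
to one exactly; small negative memberships from the low-rank
reconstruction are clipped to zero and renormalized per variable at
export, after the iteration has finished on the raw values.

## 5. Association (`odontofa.association`)

High FA is regressed on the FAMD dimension scores by maximum-likelihood
logistic regression (IRLS, via the GLM machinery), separately per sex.
Dimension scores enter unscaled, exactly as produced by the
decomposition, so coefficients are per-dimension-unit. Model adequacy
is the residual-deviance lack-of-fit p-value, the upper-tail chi-square
probability of the residual deviance at its residual degrees of
freedom. Perfect or quasi-separation is detected and flagged.
Surrounding descriptive tests: Pearson chi-square on the 2×2 high-FA ×
sex table **without** continuity correction (the convention that
reproduces the published statistic for such tables; Yates' correction
gives a different value), one-way fixed-effects ANOVA, and the Welch
unequal-variance t-test with Welch–Satterthwaite (fractional) degrees
of freedom.

## 6. Synthetic cohorts (`odontofa.simulate`)

The generator produces study-shaped data with known truth. Defaults are
the study conditions: 303 individuals (154 M / 149 F), 20 bilateral
traits with mean sizes spanning 2–7 mm, a 30-individual second-session
replicate subset, 21 mixed covariates (6 quantitative, 15 categorical)
driven by 4 latent factors, ≤5% covariate missingness (3% MCAR per
variable), and female-only negative instability coefficients
β₂ = −0.25, β₄ = −0.30 on factors 2 and 4 (males all zero).

Generative model, per individual i:

- latent factors `z_i ~ N(0, I₄)`; instability scale
  `s_i = exp(Σ_d β_{d,sex(i)} z_{id} + τ·ε_i)` with `ε_i ~ N(0,1)` — a
  log-linear multiplicative scale on the asymmetry sd, the minimal
  structure consistent with FA as a variance phenomenon. The
  sex-independent noise term (τ = 0.30) represents unmeasured sources
  of developmental instability; without it the male instability scale
  would be exactly constant (all male β are zero), the pooled z > 1
  cutoff would select almost only females, and a male high-FA group
  could be empty — biologically implausible and statistically
  degenerate;
- covariates: latent propensity `u = L'z + noise` with unit variance;
  quantitative values affine in u; categorical levels by thresholding u
  at normal quantiles matching target level frequencies (≈42%
  breastfed, ≈89% term births, education/occupation/nationality
  spreads typical of a 1950s Ontario cohort). Factor themes: 1 =
  parental age, 2 = breastfeeding history, 3 = parental education and
  occupation, 4 = migration background and gestational condition.
  Factor-4 loadings (0.85 on group membership, −0.6 on deciduous FA,
  −0.5 on birthweight) were set so that all four factors stand above
  the eigenvalue bulk of a fitted scree — a four-factor generator whose
  fourth factor is invisible would not exercise the retention decision;
- per trait t: signed asymmetry `d ~ N(DA_t, (σ_t s_i)²)` with
  σ_t = 0.12 mm; sides `L = T − d/2`, `R = T + d/2` with
  `T ~ N(size_t, 0.30²)`;
- observer error per recorded value: a session-shared component
  (σ_session = 0.02 mm; shared by both sides of a trait within a
  measurement session — landmark re-identification error) plus an
  independent per-event component (σ_event = 0.03 mm). The shared
  component cancels from same-session |R − L| but not from
  between-session replicate differences. This two-component structure
  is what makes the error-versus-asymmetry screen well-posed: with
  purely independent per-event error, the expected mean |m2 − m1| can
  never exceed the expected mean |R − L|, because the same error
  variance enters both;
- missingness: measurement cells MCAR at 9.5%, with a 2.8% "poor cast"
  subgroup missing 60% of traits. These rates target a mean of ≈17.8
  observed traits per individual and ≈2% of individuals below the
  10-trait inclusion threshold (≈6 exclusions from 303).

Pathology injections (`inject_pathology`) alter exactly one assumption
for chosen traits: inflated between-session error (magnitude × σ_t as
the session sd), a DA mean shift, an antisymmetric two-mode mixture at
±magnitude, size-coupled asymmetry sd, or reduced trait presence. All
randomness derives from one seed through named `SeedSequence` child
streams, so outputs are byte-identical under a fixed seed and adding
draws to one component does not shift the others.

Because the decomposition orders dimensions by variance and fixes signs
by convention, fitted dimensions need not match the generator's factor
indexing. `align_dimensions` greedily matches dimensions to true
factors by largest absolute correlation and flips signs to positive
correlation, making sign assertions on recovered coefficients well
defined.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: covariate effects are linear in
Gaussian factors (no interactions, no MNAR missingness); traits are
conditionally independent given s_i (no odontometric covariance between
neighbouring traits); there is no age/attrition structure, no
inter-observer design, and no familial correlation. Recovery results
show the pipeline finds structure it was built to find; they do not
validate the biological model.

## 7. Numerical conventions and degenerate inputs

- Zero-variance guards use a relative tolerance (sd ≤ 1e-12 × data
  scale) so float summation noise does not masquerade as variance.
- Exact replicate bias with zero difference variance is flagged
  (`exact_bias`) instead of dividing by zero.
- The error-versus-asymmetry comparison is a strict inequality; exact
  equality retains the trait.
- Ties at the high-FA cutoff go to 0 (strict `>`).
- Holm adjustment passes NaN p-values through unadjusted and excludes
  them from the family size.
- The imputation relative-change denominator is floored at 1e-300 to
  keep the first iteration finite when all imputed cells start at 0.

## 8. Problem sizes used in the validation suite

The acceptance checks run full-size cohorts (n = 303, 20 or 28 traits)
for single-cohort claims. Monte-Carlo claims use 200 seeds for
screen/Wald calibration under null settings, 100 seeds for sex-specific
sign recovery, and 50 seeds for the imputation-versus-mean comparison
(at n = 150 per table) — sizes chosen so each estimate's binomial or
sampling error is small relative to the asserted margins while the
whole suite stays comfortably re-runnable on a laptop. The recovery
thresholds asserted in the regression tests were frozen from a pilot
run at these sizes (rates minus a binomial safety margin) and are
regression guards, not claims of optimal power.

## 9. Known limitations

- FAMD supplementary-variable projection, confidence ellipses and
  graphical output are out of scope; outputs are tabular.
- Multiple imputation with uncertainty propagation is not provided; a
  single completed table feeds the decomposition, so downstream
  standard errors ignore imputation uncertainty.
- The logistic models offer Wald inference only (no Firth correction,
  no profile or odds-ratio confidence intervals); quasi-separation is
  flagged but not penalized away.
- Measurement-error partitioning by mixed models (two-way ANOVA of
  sides × individuals) is not implemented; the battery follows the
  replicate-difference screens described above.
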