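# odontofa

Dental fluctuating asymmetry (FA) — random, non-directional deviation
from bilateral symmetry — is used in biological anthropology and
epidemiology as a retrospective biomarker of developmental stress:
tooth crowns form in gestation and infancy, do not remodel, and so
carry a permanent record of instability during that window. Testing
whether early-life conditions (parental socioeconomic status,
gestation, infant feeding, childhood illness) predict dental FA
requires a long chain of statistical machinery, each link of which has
well-known failure modes. `odontofa` packages that chain, end to end,
for analysts working with bilateral metric traits (e.g. molar
intercuspal distances measured on serial dental casts) and mixed
biocultural covariate tables:

1. **QC screening battery** (`odontofa.qc`) — per-trait screens for
   intra-observer replicate bias, measurement error exceeding the
   asymmetry signal, Grubbs outliers, directional asymmetry
   (mean R − L ≠ 0), antisymmetry (platykurtic R − L), and size
   dependence of |R − L|, with Holm (sequential Bonferroni) correction
   across traits per test family.
2. **Composite FA index** (`odontofa.fa`) — per-trait |R − L|
   z-standardized over the full sample, averaged within individuals
   over observed traits (minimum: half the battery, rounded up), the
   composite z-standardized and dichotomized at z > 1 into high vs
   low/average FA.
3. **FAMD** (`odontofa.famd`) — factor analysis of mixed data from its
   SVD definition (PCA-standardized quantitative columns +
   MCA-weighted category indicators in one weighted decomposition),
   statsmodels-style: `FAMD(df).fit(n_components)` returns a results
   object with eigenvalues, coordinates, contributions and
   `summary()`.
4. **Regularized iterative FAMD imputation** (`odontofa.impute`) — the
   EM-like loop that alternates low-rank reconstruction (shrunken
   singular values, `ncp` components) with refilling the missing cells
   only, for mixed tables with modest missingness.
5. **Sex-stratified association** (`odontofa.association`) — logistic
   regression of high FA on the FAMD dimension scores, per sex, with
   residual-deviance lack-of-fit; plus the surrounding descriptive
   tests (uncorrected 2×2 Pearson chi-square, one-way ANOVA, Welch t).
6. **Synthetic cohorts** (`odontofa.simulate`) — a generator producing
   study-shaped measurement and covariate tables from known latent
   structure (4 factors driving 21 mixed covariates; instability
   s = exp(β·z + τε) scaling the asymmetry sd; session-structured
   observer error; MCAR masks), with injectable pathologies to
   validate every screen against ground truth.

Everything is scriptable from Python or from the `odontofa` CLI
(`simulate`, `qc`, `index`, `impute`, `famd`, `regress`, `all`).

## Worked example

Generate a cohort at the default study conditions (303 individuals,
154 M / 149 F, 20 bilateral traits, 21 mixed covariates on 4 latent
factors, female-only protective coefficients on factors 2 and 4) and
run the full pipeline:

```python
from odontofa import SimulationConfig, generate, analyze_cohort

cohort = generate(SimulationConfig(seed=2))
analysis = analyze_cohort(cohort, ndim=4, ncp=5, align=True)

print(analysis.screen.summary())
fa = analysis.fa
print(f"FA index: {fa.n_included} included (min {fa.min_traits} traits), "
      f"{fa.n_excluded} excluded, {int((fa.included['high_fa'] == 1).sum())} high-FA")
print(analysis.famd.summary())
print(analysis.aligned_fits["F"].summary())
print(analysis.aligned_fits["M"].summary())
```

which prints:

```
screened 20 traits: 0 excluded by error screens, 0 by low presence, 20 retained
FA index: 298 included (min 10 traits), 5 excluded, 50 high-FA

Factor analysis of mixed data
=================================
n individuals:        303
variables:            21 (6 quantitative, 15 categorical)
total inertia:        48.7879
components retained:  4

dim   eigenvalue   % variance   cumulative %
  1       3.2564         6.67           6.67
  2       2.7634         5.66          12.34
  3       2.2028         4.52          16.85
  4       1.7667         3.62          20.48

Logistic regression [F] (n = 146)
term                coef        SE        z    P>|z|
const             -1.726     0.281    -6.13    0.000
z1                -0.022     0.137    -0.16    0.873
z2                -0.521     0.187    -2.79    0.005
z3                -0.248     0.178    -1.39    0.164
z4                -0.580     0.165    -3.52    0.000
null deviance 148.31 on 145 df; residual deviance 118.86 on 141 df
lack-of-fit P = 0.91

Logistic regression [M] (n = 152)
term                coef        SE        z    P>|z|
const             -1.924     0.250    -7.68    0.000
z1                 0.211     0.144     1.46    0.144
z2                 0.029     0.152     0.19    0.849
z3                -0.085     0.182    -0.47    0.640
z4                -0.082     0.145    -0.57    0.572
null deviance 118.37 on 151 df; residual deviance 115.60 on 147 df
lack-of-fit P = 0.97
```

Reading the output: no trait fails the error screens in this clean
cohort; 5 of 303 individuals fall below the 10-trait minimum, leaving
298 for analysis, 50 of them (≈17%) above the z > 1 high-FA cutoff —
near the Gaussian-tail expectation of 15.9%. The four leading FAMD
dimensions carry 20.5% of the inertia of the 21 mixed covariates. In
the sex-stratified regressions (here on dimensions matched and
sign-aligned to the generator's true factors via
`align_dimensions`), the female fit recovers significant negative
slopes on factors 2 and 4 — the two factors the generator made
protective in females (injected β₂ = −0.25, β₄ = −0.30 on the
log-instability scale) — while all male slopes are indistinguishable
from zero, exactly the built-in sex-specific structure. Large
lack-of-fit p-values indicate no evidence of misspecification.

The same pipeline runs from the shell on CSV inputs:

```sh
odontofa simulate --seed 2 --out cohort/
odontofa all --simulate --seed 2 --out run/     # one-shot, writes manifest.json
odontofa qc --measurements cohort/measurements.csv --out screen.csv
```

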