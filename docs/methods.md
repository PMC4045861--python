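# Methods

`diabscreen` simulates the population impact of diabetes screening
guidelines using two synthetic national surveys: an *examination*
survey with laboratory glycemia measures, used to fit risk models, and
a *utilization* survey with health-care visit counts, used to project
those risks onto the screening-eligible population. This document
describes the model, the synthetic data generator, the parameter
defaults, the numerical choices, and the known limitations.

## 1. Glycemic classification

Each examination-survey adult carries a partial laboratory panel
(HbA1c in %, fasting plasma glucose [FPG] in mg/dL, 2-hour OGTT in
mg/dL) plus self-reported diagnosis flags. Classification applies the
standard clinical cut points:

| test | prediabetes | diabetes |
|---|---|---|
| HbA1c | 5.7 – <6.5 % | ≥6.5 % |
| FPG | 100 – <126 mg/dL | ≥126 mg/dL |
| 2-h OGTT | 140 – <200 mg/dL | ≥200 mg/dL |

A person is *diabetic* if **any** available test is in the diabetes
range, *prediabetic* if no test reaches the diabetes range but at
least one is in the prediabetes range, otherwise *normal*. All
intervals are half-open, anchored at the diabetes cut points, so every
lab value maps to exactly one category. Diagnosis flags dominate lab
values: a diagnosed-diabetes flag yields `diagnosed_diabetes`
regardless of labs, and a diagnosed-prediabetes flag promotes
lab-prediabetes to `diagnosed_prediabetes`.

Before modeling, pregnant respondents and diagnosed-diabetes
respondents are excluded (pregnancy attributed first when both apply),
matching the analysis population of asymptomatic, non-pregnant adults
without known diabetes.

## 2. Risk models

The central model is a survey-weighted **polytomous (multinomial)
logistic regression** with three outcome levels — normal (reference),
total prediabetes, and undiagnosed diabetes:

    log [ P(Y = k | x) / P(Y = 0 | x) ] = α_k + x'β_k ,  k = 1, 2.

The design vector `x` has 26 reference-coded terms: male sex; five age
bands (18–34 reference); three race/ethnicity indicators (non-Hispanic
white reference); nine comorbidity indicators (hypertension, high
cholesterol, cardiovascular disease, kidney disease, eye disease,
depression, arthritis, asthma, back problems); overweight and obese
(normal BMI reference); household income (continuous, thousands of
dollars); insured; Medicaid; and three survey-wave indicators.

A companion **binary logistic regression** with the same design models
diagnosed prediabetes. Per-person risk profiles on the utilization
survey are

- `p_total_predm`, `p_undiag_dm`, `p_normal` — softmax of the
  polytomous linear predictors;
- `p_diag_predm` — from the binary model;
- `p_undet_predm = max(0, p_total_predm − p_diag_predm)` — the
  *undetected* prediabetes probability, clamped at zero because the
  two models are fitted separately and their difference is not
  guaranteed nonnegative.

### Estimation

The fitter is a hand-written Newton–Raphson maximizer of the weighted
pseudo-log-likelihood (this solver is the package's core numerical
component; `statsmodels` and `scipy.optimize` appear only in the test
suite as independent oracles):

- **Weight normalization.** Sampling weights are rescaled to mean 1
  inside the fitter. Point estimates are exactly invariant to the
  scale of the weights, and the model-based standard errors (inverse
  observed information) are those of a pseudo-MLE with effective
  sample size equal to the record count. Raw frequency-scale weights
  (~10⁴) would otherwise make model-based SEs meaninglessly small.
- **Convergence.** Iterate until the mean absolute score per record
  falls below 1e-8, up to 100 iterations, with step-halving (≤30
  halvings) when a step fails to improve the objective.
- **Conditioning.** A ridge of 1e-6 is added to the Hessian diagonal
  only if factorization fails. Empty outcome categories raise
  `DegenerateDataError`; non-convergence raises `ConvergenceError`
  carrying the last iterate.

### Model assessment

- **Concordance.** Percent concordant/discordant/tied pairs, Somers'
  D, and the c-statistic are computed in O(n log n) using midranks and
  per-distinct-score tie counts, verified in the test suite against
  O(n²) brute-force enumeration.
- **Split-sample validation.** A seeded half split (optionally
  stratified on outcome) fits each half and compares predicted versus
  observed weighted outcome totals by age band in the opposite half,
  plus the stability of the two half-fits' coefficients.
- **Calibration scale.** When an external prevalence total is
  trusted more than the model's aggregate, a single multiplicative
  scale `s = target / predicted` is applied to the predicted
  probabilities at projection time (e.g. 88.2/86.0 ≈ 0.975 was the
  magnitude used in the original analysis).

## 3. Screening rules and projection

Rules return per-record eligibility and an annual screening fraction:

- **ADA**: eligible if age ≥45, or overweight/obese with at least one
  risk factor (default set: hypertension, high cholesterol,
  cardiovascular disease, or minority race/ethnicity). Records
  eligible *solely* by age get fraction 1/3 — one third of a
  three-year screening cycle falls in the simulated year — while
  risk-factor-eligible records get fraction 1.
- **USPSTF** (2008-era): eligible with fraction 1 if the hypertension
  indicator is set.
- Custom rules can be composed from configuration (`any_of` clauses
  over equality/membership tests) or by subclassing `ScreeningRule`.

Projection is weighted expectation arithmetic. With weight `w`,
screening fraction `f`, calibration scale `s`, and per-person
probabilities `p`:

    screened            = Σ w·f
    detected (per cond) = Σ w·f·s·p

Totals are reported exactly; rounding (half away from zero) happens
only in presentation helpers (`screened_per_case`, `percent_more`,
`coverage_percent`, `percent_of`). Subgroup tables partition the same
sums by age, sex, race, BMI class, weighted income quartile, and
insurance, and are additive to the overall totals by construction.
`diabscreen.reference` ships the published 2010 national totals (in
thousands) used by the documentation and the acceptance script as
fixture inputs to these ratio/percentage operations.

## 4. Utilization and the primary-care opportunity

The utilization survey carries annual visit counts for five settings:
primary care office, non-primary-care office, hospital outpatient,
emergency department, and inpatient stays. Two products:

- **Usage by risk band.** `RiskBandSpec` partitions a predicted
  probability into half-open bands `[lo, hi)`; the table reports the
  weighted population and weighted mean visits per setting in each
  band.
- **Primary-care opportunity.** Among rule-eligible adults, the share
  with ≥1 primary care office visit, and the share of expected
  detections carried by that reachable subset. Only primary care
  office visits count as screening opportunities.

## 5. Synthetic data generator

The generator emulates the *structure* of the NHANES/MEPS workflow —
covariate mix, partial lab panels, sampling weights, visit counts —
without reproducing either survey's microdata. Scope and mechanics:

1. **Covariates** are drawn independently per record: sex
   (P(male)=0.50), age band (0.30/0.18/0.18/0.14/0.10/0.10),
   race/ethnicity (0.70/0.11/0.06/0.13), BMI class conditional on age,
   nine comorbidities from per-condition logistic links in age and BMI
   index, log-normal income (median $40k, σ=0.80), insurance
   (P=0.78) with nested Medicaid (P=0.06), survey wave (uniform over
   four waves), and pregnancy (4% of women).
2. **Diagnosed diabetes first.** A logistic model in the same design
   draws the diagnosed-diabetes flag; its intercept is solved at
   generation time (Brent root-finding on the mean probability) to hit
   the configured rate (10.5%). Drawing this flag *before* the latent
   glycemic state means the post-exclusion sample follows the
   generating polytomous model exactly — essential for honest
   parameter-recovery testing.
3. **Latent glycemic state** among the non-diagnosed follows the
   polytomous model with slopes equal to the natural logs of the
   published odds ratios and intercepts (−2.835, −5.452) solved
   numerically so the sample matches the study's approximate
   prevalences (~37% prediabetes, ~2.7% undiagnosed diabetes).
   Diagnosed prediabetes is then drawn among latent prediabetes at a
   10% conditional rate. Note the *marginal* diagnosed-prediabetes
   model is therefore not logistic with the conditional slopes; the
   fitted binary model estimates the marginal association, as the
   original analysis did.
4. **Labs** are assigned per the panel-availability rates (HbA1c 1.00,
   FPG 0.48, OGTT 0.31, with a fallback guaranteeing ≥1 test) and
   drawn uniformly within the classification range implied by the
   latent state, so classification inverts generation exactly unless a
   nonzero `discordance_rate` is configured.
5. **Visits** are Poisson with per-setting means linear in the true
   undiagnosed-diabetes probability (e.g. primary care office: base
   0.90, slope 12), with optional zero inflation.
6. **Weights** are log-normal (median 10,000, σ=0.50) — frequency
   scale, unrelated to outcomes, exercising the weight-invariance
   guarantees.

All draws come from a single `numpy` Generator per survey (child seeds
`[seed, 1]` and `[seed, 2]`), fully vectorized; generation of 50,000
records takes ~0.5 s.

## 6. Numerical choices

- Half-open classification intervals anchored at the diabetes cut
  points — every value maps to exactly one category.
- `p_undet_predm` clamped at 0 (separate-model subtraction).
- Weights normalized to mean 1 inside all fitters.
- Newton tolerance 1e-8 on the mean absolute score; ridge 1e-6 only on
  factorization failure; step-halving line search.
- Rounding half away from zero, applied only in presentation helpers,
  never to the accumulated totals.
- Screening fractions enter the expectation linearly by default
  (`fraction_mode="expected"`); `"bernoulli"` draws realized screening
  for stochastic sensitivity runs.

## 7. Decisions on underdetermined points

- The diagnosed-prediabetes probability is predicted for **all**
  adults in the projection survey and subtracted from total
  prediabetes, rather than being predicted only among predicted
  prediabetics.
- The age-only ADA screening fraction of 1/3 multiplies the
  *detection* expectations of that subgroup as well as its screened
  count (screening and detection scale together within the year).
- Split halves with odd input place the extra record in the first
  half; stratified splits balance each outcome level to within one
  record.
- Holdout validation compares lab-derived status (diagnosed-diabetes
  records excluded), consistent with the fitting sample.

## 8. Limitations

- Covariates are drawn independently (apart from BMI|age and the
  comorbidity links), so the synthetic population lacks the full
  correlation structure of real survey data; absolute projected totals
  are illustrative, not national estimates.
- Sampling weights are outcome-independent by construction; the
  pseudo-MLE's robustness properties under informative weighting are
  not exercised.
- The USPSTF rule uses the hypertension indicator as a proxy for
  sustained measured blood pressure >135/80 mm Hg.
- Lab values are uniform within category ranges — adequate for
  classification and screening arithmetic, not for modeling continuous
  glycemia.
- Visit counts are independent Poisson per setting given risk; no
  within-person correlation across settings.
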