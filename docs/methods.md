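# Methods

## The evaluation problem

National guidance moved prophylactic antibiotics for caesarean section from
administration after cord clamping to administration before the skin
incision. Pre-incision antibiotics cross the placenta, so the change exposes
the baby at a moment when the gut microbiome is being founded; the question
is whether that exposure shifts the incidence of childhood immune-mediated
conditions (asthma, eczema, allergy, infection) while it reduces maternal
surgical-site infection. Individual antibiotic timing is not recorded in
routine data, so the evaluation is a **controlled interrupted time series
(CITS)**: hospitals adopted the pre-incision policy in different calendar
years, caesarean births before/after a hospital's change year are compared,
and **vaginal deliveries form the control series** — the policy does not
apply to them, so shared secular trends in diagnosis are differenced out.

This package implements that design end to end on synthetic data: cohort
generation, exposure assignment, person-time expansion, model fitting,
reporting, and the power/misclassification simulation. Real primary-care
and admissions databases are licensed and cannot ship with the package; the
generator reproduces the statistical structure the design relies on, not
the datasets.

## Exposure regimes

Two observation regimes for the same latent exposure (caesarean birth under
a pre-incision policy):

* **hospital (indicator)** — the hospital's policy-change year is known
  from a survey. A caesarean birth is exposed iff its birth year is
  strictly greater than the change year; births in the change year itself
  are excluded (policy switched mid-year, timing unknowable at year
  resolution); births at hospitals whose policy is unknown are excluded.
  Vaginal births are always unexposed and retained (a switch
  `exclude_vaginal_in_change_year` removes them too; default keeps them,
  since only caesarean exposure is policy-dependent).
* **national (probability)** — only the national uptake curve is known.
  Each caesarean birth in year *y* receives the probability
  p(y) = (caesarean births in year *y* at hospitals whose change year < *y*)
  / (caesarean births in year *y* at known-policy hospitals), weighted by
  birth counts so the probability applies to births rather than to
  hospitals. A year with no informative births is flagged undefined, never
  silently zero.

The exposure covariate enters the log-rate linearly, so a probability *p*
contributes *p*·β and exp(β) is the fully-exposed-versus-unexposed
incidence rate ratio (IRR).

## Person-time

For each outcome, time at risk runs from birth to the earliest of the fifth
birthday, loss to follow-up, the study end (31 December 2018 by default),
or the first diagnosis; the event indicator is 1 iff the diagnosis attains
that minimum (ties count as events — first diagnosis defines the outcome).
Follow-up is split into one row per year of life (ages 0–4, half-open
intervals [a, a+1)), the final partial year carrying the fractional time.

Day-level conventions (not dictated by the design; chosen once and fixed):
years are days/365.25; censoring at study end or loss to follow-up counts
the censoring day (the child was observed through it), diagnosis does not;
the fifth birthday contributes exactly 5.0 years; 29 February birthdays map
to 28 February. Conservation (row times sum to follow-up within 1e-9 years)
and the age bound are enforced by property tests.

## Models

* **Primary-care variant**: Poisson regression, log link, log person-time
  offset; covariates year of birth, age (year of life), their full
  interaction, delivery type, exposure. Year and age are categorical with
  the earliest level as reference (flexible rather than linear trends; a
  linear-coding switch exists). One observation per child-year.
* **Admissions (hes) variant**: year of birth, delivery type, exposure; no
  age terms, matching the covariate set used for hospital-recorded
  outcomes. Change-year and unknown-policy births are excluded upstream.
* **Maternal variant**: Poisson with log link on the binary six-week
  postpartum indicator with a unit offset — a risk-ratio model, chosen over
  logistic odds ratios because postpartum infection after caesarean is not
  rare (~8.6%) and the target estimand is labelled a rate ratio. Adjusted
  for delivery year and delivery type.
* **Continuous variant**: OLS difference in means (length of stay),
  adjusted for year and delivery type.
* **Subgroup interaction**: an exposure × elective-caesarean term added to
  the CITS model; reported as per-subgroup IRRs and a Wald p-value for
  their ratio.

Wald 95% intervals on the log scale with z = 1.959964 throughout. A
rare-outcome guard suppresses model fitting below 200 events, reporting
counts only. Before fitting, person-year rows are aggregated over unique
covariate cells (events and time summed) — exact for a log-link Poisson
model with offset, and it makes fits on large simulated cohorts take
milliseconds. Fitting is delegated to statsmodels GLM/OLS; the design
construction, aggregation and exposure handling are this package's own.
Degenerate designs (constant exposure, empty exposure strata, rank
deficiency) are flagged rather than silently estimated; IRLS convergence is
relative tolerance 1e-10 within 100 iterations. No overdispersion
adjustment by default (a quasi-Poisson scale option exists): the outcome is
a first event per child, which if anything is slightly under-dispersed.

## Synthetic cohort generator

The generator emulates the features the CITS analysis assumes; defaults are
the study conditions.

| parameter | default | rationale |
|---|---|---|
| birth years | 2006–2018 | study inclusion window |
| caesarean fraction | 0.281 | observed caesarean share |
| elective share of caesareans | 0.40 | typical UK elective/emergency split |
| change-year mix | 0.40 unknown, 0.05 never, 0.55 spread 2008–2014 | staggered adoption; ~55% of births at known-change hospitals |
| baseline rates | asthma 9.9, eczema 71.9 /1000 py | observed incidence scale |
| age multipliers | (0.7, 1.3, 1.2, 1.0, 0.8) | first-event hazard peaks in toddler years |
| year trend | 0.99 per calendar year | mild secular decline in diagnosis |
| delivery RR | 1.1 | modestly higher risk after caesarean |
| true IRR | 1.0 | null unless a scenario sets otherwise |
| compliance | 1.0 | audits report 70–100%; scenarios use 0.85 |
| LTFU | 0.03/year geometric | no dropout mechanism reported; independence assumed |
| multiple births | 0.03 | twin share of births |
| maternal risks | composite 8.61% vs 1.43%, RR 0.70; wound 8.09% vs 1.02%, RR 0.62 | observed delivery-type risks and protective effects |
| length of stay | 3.0 vs 1.5 d, shift −0.23 d, SD 1 d | observed medians and adjusted difference |

Event times use a piecewise-constant hazard per year of life
(λ = baseline × age multiplier × trend^(year−first) ×
delivery_rr^[caesarean] × IRR^[exposed], exponential waiting time within
each year), matching the per-year-of-life analysis rows. Birth dates are
uniform within the birth year — the design works at year resolution, so
finer calendar structure would add nothing. Twin pairs share mother,
hospital and birth date; exactly one child per pair is retained at random,
mirroring the analysis rule. Hospitals answering "unknown" in the survey
still carry a latent change year (drawn from the known part of the mix,
renormalised): the truth exists, the survey just fails to observe it, which
is precisely what makes probability-based exposure a misclassification
problem. Change-year births are truly unexposed in the generator (the
hospital regime excludes them regardless).

What the generator does **not** emulate: clinical coding systems,
practice/hospital-level clustering beyond the policy year, regional
geography, covariate-driven confounding (maternal age, BMI, deprivation…),
within-year adoption timing, recurrent events, or sibling correlation.
Passing tests therefore show the estimator recovers effects under the
design's own assumptions — they cannot show robustness to confounding
structures the generator does not contain.

## Simulation experiments and problem sizes

Each replicate runs the whole pipeline (generate → survey → exposure →
person-time → fit); per-replicate seeds derive from a master seed via a
counter, so results are independent of sweep order. Aggregates: power
(rejection of IRR = 1 at α = 0.05), 95% CI coverage of the true IRR, mean
log-IRR bias, and attenuation 1 − mean(log IRR̂)/log(IRR).

Desk-scale problem sizes, chosen from a Wald power calculation before the
experiments were frozen:

* **null recovery**: 300 replicates × 100 000 children, indicator
  exposure — bias, coverage and type-I error;
* **power**: 50 replicates × 400 000 children at IRR 1.18, indicator
  exposure at the asthma event scale (Wald calculation: per-fit
  SE_log ≈ 0.03, predicted power ≈ 0.99). At 100 000 children the same
  scenario has SE_log ≈ 0.09 and predicted power ≈ 0.45 — detecting 1.18
  genuinely requires a cohort within an order of magnitude of the full
  study;
* **attenuation**: 100 replicates × 100 000 children at IRR 1.3 with 85%
  compliance under the national-probability regime; expected attenuation
  ≈ 15%, consistent with the at-most-15%-underestimation allowance built
  into the original power statement.

## Numerical and display choices

Rates are 1000·n/py with log-normal Wald intervals rate·exp(∓1.96/√n)
(this reproduces the published eczema interval to the printed precision);
undefined at zero events. Display rounding is decimal half-up to two
places (the published tables' apparent convention; the rounding rule is not
stated there), with full-precision values retained in raw CSV companions.
Counts of five or fewer can be masked as "≤5" behind a flag, mirroring
small-number suppression rules. Zero follow-up yields an empty row list
with a warning; zero denominators raise.

## Known limitations

* Year-resolution exposure: within-year adoption timing is not modelled,
  so change-year births can only be excluded, not classified.
* No random effects for hospital or practice, no sibling designs, no
  robust/clustered standard errors — listed as out of scope.
* The generator's independence assumptions (LTFU independent of outcome,
  no confounders) make recovery experiments a verification of the
  estimator, not evidence about bias in real data.
* The uptake curve treats the survey as error-free for known hospitals;
  survey misreport is not modelled beyond the "unknown" mass.
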