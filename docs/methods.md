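# Methods

This note documents the modelling and numerical choices behind
`shouldercoi`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Cohort model

**Qualifying codes.** 29 ICD-10 codes, normalized by stripping dots and
whitespace and upper-casing, map to four diagnosis categories; compact
ranges ("M751-9") expand over the final digit.  Classification is a total
function — unknown codes map to `not_qualifying` — and the four code sets
are pairwise disjoint.  A patient with qualifying codes from several
categories is assigned the category of the first qualifying visit; no
clinical precedence is defensible from coded data alone.

**Inclusion.** Age 20–64 inclusive, residence in one of the two study
municipalities, and at least one in-window visit carrying a qualifying
code.

**Episodes.** "At least one visit per month" is operationalized as a
maximum inter-visit gap of 31 days.  A gap whose interval overlaps the
holiday window (default July 1 – August 15, the Swedish primary-care
holiday season) may be up to twice that; doubling (rather than suspending
the rule entirely) keeps the rule meaningful across the summer while
tolerating clinic closures.  Episode durations bucket into half-open day
intervals [0, 42], (42, 84], (84, 182], (182, ∞); the 7–12/12–26-week
labels overlap at week 12, which we assign to the 7–12-week bucket.
Censoring flags mark episodes touching a window boundary.  Construction is
invariant to the input ordering of visits.

## Costing model

Direct costs are unit counts × unit prices (EUR, 2009 price level): GP
visit 107, PT session 50, shoulder x-ray 65, ultrasound 124.  The medicine
price per filled prescription defaults to 718/58 ≈ 12.4 — the cohort's
total medication cost divided by its prescription count — because the
underlying hospital-pharmacy price list is not public.  Every prescription
is costed as filled once.

Sick leave is converted to full-day equivalents by weighting each
prescribed calendar day (clipped to the window) by grade/100
(`graded_weighting`, the default).  This is the only reading consistent
with the published aggregate: 1844 listed days at EUR 205 would give
EUR 378 020, while the printed sick-leave total of EUR 355 610 equals
≈1735 day equivalents × 205, i.e. the graded conversion.  A `full_day`
policy (every prescribed day counts fully) is retained as a switch.
Overlapping prescriptions are merged day-wise taking the maximum grade.

The daily productivity cost is income × (1 + social fares + indirect
taxes) with default loadings 0.40 and 0.28; the packaged schedule carries
the resulting EUR 205/day as the authoritative price, and
`daily_productivity_cost` is exposed for users with their own regional
income data.  The friction-cost method rescales the human-capital value by
a factor of 0.387 (default), reflecting that production is only lost until
a replacement worker is trained.

Costs are carried at full floating precision; rounding (half-up to whole
euros, percentages to one decimal) happens only in rendered reports.

Secondary care is estimated, not measured: orthopaedic outpatient visits
(EUR 335), MRI (EUR 308, default count 10) and ambulatory shoulder surgery
(EUR 2420) multiply counts taken from the cohort's referral/surgery fields
or supplied directly.  Annual burden is the six-month total × 2, which
assumes stationary patient flow across half-years.

## Analytics

Confidence intervals are z-normal, mean ± 1.96·sd/√n.  This choice is
deliberate: applied to the published mean/SD/n it reproduces the printed
intervals exactly after euro rounding (2069.4 ± 786.3 → 1283–2856;
326.2 ± 53.4 → 273–380), so it is the convention the original analysis
used.  With n < 2 the CI is reported as undefined rather than failing.
Medians and quartiles use the inclusive (linear-interpolation) convention
and are only available from patient-level data; cohort margins flag them
absent.

The high-cost subgroup is defined by total cost *strictly greater* than
the threshold (default EUR 1000).  Concentration shares sort totals
descending and take the top ⌈fraction·n⌉ patients.  No multiple-testing
correction is applied anywhere (none is applied in the source analysis).

The regression is OLS of log(cost) on place of treatment, gender and age
with an intercept, via statsmodels.  Zero-cost patients are excluded from
the log fit and their count reported — this mirrors published regression
n's that fall one short of the cohort n.  Rank-deficient designs raise an
error naming the collinear covariate.  The regression *procedure* is in
scope; its published coefficient values are not reproducible without the
original patient-level records and are not targeted.

## Sensitivity engine

The model is exactly linear in unit prices, so the engine's output must
match the closed form

pct_change_total = Σ<sub>c</sub> δ<sub>c</sub> · (base total of c) / (base grand total) · 100

to machine precision, multi-way scenarios superpose, and healthcare-cost
changes are invariant to sick-leave perturbations and vice versa — all of
which the tests assert.  Scenarios accept arbitrary multiplier sets
(> −1, i.e. no negative prices) plus an optional valuation-method switch;
the empty scenario is the identity and reproduces the base case
bit-for-bit.  Perturbed CIs require patient-level data (the perturbed
per-patient totals); from margins alone they are reported as unavailable
rather than approximated from unknown component covariances.

One cell of the published scenario table is *not* regenerable: the
four-component multi-way row prints changes (5.7% total / 35.8%
healthcare) that exceed the sum of its own one-way constituents (5.6 /
35.6) and the linear recomputation from the printed component totals
(5.60 / 35.52).  The printed row is internally inconsistent with the rest
of the table; the engine reports the linear value and the corresponding
acceptance check documents the discrepancy by failing for that row.

## Synthetic-data generator

The generator emulates the *statistical structure* of a six-month
primary-care shoulder-pain cohort; its defaults are the study conditions
(n = 204, ages 20–64 with mean 48/SD 11, 103/204 female, category weights
181/10/7/6, window January–June 2009).

* **Visit counts** are zero-inflated negative binomial (zero inflation 0
  by default), moment-matched to mean/SD targets 0.89/0.97 (GP) and
  3.91/7.40 (PT).  The PT variance is ~14× its mean; a negative binomial
  with r ≈ 0.3 is the simplest family that reaches it.
* **Everyone presented at least once**: draws with zero GP and zero PT
  visits receive one index visit (GP with probability equal to the GP
  share of mean visits).  The sampling means are pre-shrunk by a
  fixed-point iteration so the *final* marginal means still equal the
  targets; the SD targets are matched before this correction, leaving a
  small (<2%) residual distortion in the realized SDs.
* **Sick leave**: 20% of patients have any; durations are lognormal with
  (μ, σ) solved numerically (capped-lognormal moment equations, scipy
  root-finding) so that the *window-capped* durations have the target
  conditional moments (45.2/51.2 days).  Matching the uncapped moments
  instead would bias the in-window mean down by ≈0.4 days.  Occurrence and
  duration are coupled to the PT count through a Gaussian copula
  (correlation 0.4 by default), so long absences co-occur with heavy
  physiotherapy use and the top cost quintile reliably carries ≈90% of
  total cost — matching the published concentration, with >60% guaranteed
  structurally in ≥95% of replicate seeds.
* **Partial grades**: 11% of each spell's days (rounded) are prescribed at
  a grade drawn uniformly from {25, 50, 75}%; the source states the range
  but not the grade frequencies.  With the graded conversion this yields
  ≈8.5 day equivalents per patient, consistent with the published
  sick-leave cost.
* **Other events**: x-ray/ultrasound/prescription are Bernoulli with
  probabilities 0.28/0.11/0.28 (the published mean counts; the printed
  count SDs 0.45 and 0.31 are exactly Bernoulli SDs, supporting the
  family choice).  Referral, surgery-given-referral and postoperative-
  rehab probabilities default to 29/204, 4/29 and 19/204.
* **Visit timing**: inter-visit gaps are uniform on 3–28 days (compressed
  proportionally when a long history exceeds the window), so every
  simulated patient has exactly one episode under the gap rule; the first
  visit is placed uniformly over the feasible window.

What the generator does **not** emulate: episode-duration margins (the
published 50%-within-6-weeks split is an emergent, not calibrated,
property and the synthetic cohorts skew shorter); seasonal visit patterns
and holiday gaps; covariate effects on cost (age, sex, municipality are
independent of utilization by construction — which is what the null
regression tests exploit); comorbidity; employment status; real personal-
identity formats; and the fine structure of repeated prescriptions per
patient (at most one medication event is drawn).  Passing tests on
synthetic cohorts therefore validate the pipeline mechanics and the
calibrated margins, not clinical realism at the individual-trajectory
level.

Determinism: one `numpy` generator seeded once drives all sampling in a
fixed order, so identical (config, seed) gives byte-identical output
tables.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks use 200 replicate cohorts of 204 patients (standard
error of the GP-visit mean ≈ 0.005 against a ±0.05 check band, and of the
sick-leave-day mean ≈ 0.14 against ±0.6); the unit-test calibration uses a
lighter 40-seed version of the same checks.  Regression parameter recovery
uses one simulated cohort of n = 2000 (coefficient SE ≈ 0.036 against a
±0.15 band); null-effect coverage uses 100 replicate default cohorts.  The
margins-based reproductions are closed-form and run in milliseconds.

## Known limitations

* The published component totals are internally inconsistent at the
  EUR 10–60 level with printed unit counts × unit prices (e.g. 181 GP
  visits × 107 = 19 367 vs a printed 19 429), presumably from rounding of
  unrounded per-visit costs.  The printed totals are treated as canonical;
  no synthetic cohort can satisfy counts and totals simultaneously.
* Margins-based runs cannot produce medians, IQRs, episode tables or
  perturbed CIs; the reports mark these unavailable rather than imputing.
* The friction-cost method is a fixed rescaling, not a spell-by-spell
  friction-period model; short spells are not treated differently from
  long ones.
* Costs attributable to comorbidity, co-payments, over-the-counter
  medication and post-operative sick leave prescribed in secondary care
  are outside the measured model, as in the source design.
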