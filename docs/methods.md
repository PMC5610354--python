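# Methods

## The design

`bacikit` implements a before-and-after control-intervention (BACI)
evaluation of an at-home telemonitoring service for chronically ill
patients aged 50 and over. Each monitored ("test") patient is case
matched to one or more usual-care controls; all event histories —
medical and pharmaceutical benefit claims, hospital admissions, deaths
— are synchronised to the day telemonitoring started (day 0; controls
inherit their partner's anchor), which averages out seasonal effects.
The intervention effect is read from the *change in slope* of each
outcome's time trend at day 0, compared between arms, rather than from
a simple before/after mean difference: chronically ill cohorts
deteriorate, so every outcome is expected to drift upward and a flat
after-period is already a treatment effect.

## Binning and transforms

Claims are totalled per patient into 30-day bins, 36 before and 12
after intervention (≈3 years / 1 year); hospital admissions and length
of stay (LOS) use 100-day bins (11 before, 4 after) because admissions
are sparse and 30-day hospital bins would be mostly zero. Bins are
half-open `[b·w, (b+1)·w)`; day 0 belongs to the first after-bin. A bin
cut short by death is flagged unobserved and excluded — zero-filling
would manufacture an expenditure decline out of mortality. Per bin, the
outcome is averaged across the observed patients of an arm (multiple
controls of one test patient are first averaged into a single
"effective control").

The regression scale is chosen by residual normality: Shapiro–Wilk on
the residuals of the segmented linear fit under each candidate
transform (identity, sqrt, log), keeping the first whose p ≥ .05. The
test is applied to residuals rather than raw values because residual
normality is what the linear model assumes. Cost data are classically
sqrt-transformed; note that a cross-patient mean of ~100 patients is
already close to Gaussian, so on well-behaved synthetic data the
selector legitimately retains the identity scale. Transform selection
happens *after* cross-patient averaging (the averaged series is what is
modelled). Control-minus-test difference series are analysed
untransformed.

## Segmented regression and the slope test

On the chosen scale the model is

    y_t = b0 + b1·t + b2·I(t≥0) + b3·t·I(t≥0) + e_t,

ordinary least squares on the averaged series. `b3` is the change in
slope at intervention; its two-tailed t test is the ANCOVA slope
comparison (and equals the partial F test dropping the interaction —
asserted to 1e-10 in the suite). Fitting before and after separately
reproduces the same segment coefficients, so the interaction estimate
is exactly `slope_after − slope_before`. A second, descriptive contrast
fits the pooled single line and tests its slope against the before-only
line (the "does adding the after data move the line?" check); the two
point sets share data, so it is reported as a descriptive diagnostic,
not an independent-samples test.

Outliers are screened iteratively: refit, remove the worst point if its
externally studentized residual exceeds 3 in absolute value, stop after
at most 10% of bins or when a period would drop below 3 bins. The
threshold/cap are this package's choices; published analyses of this
kind state that outliers were excluded without giving a rule.

Prediction intervals are the standard OLS new-observation intervals,
`ŷ ± t·s·sqrt(1 + 1/n + (t−x̄)²/Sxx)`; empirical coverage is verified
at 95% ± 1.5 points over 10,000 (refit, fresh draw) pairs.

## Annualised rate curves and savings

A sqrt-scale segment `a + b·t` back-transforms to a bin expectation
`(a+bt)²`, annualised by 365/w into the quadratic rate curve
`rate(t) = (365/w)(a+bt)²` (AUD, admissions or days per year; the unit
tag travels with the curve and mixing units is an error). The before
curve, fitted on 3 pre-intervention years, is projected across the
after-year; the after curve is fitted on the after bins. Savings over
the year are the area between the curves, integrated in closed form
(`∫(a+bt)²dt`; verified against adaptive quadrature at 1e-8 relative).
Integration starts at the curves' intersection day when one exists
inside the year — the intervention needs time to take effect, and
starting at day 0 overestimates savings — else at day 0. The
intersection solves the linear equation on the sqrt scale. Identity
scale curves (difference series) annualise linearly, clipped at zero,
with piecewise-linear integration. The 1-year rate reduction is
`100·(1 − rate_after(T)/rate_before(T))` at T = 365 days. If the
sqrt-scale line changes sign inside the integration window the squared
extrapolation is refused with an error rather than silently producing a
U-shaped cost curve. ROI is annual saving divided by annual service
cost.

Annualisation squares first, then scales: `rate = (365/w)·(a+bt)²`.
Scaling the sqrt-scale value before squaring would change units
incoherently; squaring first yields the quadratic annual-cost curves
the method is built around.

## Mortality standardisation

Age-specific death rates (ASDR = 100·deaths/pop per 10-year band) from
a reference register give a cohort's expected deaths by indirect
standardisation (Σ band count × ASDR/100); "deaths saved" is expected
minus observed. Two arithmetic paths are reported: full precision
(canonical — all chaining unrounded, rounding only at presentation) and
"as printed", which replays the chained rounding of a published summary
table (ASDRs rounded to 2 dp, band products rounded, totals summed from
rounded cells). The two can disagree in the last digit — e.g. a band
expectation of 14×0.1361 = 1.9054 → 1.91 as printed versus
14×60/441 = 1.9048 → 1.90 at full precision, propagating to totals
13.68 vs 13.67 — so reproducing a published table cell-for-cell
requires the as-printed path. The same applies to the crude-rate
reduction (one-decimal rates give 48.5%, full precision 48.7%); both
are reported, the as-printed value flagged as such. All presentation
rounding is half-up, matching hand-computed tables. The bundled
worked-example register carries one further documented discrepancy in
its original source (an abstract range of 41.3–44.5% that the table
arithmetic does not produce); this package reproduces the table-backed
values 41.5% / 48.5%.

## Baseline comparisons

Per-patient costs are summed over two 100-day windows: `[-100, 0)`
before the start, and the last 100 days of each patient's own
monitoring period (monitoring durations varied, so the end anchor is
per-patient: death day + 1 if the patient died, else the configured
horizon). Matched-pair comparisons use the paired t test for symmetric
paired differences and the Wilcoxon signed-rank test otherwise, with
the symmetric/skewed dispatch operationalised by Shapiro–Wilk at
α = .05. Unpaired group comparisons dispatch to chi-square (Fisher
exact for 2×2 tables with an expected cell < 5), two-sample t, or
Wilcoxon rank-sum. Group means carry t-based 95% CIs (the CI method is
labelled in the output since summary tables of this kind often omit
it). The end-of-trial arm difference is annualised by 365/100. No
multiplicity correction is applied across baseline tests.

## The synthetic cohort generator

The generator produces the data structure the analysis assumes, and
only that structure:

* **Claims.** For 30-day bin `t` the expected total is
  `(s0 + β·(t+36) + δ_arm·max(t,0))²` with `s0 = baseline_sqrt_cost`,
  `β = pre_slope_sqrt`, and `δ` the per-arm post-intervention drift
  change. A per-bin sqrt-scale target is drawn as the line plus
  N(0, `cost_noise_sd`) noise (clipped at 0), then realised as
  Poisson-many gamma-distributed claim amounts rescaled to hit the
  target exactly — sparse, realistic-looking claims whose binned sqrt
  is exactly normal about the line. Each claim is tagged medical or
  pharmaceutical with fixed probability, so each category's sqrt-mean
  stays linear (scaled by √fraction).
* **Admissions.** Gamma-Poisson (negative-binomial-like) counts per
  100-day bin, mean `admission_rate_per_100d` multiplied per arm after
  day 0; per-admission LOS is 1 + Poisson(mean−1), post-multiplied per
  arm; a small fixed fraction of events are same-day (non-overnight)
  attendances, which the analysis filter excludes. Admission horizons
  are bin-aligned (−1100..+400 days) so all 15 analysis bins are fully
  covered, while claims use the 30-day-aligned −1080..+360.
* **Deaths.** Constant per-day hazard within each age band, calibrated
  so the one-year death probability equals the band's configured ASDR,
  applied from day 0 over the after-period: a trial cohort is alive at
  enrolment by construction, so no pre-intervention deaths are
  simulated. Death truncates all event streams and flags partial bins
  unobserved.
* **Matching structure.** Controls are generated as exact matches of
  their test partner on gender, diagnosis group, SEIFA and age band,
  with age re-drawn within the band, and inherit the partner's
  intervention anchor.

Default conditions: 100 test patients matched 1:2; age distribution
(0.41, 0.31, 0.14, 0.13, 0.01) over the bands 50–100; 67% male;
diagnosis mix 50/30/20 cardiovascular/respiratory/diabetes; band ASDRs
(9.44, 14.84, 13.61, 21.98, 44.05)%; `s0 = 20 √AUD`, `β = 0.12 √AUD`
per bin (≈$590/30 days at intervention, in the range of the bundled
expenditure summaries), `δ_test = −0.06` (post-intervention drift
halved — the canonical recovery scenario), `δ_control = 0`;
`cost_noise_sd = 2 √AUD` per patient-bin (cross-patient mean noise
≈0.2 √AUD at n=100); 0.6 admissions/100 days with post-multiplier 0.5
(test), LOS mean 7 days with post-multiplier 0.4 (test); ~3 claims per
patient-bin, 65% medical, admission dispersion 2, 95% overnight.

What the generator does **not** emulate: calendar seasonality,
heavy-tailed individual claim amounts beyond the gamma shape,
correlation between expenditure level and death hazard, enrolment-date
effects, or any mortality benefit of the intervention (both arms share
hazards). Passing recovery tests therefore demonstrates that the
machinery is unbiased and calibrated under its own model assumptions —
not that real claims data satisfy those assumptions.

## Problem sizes in the test suite

The acceptance properties run at sizes chosen to give comfortable
Monte-Carlo margins on one CPU: 1000 null replicates for the type-I
rate of the slope test (tolerance 0.05 ± 0.014), 500 simulated
100-patient cohorts for power (≥80%) and for recovery of the planted
1-year rate reduction (mean within ±5 percentage points of the
analytic value implied by the generating coefficients), 10,000
fit/draw pairs for prediction-interval coverage, 1000 random curve
pairs for the closed-form-vs-quadrature check, and exhaustive
hypergeometric enumeration for Fisher p-values on small tables.

## Numerical conventions

* Day offsets are integers; day 0 is the first monitored day.
* OLS via statsmodels; coefficients agree with the closed-form
  normal-equations solution to 1e-10.
* Degenerate fits (zero residual variance) report r² = 0 for constant
  series, p = 1 for an exactly absent slope change and p = 0 for an
  exact nonzero one, and zero-width prediction intervals.
* Matching ties break lexicographically by patient id; greedy
  assignment processes test patients in ascending age. Hungarian /
  propensity-score matching is out of scope.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configurations give
  byte-identical CSV and JSON outputs.
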