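# bacikit

Before-and-after control-intervention (BACI) analysis of matched
health-service cohorts, built for evaluating at-home telemonitoring of
chronically ill patients on claims expenditure, hospital admissions,
length of stay and mortality.

Chronically ill cohorts deteriorate over time, so every outcome drifts
upward and a naive before/after mean comparison understates any
benefit. The BACI design instead matches each monitored ("test")
patient to usual-care controls, synchronises all event histories to
the day monitoring started, and reads the intervention effect from the
**change in slope** of each outcome's time trend at day 0 — in each
arm and in the control-minus-test difference series.

## What it computes

For an outcome binned into 30-day (costs) or 100-day (hospital)
periods, averaged across patients per bin, on a normalising transform
scale (typically √):

* **Segmented regression / ANCOVA** — the model
  `y_t = b0 + b1·t + b2·I(t≥0) + b3·t·I(t≥0)`; the two-tailed t test of
  `b3` is the before/after slope comparison (equal to the partial F
  test), with outlier screening, goodness-of-fit measures and 95%
  prediction intervals.
* **Model-based annual savings** — a sqrt-scale segment `a + b·t`
  annualises to the quadratic rate curve `(365/w)(a+bt)²`; savings over
  the after-year are the closed-form area between the projected
  before-curve and the actual after-curve, accrued from the curves'
  intersection day, plus the 1-year rate reduction
  `100·(1 − rate_after(T)/rate_before(T))` and ROI.
* **Age-standardised mortality** — age-specific death rates
  (ASDR = 100·deaths/pop per 10-year band) from a reference register,
  expected deaths by indirect standardisation, deaths saved, and crude
  death-rate comparisons, each in full precision and in a
  rounded-as-printed variant that reproduces published tables
  cell-for-cell.
* **Baseline matching checks** — 100-day windowed expenditure sums with
  paired t / Wilcoxon signed-rank comparisons and annualised arm
  differences.
* **A synthetic cohort generator** — matched test/control cohorts with
  claim streams whose binned √cost is linear in time (drift change at
  day 0), overdispersed admissions, and age-band constant-hazard
  deaths, so the whole pipeline is testable without confidential
  patient records.

## Worked example: age-standardised mortality

The bundled register (1,429 chronically ill patients, deaths
cross-checked against state registers) standardises a 100-patient
monitored cohort with 8 observed deaths:

```python
from bacikit import mortality as mort
from bacikit.datasets import master_register, monitored_cohort_mortality

reg, coh = master_register(), monitored_cohort_mortality()
table = mort.compute_asdr(reg["pop"], reg["deaths"])
cmp = mort.expected_deaths(table, coh["n"], coh["observed_deaths"])
print("band ASDRs (%):", list(cmp.printed["asdr_pct"]))
print("expected deaths:", cmp.printed["expected_total"],
      "(full precision:", round(cmp.expected_total, 4), ")")
print("deaths saved:", cmp.printed["deaths_saved"],
      "-> reduction:", cmp.printed["reduction_pct"], "%")
```

prints

```
band ASDRs (%): [9.44, 14.84, 13.61, 21.98, 44.05]
expected deaths: 13.68 (full precision: 13.6749 )
deaths saved: 5.68 -> reduction: 41.5 %
```

i.e. 13.68 deaths were expected at register rates but only 8 occurred —
a 41.5% mortality reduction. (The as-printed value 13.68 replays the
chained rounding of published tables; the full-precision chain gives
13.67 — see `docs/methods.md`.)

## Worked example: simulated intervention effect

Generate the canonical synthetic cohort — 100 test patients whose
sqrt-scale cost drift (+0.12 √AUD per 30-day bin) is halved at
intervention — and recover the effect through the full pipeline:

```python
from bacikit import (CohortConfig, generate_cohort, bin_patients, average_patients,
                     apply_transform, compare_slopes, annualize, estimate_savings)

cfg = CohortConfig(seed=1)
cohort = generate_cohort(cfg)
tests = cohort.patients[cohort.patients["arm"] == "test"]
claims = cohort.claims[cohort.claims["patient_id"].isin(set(tests["patient_id"]))]
totals, _ = bin_patients(claims, tests, width=30)
series = apply_transform(average_patients(totals, "cost", 30), "sqrt")

cmp = compare_slopes(series)
est = estimate_savings(annualize(cmp.fit_before, 30), annualize(cmp.fit_after, 30))
```

```
sqrt-scale slope before: +0.1166 /bin (configured +0.12)
slope change at day 0:  -0.0718 (configured -0.06), p = 0.00016
projected spend 6,291 AUD/yr, actual 6,113 AUD/yr
saving 178 AUD (2.8%), 1-yr rate reduction 5.5%, curves cross at day 67
```

The fitted before-slope and the slope change recover the generating
coefficients within sampling noise, the slope-change test is clearly
significant, and the savings machinery integrates the two quadratic
annual-cost curves from their crossing day.

## Command line

```sh
bacikit simulate --config cohort.yaml --out data/
bacikit match    --patients data/patients.csv --out pairs.csv --k-max 2
bacikit analyze  --patients data/patients.csv --claims data/claims.csv \
                 --admissions data/admissions.csv --out results/
bacikit mortality --register register.csv --cohort cohort.csv --out mortality.json
bacikit report   --in results/
```

CSV schemas are documented in `docs/formats.md`; `report.json`
validates against the schema shipped at
`src/bacikit/schemas/report.schema.json`.

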