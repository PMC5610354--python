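# CSV and JSON formats

All dates are signed integer day offsets from the patient's
intervention anchor (day 0 = first monitored day). All CSVs have a
header row and no index column.

## patients.csv

| column | type | notes |
|---|---|---|
| patient_id | str | unique, opaque |
| arm | str | `test` or `control` |
| age_at_intervention | float | years, ≥ 50 |
| gender | str | `M` / `F` |
| diagnosis_group | str | `cardiovascular`, `respiratory`, `diabetes` |
| seifa | int | ordinal socioeconomic level, 1..levels |
| intervention_date | int | calendar anchor day; controls inherit their partner's |
| death_day | float/empty | day offset of death; empty if alive |
| matched_test_id | str/empty | generator ground truth; empty for test patients |

## claims.csv

| column | type | notes |
|---|---|---|
| patient_id | str | |
| day | int | signed offset |
| category | str | `medical` / `pharmaceutical` |
| cost | float | AUD, ≥ 0 |

## admissions.csv

| column | type | notes |
|---|---|---|
| patient_id | str | |
| admit_day | int | signed offset |
| los | int | days, ≥ 1 for overnight stays |
| overnight | bool | non-overnight attendances are excluded from analysis |

## pairs.csv

`test_id, control_ids (joined by ';'), match_distance`

## binned.csv

`outcome_label, arm, bin_index, n_observed, value, transform`

## register.csv / cohort.csv (mortality subcommand)

`band, pop, deaths` and `band, n, observed_deaths`; bands must match
row-for-row between the two files.

## fits.json / savings.json

Per-outcome, per-arm extracts of the report: segment coefficients,
p-values and goodness-of-fit measures (`fits.json`); projected/actual
annual totals, saving, rate reduction and intersection day
(`savings.json`).

## report.json

Validates against `src/bacikit/schemas/report.schema.json` (generated
from the `bacikit.pipeline.AnalysisReport` pydantic model). All numbers
are full precision; presentation-rounded views appear only under
`mortality.as_printed`.

## cohort_config.json

Sidecar written next to simulated CSVs: the full `CohortConfig`
including the seed, sufficient to regenerate the cohort byte-for-byte.
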