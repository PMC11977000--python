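# Data dictionary

## Cohort table (`cohort.csv`, `cohort_derived.csv`)

One row per participant.  Generated by `coda-activity simulate cohort`
or the pipeline; consumed by the derive and fit stages.

| column | description |
|---|---|
| `participant_id` | unique participant identifier |
| `sex` | `"M"` or `"F"` |
| `age9`, `age10` | age at the 9-/10-year clinic (years) |
| `aphv9`, `aphv10` | age in years from peak height velocity at each clinic (negative = pre-PHV) |
| `social_class` | mother's social class: `I`, `II`, `III_nonmanual`, `III_manual`, `IV`, `V` |
| `family_history` | family history of hypertension/diabetes/high cholesterol/vascular disease (1 = yes) |
| `time_vasc_accel` | years between vascular and accelerometer measurements |
| `time_cvd_accel` | years between CVD-risk and accelerometer measurements |
| `body_mass` | total body mass (kg) |
| `lean_mass` | total body lean mass (kg) |
| `lean_mass_index` | lean mass / height² (kg·m⁻²) |
| `fat_mass_index` | fat mass / height² (kg·m⁻²) |
| `baseline_diameter` | baseline brachial artery diameter (mm) |
| `sbp9`, `dbp9` | systolic/diastolic blood pressure at 9 y (mmHg) |
| `map9` | mean arterial pressure (mmHg) — derived |
| `tag` | triglycerides (mmol·L⁻¹) |
| `chol_hdl` | total cholesterol : HDL ratio |
| `insulin` | insulin (mU·L⁻¹) |
| `pwc170` | physical work capacity at HR 170 (W) |
| `crf_scaled_lean` | PWC170 scaled to lean mass (W·kg⁻ᵇ); `crf_scaled_lean_fitted` is the pipeline's re-fitted version |
| `st_min`, `lpa_min`, `mvpa_min` | activity composition (min·day⁻¹, closed to 960) |
| `fmd` | flow-mediated dilation (%) |
| `dc` | distensibility coefficient (% per mmHg) |
| `pwv` | pulse wave velocity (m·s⁻¹) |
| `cvd_risk` | clustered cardiometabolic risk z-score; `cvd_risk_components` is the score recomputed from the five components |

## Epoch table (`simulate stream`, pipeline `days.csv` inputs)

| column | description |
|---|---|
| `participant_id` | participant identifier |
| `day` | 0-based day index |
| `epoch_index` | 0-based 60-s epoch index within the day |
| `counts` | accelerometer counts·min⁻¹ for the epoch |

## Day summaries (`days.csv`)

`wear_minutes`, `st_minutes`, `lpa_minutes`, `mvpa_minutes` (summing to
wear exactly) and the `valid` flag (wear ≥ 500 min).

## Person summaries (`person_summaries.csv`)

`included` flag, machine-readable exclusion `reason`
(`insufficient_valid_days` / `insufficient_mean_wear`), `n_valid_days`,
`mean_wear_minutes`, and mean daily `st_min`/`lpa_min`/`mvpa_min` over
valid days.

## Association tables (`association_*.csv`, pooled tables)

Keyed by (`outcome`, `stratum`, `part`); `label` is the reporting row
("ST: LPA & MVPA", ...); `beta_ilr1` with `se`, `ci_low`, `ci_high`,
`p_value`, `n`, `r_squared`, `significant`; pooled tables add `df` and
`m` (number of imputation replicates).

All pipeline CSVs start with a `# seed=... package=...` comment line;
read them with `pandas.read_csv(..., comment="#")` or
`coda_activity.pipeline.read_run_csv`.
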