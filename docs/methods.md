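# Methods

This note documents the models and procedures the package implements,
the choices made where the underlying study design left the details
open, and what the synthetic-data tests do and do not establish.

## The compositional model

Daily activity of a child splits a fixed waking budget (assumed 16 h =
960 min, i.e. 8 h of sleep) into sedentary time (ST), light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA).
Because the three parts are exhaustive and mutually exclusive, only
their relative sizes are informative: the data live on a 3-part simplex
and are analysed in Aitchison geometry.

The package uses pivot isometric log-ratio (ilr) coordinates.  For a
composition x ordered so the part of interest comes first,

    z1 = sqrt(2/3) * ln( x1 / sqrt(x2 * x3) )
    z2 = sqrt(1/2) * ln( x2 / x3 )

(natural logarithms; the general D-part form uses the sequential binary
partition with normalising constants sqrt((D-k)/(D-k+1))).  z1 carries
all information about the first part relative to the geometric mean of
the rest, so its regression coefficient ("beta_ilr1") is the quantity
reported for each behaviour.  Refitting under the three cyclic
rotations of (ST, LPA, MVPA) yields the three reported rows; the
rotations are orthogonal reparameterisations of one model, so fitted
values and R² agree across them and the three beta_ilr1 values sum to
zero exactly.  The part order is fixed as (ST, LPA, MVPA) and the
reported rotations keep the cyclic tail order ("ST: LPA & MVPA",
"LPA: MVPA & ST", "MVPA: ST & LPA").

The pivot basis is one of several orthonormal ilr bases; since the
emulated analysis does not print its normalising constants, the
standard sequential-binary-partition form above is assumed.  Basis
choice rescales individual coordinates but not fitted values or R²
(checked numerically in the tests); beta_ilr1 values are interpretable
only relative to this basis.

Zeros: a participant with zero minutes in a behaviour has no finite
log-ratio.  Non-positive parts are repaired by multiplicative
replacement — zeros become delta (default 1 min/day, the smallest
meaningful epoch aggregate) and the remaining parts shrink
proportionally so the total is preserved.  Closure constants are 960
min for minute-scale reporting and 100 for percentage reporting.

## Accelerometer processing

Input is a long table of 60-s epochs in counts·min⁻¹.  Per day:

* **Non-wear** is a maximal zero-count window of ≥ 60 min allowing up
  to 2 min of non-zero interruptions.  Windows must start and end on a
  zero epoch; scanning is greedy left-to-right (earliest feasible
  start, extended as far as the interruption budget allows), which
  makes intervals maximal and non-overlapping.  "Up to two min of
  interruptions" is ambiguous between a *total* cap (at most 2
  non-zero epochs anywhere in the window; the default, matching the
  common Troiano-family reading) and a *consecutive* cap (each
  interruption run at most 2 min, unlimited runs); both are
  implemented via `WearRules.interruption_mode`.  Intervals use
  0-based half-open `[start, end)` epoch indexing.
* **Cut-points** (youth calibration): ST < 100, MVPA ≥ 2296
  counts·min⁻¹, LPA in between.  The MVPA boundary is implemented as
  ≥ 2296 (the published calibration bins), with the exact value
  configurable; an epoch at exactly 100 counts is LPA.
* **Valid day**: ≥ 500 wear minutes.  A zero-wear day is simply
  invalid (no division by zero).  ST + LPA + MVPA equals wear minutes
  exactly on every day.
* **Inclusion**: ≥ 3 valid days and mean wear over valid days ≥ 600
  min·day⁻¹; no weekend-day constraint.  Excluded participants carry a
  machine-readable reason (`insufficient_valid_days` or
  `insufficient_mean_wear`), tallied in the exclusion report.

The tests compare the scanning detector against an independent oracle
that enumerates every valid window from prefix sums and then applies
the same greedy selection — the two formulations share only the window
definition, not the algorithm.

## Derived measures

* FMD (%) = 100 · (peak − baseline diameter) / baseline diameter.
* MAP = DBP + (SBP − DBP)/3.
* Distensibility coefficient = 100 · (ds² − dd²)/dd² / pulse pressure
  (% change in cross-sectional area per mmHg).  The verbal definition
  does not fix the reference area; the diastolic-area form is the
  default and a systolic-area variant is available.  The measurement
  CV of ~18% cannot arbitrate between the two.
* PWV = carotid-radial path length (m) / pulse transit time (s).
* Clustered CVD risk = mean of the sex-specific z-scores of the
  log-transformed fat mass index, MAP, triglycerides, total
  cholesterol:HDL ratio and insulin.  Natural logs are used (the base
  cancels in a z-score).  Standardisation uses the analysis sample
  supplied, sample SD (ddof = 1), so within-sex score means are zero
  by construction; external norms are not used.  The score is computed
  on whatever sample is passed (complete-case or one imputed
  replicate) — whether standardisation precedes or follows imputation
  is a user decision.
* Allometric CRF scaling: ln(PWC170) = a + b·ln(mass) + c·female,
  fitted by OLS on the pooled sample with sex as a covariate (per the
  stated model; not per-sex), scaled value = PWC170 / mass^b.
  Validation correlates the scaled values against the size variable
  (group and by sex); a stratum passes when |r| < 0.1 or p > 0.05.

## Regression models

OLS throughout, one fit per (outcome, stratum, pivot rotation).
Covariates: clinic age, years from peak height velocity, mother's
social class, clinic-to-accelerometer time gap, lean-mass-scaled CRF,
lean mass index, family history of disease, plus clustered CVD risk
(except when it is the outcome), baseline vessel diameter (FMD only)
and sex (whole-group models only).  Models with clustered CVD risk as
outcome use the 9-year clinic age/maturity/time-gap variables; the
vascular outcomes use the 10-year ones.

Coding decisions: sex as a 0/1 female indicator; social class as
categorical indicators with class I as reference (the printed six
categories, III split into non-manual/manual; an ordinal 1–6 coding is
available); family history as 0/1; continuous covariates untransformed.
Confidence intervals use Student-t quantiles.  Classical covariance is
the default with HC3 robust covariance available.  No multiple-testing
adjustment (alpha = 0.05 per test, as in the emulated analysis).
Constant covariate columns within a stratum (e.g. sex in a stratified
fit, or a social class level absent from a small stratum) are dropped
with a warning; genuine rank deficiency (e.g. identical compositions)
raises an error naming the offending columns.

The sex-interaction screen augments the whole-group model with
female·z1 and female·z2 and reports each term plus their joint F-test.

Years-from-PHV convention: the generator emits the difference (age
minus age at peak height velocity, negative before PHV, as the source
cohort tabulates it); the regression consumes whichever maturity column
is supplied, so either convention can be used.

Multiply-imputed data are fitted one replicate at a time and combined
with Rubin's rules: Q̄ = mean estimate, W = mean within-imputation
variance, B = between-imputation variance (ddof = 1), total
T = W + (1 + 1/m)B, df = (m−1)(1 + W/((1+1/m)B))², reducing to the
single-model result with infinite df when the replicates agree.
Relative efficiency of m imputations is (1 + γ/m)⁻¹ with γ the
fraction of missing information, approximated by the observed
missingness proportion.  The chained-equations imputer itself is out
of scope; a seeded noisy-regression imputer exists only as a test
fixture.

## Synthetic data: what it emulates and what it does not

The generator emulates the structure of a large UK birth-cohort
subsample (~4,300 children, ~52% girls, aged ~10.6 y): sex-specific
3-part logistic-normal activity compositions; covariates drawn at the
cohort's printed means/SDs and category frequencies (log-normals,
moment-matched, for skewed positive quantities — fat mass index,
triglycerides, cholesterol ratio, insulin); outcomes linear in the ilr
coordinates with Gaussian noise.  Defaults that define the study
conditions:

* ilr locations per sex = exact ilr images of the published
  sex-specific geometric means (boys 426.9/455.9/77.2, girls
  448.2/457.3/54.4 min/day).
* ilr covariance = diag(0.12, 0.14) for both sexes, moment-matched to
  the printed arithmetic means and SDs of daily minutes assuming
  independent log-parts.  The source reports no compositional
  covariance, so the off-diagonal defaults to zero.
* Outcome coefficients: vascular outcomes have no compositional effect
  (the study's finding); clustered CVD risk uses the published
  first-pivot triple (ST +0.136, LPA −0.010, MVPA −0.126), converted
  exactly to a canonical-basis coefficient pair.  Intercepts and
  residual SDs track the printed outcome means/SDs.
* Clinic time gaps are Normal(1.1, 0.3) and Normal(1.9, 0.3) years, as
  tabulated; constants may be supplied but are dropped from designs as
  collinear with the intercept.
* PWC170 is generated from the power law
  scaled · lean_mass^0.59 with log-normal scatter, so the allometric
  fit has a recoverable exponent.

Epoch streams are built from planted per-day behaviour minutes:
labels shuffled uniformly within the day, counts uniform within each
cut-point band (the analysis uses band membership only, so the
within-band law is irrelevant), sedentary counts ≥ 1 by default so
that planted non-wear blocks (pure zero runs ≥ 60 min) are the only
zero runs and the planted truth is exact.  Day-to-day target variance
is exposed (`day_target_sd`) but defaults to 0; no value is reported
for the emulated cohort.  Missingness is limited to MCAR masking in
the pooling tests.

Limitations of the emulation: no within-person day structure (diurnal
patterns, bouts), no device artefacts or calibration error, no
non-waking time, no real covariate correlation structure (covariates
are drawn independently apart from sex), no informative missingness.
Passing tests therefore establish the correctness of the arithmetic,
the processing rules, the estimators and their frequentist calibration
under the stated generating model — not robustness to the messiness of
real accelerometer or clinic data.

## Numerical choices and problem sizes

Closure tolerance 1e-9 relative; ilr round-trips are tested to 1e-9
and the zero-sum/rotation invariances to 1e-10.  Positive-definiteness
of ilr covariances is checked by Cholesky.  Random draws use numpy's
PCG64 `default_rng`; every public generator takes an explicit seed and
identical seeds give byte-identical tables.

Simulation-based checks run at: n = 4277 × 200 replicates for
coefficient recovery and CI coverage (coverage ≥ 93%, |mean bias| <
0.01); n = 150 × 1000 replicates for type-I-error calibration (0.05 ±
0.02); 500 random streams for the non-wear oracle; n = 20,000 for
geometric-mean reproduction, with a delta-method Monte-Carlo tolerance
(3.5 propagated SEs + printed rounding).  These sizes were chosen to
make the Monte-Carlo bands decisively tighter than the assertions they
feed while keeping the default suite fast.
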