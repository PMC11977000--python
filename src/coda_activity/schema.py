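"""Shared column naming and coding conventions for cohort tables.

One row per participant.  Activity parts are always ordered
(sedentary time, light PA, moderate-to-vigorous PA); the regression
layer relies on this canonical order when building pivot coordinates.
"""

from __future__ import annotations

#: canonical activity-behaviour part labels, in fixed order
PARTS: tuple[str, ...] = ("st", "lpa", "mvpa")

#: cohort-table column holding each part, in minutes per day
PART_COLUMNS: dict[str, str] = {"st": "st_min", "lpa": "lpa_min", "mvpa": "mvpa_min"}

#: outcome columns the regression layer knows about
OUTCOMES: tuple[str, ...] = ("fmd", "dc", "pwv", "cvd_risk")

#: registrar-general social class categories (III split into non-manual/manual)
SOCIAL_CLASS_LEVELS: tuple[str, ...] = (
    "I", "II", "III_nonmanual", "III_manual", "IV", "V",
)

#: sex codes used throughout ("F" = female)
SEX_LEVELS: tuple[str, str] = ("M", "F")

#: human-readable description of every cohort column the package reads or writes
DATA_DICTIONARY: dict[str, str] = {
    "participant_id": "unique participant identifier",
    "sex": 'participant sex, "M" or "F"',
    "age9": "age at the 9-year clinic (years)",
    "age10": "age at the 10-year clinic (years)",
    "aphv9": "age in years from peak height velocity at the 9-year clinic "
             "(negative = pre-PHV)",
    "aphv10": "age in years from peak height velocity at the 10-year clinic",
    "social_class": "mother's social class, one of " + "/".join(SOCIAL_CLASS_LEVELS),
    "family_history": "family history of hypertension/diabetes/high cholesterol/"
                      "vascular disease (1 = yes)",
    "time_vasc_accel": "years between vascular and accelerometer measurements",
    "time_cvd_accel": "years between CVD-risk and accelerometer measurements",
    "body_mass": "total body mass (kg)",
    "lean_mass": "total body lean mass (kg)",
    "lean_mass_index": "lean mass / height^2 (kg m^-2)",
    "fat_mass_index": "fat mass / height^2 (kg m^-2)",
    "baseline_diameter": "baseline brachial artery diameter (mm)",
    "sbp9": "systolic blood pressure at 9 years (mmHg)",
    "dbp9": "diastolic blood pressure at 9 years (mmHg)",
    "map9": "mean arterial pressure at 9 years (mmHg), derived",
    "tag": "plasma triglycerides (mmol L^-1)",
    "chol_hdl": "total cholesterol : HDL ratio (dimensionless)",
    "insulin": "plasma insulin (mU L^-1)",
    "pwc170": "physical work capacity at heart rate 170 (W)",
    "crf_scaled_lean": "PWC170 allometrically scaled to lean mass (W kg^-b)",
    "st_min": "sedentary time (min day^-1, closed composition)",
    "lpa_min": "light physical activity (min day^-1, closed composition)",
    "mvpa_min": "moderate-to-vigorous physical activity (min day^-1, closed)",
    "fmd": "flow-mediated dilation of the brachial artery (%)",
    "dc": "brachial distensibility coefficient (% per mmHg)",
    "pwv": "carotid-radial pulse wave velocity (m s^-1)",
    "cvd_risk": "clustered cardiometabolic risk z-score (dimensionless)",
}
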