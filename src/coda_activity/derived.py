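"""Derived cardiovascular and fitness measures.

Closed-form vascular indices (flow-mediated dilation, mean arterial
pressure, distensibility coefficient, pulse wave velocity), the
clustered cardiometabolic risk z-score, and allometric scaling of
cardiorespiratory fitness with its validation-by-correlation check.

All closed forms accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "fmd_percent",
    "mean_arterial_pressure",
    "distensibility_coefficient",
    "pulse_wave_velocity",
    "clustered_cvd_risk",
    "RISK_COMPONENTS",
    "ScalingFit",
    "allometric_fit",
    "validate_scaling",
]

#: the five components of the clustered risk score
RISK_COMPONENTS: tuple[str, ...] = (
    "fat_mass_index", "map9", "tag", "chol_hdl", "insulin",
)


def fmd_percent(baseline_diameter, peak_diameter):
    """Flow-mediated dilation: percent diameter increase from baseline.

    ``100 * (peak - baseline) / baseline``, diameters in mm.  Negative
    values (constriction) are allowed.
    """
    baseline = np.asarray(baseline_diameter, dtype=float)
    peak = np.asarray(peak_diameter, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline diameter must be positive")
    out = 100.0 * (peak - baseline) / baseline
    return float(out) if out.ndim == 0 else out


def mean_arterial_pressure(sbp, dbp):
    """MAP = DBP + (SBP - DBP)/3, all in mmHg."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp < dbp):
        raise ValueError("systolic pressure must be >= diastolic pressure")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def distensibility_coefficient(
    diastolic_diameter, systolic_diameter, pulse_pressure, reference: str = "diastole"
):
    """Arterial distensibility: % cross-sectional area change per mmHg.

    ``100 * (ds^2 - dd^2) / dd^2 / PP`` with the diastolic area as the
    reference (``reference="systole"`` divides by the systolic area
    instead; the verbal definition does not pin the denominator down).
    """
    dd = np.asarray(diastolic_diameter, dtype=float)
    ds = np.asarray(systolic_diameter, dtype=float)
    pp = np.asarray(pulse_pressure, dtype=float)
    if np.any(dd <= 0) or np.any(ds < dd):
        raise ValueError("need systolic diameter >= diastolic diameter > 0")
    if np.any(pp <= 0):
        raise ValueError("pulse pressure must be positive")
    if reference == "diastole":
        ref = dd ** 2
    elif reference == "systole":
        ref = ds ** 2
    else:
        raise ValueError("reference must be 'diastole' or 'systole'")
    out = 100.0 * (ds ** 2 - dd ** 2) / ref / pp
    return float(out) if out.ndim == 0 else out


def pulse_wave_velocity(path_length, transit_time):
    """Carotid-radial PWV: arterial path length (m) / transit time (s)."""
    length = np.asarray(path_length, dtype=float)
    time = np.asarray(transit_time, dtype=float)
    if np.any(length <= 0) or np.any(time <= 0):
        raise ValueError("path length and transit time must be positive")
    out = length / time
    return float(out) if out.ndim == 0 else out


def clustered_cvd_risk(
    rows: pd.DataFrame,
    components: tuple[str, ...] = RISK_COMPONENTS,
    sex_col: str = "sex",
) -> pd.Series:
    """Clustered cardiometabolic risk: mean of sex-specific z-scores.

    Each component (fat mass index, MAP, triglycerides, total
    cholesterol:HDL ratio, insulin) is log-transformed (skewed,
    strictly positive), z-scored within sex on the supplied analysis
    sample, and the five z-scores are averaged.  Within each sex the
    resulting scores have mean zero by construction.
    """
    missing = [c for c in (*components, sex_col) if c not in rows.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    comp = rows.loc[:, list(components)].astype(float)
    if (comp <= 0).any().any():
        raise ValueError("risk components must be positive (log-transformable)")
    counts = rows.groupby(sex_col).size()
    if (counts < 2).any():
        raise ValueError("need at least 2 participants per sex stratum")
    logs = np.log(comp)

    def _z(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero within-sex SD for component {col.name!r}")
        return (col - col.mean()) / sd

    z = logs.groupby(rows[sex_col]).transform(_z)
    return z.mean(axis=1).rename("cvd_risk")


@dataclass
class ScalingFit:
    """Allometric scaling fit ln(PWC170) = a + b ln(mass) + c female."""

    exponent_b: float
    intercept: float
    sex_coef: float
    exponent_se: float
    scaled_values: np.ndarray

    def scale(self, pwc, mass) -> np.ndarray:
        return np.asarray(pwc, dtype=float) / np.asarray(mass, dtype=float) ** self.exponent_b


def allometric_fit(pwc, mass, sex) -> ScalingFit:
    """Fit the log-linear allometric model and scale fitness by mass^b.

    ``sex`` is any two-level coding ("M"/"F" accepted); the exponent is
    fitted on the pooled sample with sex as a covariate, and scaled
    values are ``pwc / mass**b``.
    """
    pwc = np.asarray(pwc, dtype=float)
    mass = np.asarray(mass, dtype=float)
    sex = np.asarray(sex)
    if pwc.size < 10:
        raise ValueError("need at least 10 observations")
    if np.any(pwc <= 0) or np.any(mass <= 0):
        raise ValueError("pwc and mass must be positive")
    if np.ptp(np.log(mass)) == 0:
        raise ValueError("degenerate design: mass is constant")
    female = (sex == "F").astype(float) if sex.dtype.kind in "OUS" else sex.astype(float)
    x = np.column_stack([np.ones_like(pwc), np.log(mass), female])
    res = sm.OLS(np.log(pwc), x).fit()
    b = float(res.params[1])
    return ScalingFit(
        exponent_b=b,
        intercept=float(res.params[0]),
        sex_coef=float(res.params[2]),
        exponent_se=float(res.bse[1]),
        scaled_values=pwc / mass ** b,
    )


def validate_scaling(
    scaled, mass, sex=None, r_threshold: float = 0.1
) -> dict:
    """Check that scaled fitness no longer correlates with body size.

    Pearson r of scaled CRF against mass, at group level and within
    each sex when ``sex`` is given.  A stratum passes when |r| is below
    ``r_threshold`` or its p-value exceeds 0.05.
    """
    scaled = np.asarray(scaled, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if scaled.size != mass.size or scaled.size < 3:
        raise ValueError("need equal-length inputs with at least 3 observations")

    def _one(s, m):
        if np.ptp(s) == 0 or np.ptp(m) == 0:
            raise ValueError("zero variance: correlation undefined")
        r, p = stats.pearsonr(s, m)
        return {"r": float(r), "p": float(p), "passed": abs(r) < r_threshold or p > 0.05}

    out = {"group": _one(scaled, mass)}
    if sex is not None:
        sex = np.asarray(sex)
        for label, code in (("boys", "M"), ("girls", "F")):
            mask = sex == code
            if mask.sum() >= 3:
                out[label] = _one(scaled[mask], mass[mask])
    out["passed"] = all(v["passed"] for v in out.values() if isinstance(v, dict))
    return out
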