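"""Covariate-adjusted linear models with ilr pivot coordinates as exposure.

For each outcome the activity composition enters an ordinary
least-squares model through a pair of pivot ilr coordinates.  Refitting
under each of the three pivot rotations reads off, in turn, the
coefficient of one behaviour relative to the geometric mean of the
other two (``beta_ilr1``).  The rotations are orthogonal
reparameterisations of the same column space, so fitted values and R^2
are identical across them and the three ``beta_ilr1`` values sum to
zero exactly.

Covariate sets follow the emulated study design: age, somatic maturity
(years from peak height velocity), mother's social class, the clinic
time gap, lean-mass-scaled cardiorespiratory fitness, lean mass index,
family history, clustered CVD risk (except when it is the outcome),
baseline vessel diameter (FMD only) and sex (whole-group models only).
Clinic ages/gaps switch to the 9-year visit when clustered CVD risk is
the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import coda
from .schema import OUTCOMES, PART_COLUMNS, PARTS, SOCIAL_CLASS_LEVELS

__all__ = [
    "ModelSpec",
    "covariates_for",
    "build_design",
    "fit_linear_model",
    "residual_diagnostics",
    "association_table",
    "interaction_model",
    "ROW_LABELS",
]

#: association-table row labels, one per pivot rotation
ROW_LABELS: dict[str, str] = {
    "st": "ST: LPA & MVPA",
    "lpa": "LPA: MVPA & ST",
    "mvpa": "MVPA: ST & LPA",
}

STRATA = ("group", "boys", "girls")
_SEX_OF_STRATUM = {"boys": "M", "girls": "F"}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, stratum, adjustment and coding switches."""

    outcome: str
    stratum: str = "group"
    adjusted: bool = True
    robust_se: bool = False
    social_class_coding: str = "categorical"  # or "ordinal"
    zero_delta: float = 1.0
    parts: tuple[str, ...] = PARTS

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        if self.social_class_coding not in ("categorical", "ordinal"):
            raise ValueError("social_class_coding must be 'categorical' or 'ordinal'")


def covariates_for(outcome: str, stratum: str = "group", adjusted: bool = True) -> list[str]:
    """Covariate column list for an (outcome, stratum) model."""
    if not adjusted:
        return []
    if outcome == "cvd_risk":
        cov = ["age9", "aphv9", "time_cvd_accel"]
    else:
        cov = ["age10", "aphv10", "time_vasc_accel"]
    cov += ["social_class", "crf_scaled_lean", "lean_mass_index", "family_history"]
    if outcome != "cvd_risk":
        cov.append("cvd_risk")
    if outcome == "fmd":
        cov.append("baseline_diameter")
    if stratum == "group":
        cov.append("sex")
    return cov


def _code_covariates(df: pd.DataFrame, covariates: list[str], coding: str) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "sex":
            female = (df["sex"] == "F").astype(float)
            if female.nunique() < 2:
                warnings.warn(
                    "sex is constant in this stratum; dropping the sex indicator",
                    stacklevel=3,
                )
                continue
            cols["female"] = female.to_numpy()
        elif cov == "social_class":
            if coding == "ordinal":
                mapping = {lev: i + 1 for i, lev in enumerate(SOCIAL_CLASS_LEVELS)}
                cols["social_class_ord"] = df["social_class"].map(mapping).to_numpy(float)
            else:
                cat = pd.Categorical(df["social_class"], categories=SOCIAL_CLASS_LEVELS)
                if cat.isna().any():
                    bad = sorted(set(df["social_class"]) - set(SOCIAL_CLASS_LEVELS))
                    raise ValueError(f"unknown social class levels: {bad}")
                dummies = pd.get_dummies(cat, prefix="social", drop_first=True)
                for name in dummies.columns:
                    col = dummies[name].to_numpy(float)
                    if col.std() == 0:
                        continue  # level absent in this stratum
                    cols[name] = col
        else:
            col = df[cov].to_numpy(float)
            if np.ptp(col) == 0:
                warnings.warn(
                    f"covariate {cov!r} is constant in this stratum; dropped",
                    stacklevel=3,
                )
                continue
            cols[cov] = col
    return pd.DataFrame(cols, index=df.index)


def build_design(
    cohort: pd.DataFrame, spec: ModelSpec, pivot: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (const, z1, z2, covariates) and response for one fit.

    ``pivot`` is a rotation of the part labels; the first label is the
    behaviour of interest whose coefficient on ``z1`` is reported.
    Rows with missing values in any used column are dropped (complete
    cases; multiply-imputed replicates are fitted one at a time and
    pooled downstream).  Non-positive compositions are routed through
    multiplicative zero replacement with a warning.
    """
    if pivot is None:
        pivot = spec.parts
    if sorted(pivot) != sorted(spec.parts):
        raise ValueError(f"pivot {pivot} must permute {spec.parts}")
    covariates = covariates_for(spec.outcome, spec.stratum, spec.adjusted)
    part_cols = [PART_COLUMNS[p] for p in spec.parts]
    needed = [spec.outcome, *part_cols]
    needed += [c for c in covariates if c != "sex"]
    if spec.stratum != "group" or "sex" in covariates:
        needed.append("sex")
    missing = [c for c in dict.fromkeys(needed) if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")

    df = cohort
    if spec.stratum != "group":
        df = df[df["sex"] == _SEX_OF_STRATUM[spec.stratum]]
    df = df.dropna(subset=list(dict.fromkeys(needed)))
    if df.empty:
        raise ValueError(f"no complete cases for {spec.outcome} in stratum {spec.stratum}")

    comp = df[part_cols].to_numpy(float)
    if np.any(comp <= 0):
        warnings.warn(
            "non-positive composition parts found; applying multiplicative "
            f"zero replacement (delta={spec.zero_delta})",
            stacklevel=2,
        )
        comp = coda.zero_replace(comp, delta=spec.zero_delta)
    perm = tuple(spec.parts.index(p) for p in pivot)
    z = coda.ilr_pivot(comp, perm)

    x = pd.DataFrame(
        {"const": 1.0, "z1": z[:, 0], "z2": z[:, 1]}, index=df.index
    )
    x = pd.concat([x, _code_covariates(df, covariates, spec.social_class_coding)], axis=1)
    return x, df[spec.outcome].astype(float)


def fit_linear_model(
    design: pd.DataFrame, response: pd.Series, robust_se: bool = False
):
    """OLS fit with t-based 95% CIs; raises on rank deficiency.

    ``robust_se=True`` switches to HC3 heteroskedasticity-robust
    covariance; the classical estimator is the default.
    """
    xv = design.to_numpy(float)
    n, p = xv.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(xv)
    if rank < p:
        # name columns whose removal restores full rank
        offending = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(xv, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; offending columns: {offending}")
    model = sm.OLS(response.to_numpy(float), design)
    return model.fit(cov_type="HC3" if robust_se else "nonrobust")


def residual_diagnostics(results) -> dict:
    """Normality / homoscedasticity summaries for a fitted model."""
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.stattools import jarque_bera

    jb, jb_p, skew, kurt = jarque_bera(results.resid)
    lm, lm_p, _, _ = het_breuschpagan(results.resid, results.model.exog)
    return {
        "jarque_bera": float(jb),
        "jarque_bera_p": float(jb_p),
        "skew": float(skew),
        "kurtosis": float(kurt),
        "breusch_pagan": float(lm),
        "breusch_pagan_p": float(lm_p),
        "condition_number": float(np.linalg.cond(results.model.exog)),
    }


def association_table(
    cohort: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOMES,
    strata: tuple[str, ...] = STRATA,
    adjusted: bool = True,
    robust_se: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The full association surface: beta_ilr1 per outcome/stratum/behaviour.

    One OLS fit per pivot rotation per stratum; ``beta_ilr1`` is the z1
    coefficient with its t-based 95% CI and two-sided p-value.  Strata
    that cannot be fitted (e.g. empty) yield rows with NaN estimates.
    """
    rows = []
    for outcome in outcomes:
        for stratum in strata:
            spec = ModelSpec(
                outcome=outcome, stratum=stratum, adjusted=adjusted, robust_se=robust_se
            )
            for pivot in coda.pivot_rotations(spec.parts):
                row = {
                    "outcome": outcome,
                    "stratum": stratum,
                    "part": pivot[0],
                    "label": ROW_LABELS.get(pivot[0], pivot[0]),
                }
                try:
                    x, y = build_design(cohort, spec, pivot)
                    res = fit_linear_model(x, y, robust_se)
                    ci = res.conf_int(alpha=alpha)
                    row.update(
                        beta_ilr1=float(res.params["z1"]),
                        se=float(res.bse["z1"]),
                        ci_low=float(ci.loc["z1", 0]),
                        ci_high=float(ci.loc["z1", 1]),
                        p_value=float(res.pvalues["z1"]),
                        n=int(res.nobs),
                        r_squared=float(res.rsquared),
                    )
                    row["significant"] = row["p_value"] < alpha
                except ValueError as err:
                    row.update(
                        beta_ilr1=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                        p_value=np.nan, n=0, r_squared=np.nan, significant=False,
                        error=str(err),
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def interaction_model(
    cohort: pd.DataFrame,
    outcome: str,
    adjusted: bool = True,
    pivot: tuple[str, ...] | None = None,
) -> dict:
    """Whole-group model plus sex-by-composition interaction terms.

    Adds ``female * z1`` and ``female * z2`` and reports each term with
    a joint F-test of both, the screen used to decide whether the sex
    strata may be pooled.
    """
    spec = ModelSpec(outcome=outcome, stratum="group", adjusted=adjusted)
    x, y = build_design(cohort, spec, pivot)
    sexes = cohort.loc[x.index, "sex"] if "sex" in cohort.columns else None
    if sexes is None or sexes.nunique() < 2:
        raise ValueError("interaction model requires both sexes in the data")
    if "female" not in x.columns:  # unadjusted models carry no sex main effect
        x = x.assign(female=(sexes == "F").astype(float))
    x = x.assign(female_z1=x["female"] * x["z1"], female_z2=x["female"] * x["z2"])
    res = fit_linear_model(x, y, spec.robust_se)
    ftest = res.f_test(["female_z1 = 0", "female_z2 = 0"])
    ci = res.conf_int()
    out = {"outcome": outcome, "n": int(res.nobs)}
    for term in ("female_z1", "female_z2"):
        out[term] = {
            "coef": float(res.params[term]),
            "se": float(res.bse[term]),
            "ci": (float(ci.loc[term, 0]), float(ci.loc[term, 1])),
            "p": float(res.pvalues[term]),
        }
    out["joint_F"] = float(np.squeeze(ftest.fvalue))
    out["joint_p"] = float(np.squeeze(ftest.pvalue))
    return out
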