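"""Rubin's rules for multiply-imputed analyses.

The chained-equations imputer itself is out of scope: this module pools
coefficient estimates produced on any stack of imputed replicates, and
computes the relative efficiency (1 + gamma/m)^-1 of finite-m pooling,
where gamma is the fraction of missing information (approximated, as in
the emulated study, by the observed missingness proportion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PooledEstimate", "rubin_pool", "relative_efficiency", "pool_association_tables"]


@dataclass
class PooledEstimate:
    """Pooled coefficients with Rubin total variance and approximate df."""

    estimate: np.ndarray      # Q-bar, mean over replicates
    within: np.ndarray        # W, mean within-imputation variance
    between: np.ndarray       # B, between-imputation variance (ddof=1)
    total: np.ndarray         # T = W + (1 + 1/m) B
    se: np.ndarray
    df: np.ndarray            # Rubin small-m approximation; inf when B = 0
    ci_low: np.ndarray
    ci_high: np.ndarray
    m: int


def rubin_pool(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Pool per-replicate estimates and squared SEs across m imputations.

    ``estimates`` and ``variances`` are (m, k) arrays (or length-m
    vectors for a single coefficient).  Total variance is
    ``T = W + (1 + 1/m) B`` and the degrees of freedom follow the
    standard approximation ``(m - 1) (1 + W / ((1 + 1/m) B))^2``; when
    the replicates agree exactly (B = 0) the pooled result reduces to
    the common single-model result with infinite df.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    if np.asarray(estimates).ndim == 1:
        est = est.T
        var = var.T
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have matching shapes")
    m = est.shape[0]
    if m < 2:
        raise ValueError("pooling requires at least 2 replicates")
    if np.any(var < 0):
        raise ValueError("variances must be non-negative")
    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    if np.any((b == 0) & (w == 0)):
        raise ValueError("degenerate pooling: zero within- and between-variance")
    t_var = w + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore"):
        df = np.where(
            b > 0,
            (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * np.where(b > 0, b, 1.0))) ** 2,
            np.inf,
        )
    se = np.sqrt(t_var)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return PooledEstimate(
        estimate=qbar,
        within=w,
        between=b,
        total=t_var,
        se=se,
        df=df,
        ci_low=qbar - tcrit * se,
        ci_high=qbar + tcrit * se,
        m=m,
    )


def relative_efficiency(gamma: float, m: int) -> float:
    """Efficiency of m-imputation pooling relative to m = infinity.

    ``(1 + gamma/m)^-1`` with ``gamma`` the fraction of missing
    information; increasing in m and decreasing in gamma.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 / (1.0 + gamma / m)


def pool_association_tables(tables: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Rubin-pool per-replicate association tables into one table.

    Each input is an :func:`~coda_activity.regression.association_table`
    computed on one imputed replicate; rows are matched on
    (outcome, stratum, part) and the pooled table keeps the same schema
    with Rubin total-variance CIs and p-values.
    """
    if len(tables) < 2:
        raise ValueError("pooling requires at least 2 replicate tables")
    keys = ["outcome", "stratum", "part"]
    ref = tables[0][keys]
    for t in tables[1:]:
        if not ref.equals(t[keys].reset_index(drop=True)):
            raise ValueError("replicate tables must have identical row keys in order")
    est = np.stack([t["beta_ilr1"].to_numpy(float) for t in tables])
    var = np.stack([t["se"].to_numpy(float) ** 2 for t in tables])
    pooled = rubin_pool(est, var, alpha=alpha)
    out = tables[0][keys + ["label"]].copy()
    out["beta_ilr1"] = pooled.estimate
    out["se"] = pooled.se
    out["ci_low"] = pooled.ci_low
    out["ci_high"] = pooled.ci_high
    out["df"] = pooled.df
    tstat = pooled.estimate / pooled.se
    out["p_value"] = 2.0 * stats.t.sf(np.abs(tstat), pooled.df)
    out["significant"] = out["p_value"] < alpha
    out["m"] = pooled.m
    out["n"] = tables[0]["n"].to_numpy()
    return out
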