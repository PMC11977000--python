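"""Synthetic cohort and accelerometer-stream generation with known truth.

Real data of this kind (a UK birth cohort of ~4,300 ten-year-olds with
vascular phenotyping and week-long hip accelerometry) sit behind managed
access, so every downstream stage here is exercised on simulated inputs
whose generating parameters are returned alongside the data.

Activity compositions are simulated as logistic-normal: a bivariate
normal draw in pivot-ilr space, mapped back to the simplex and closed to
a 960-min waking day.  Sex-specific ilr locations default to the
published compositional geometric means of the cohort this package
emulates; covariates default to that cohort's printed means/SDs and
category frequencies.  Outcomes are linear in the ilr coordinates plus
Gaussian noise, with user-settable coefficients; the default clustered
cardiometabolic-risk coefficients reproduce the published first-pivot
triple (ST +0.136, LPA -0.010, MVPA -0.126).

Epoch streams are built the other way round: per-day behaviour minutes
are fixed first, epochs are labelled and shuffled, and counts are drawn
uniformly within each cut-point band, so the accelerometry module can be
checked against exact planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import coda
from .schema import PART_COLUMNS, PARTS, SOCIAL_CLASS_LEVELS

__all__ = [
    "CohortSpec",
    "StreamSpec",
    "generate_cohort",
    "generate_epoch_stream",
    "streams_for_cohort",
    "truth_frame",
    "TABLE_GEOMETRIC_MEANS",
]

#: published sex-specific geometric means of (ST, LPA, MVPA), min day^-1
TABLE_GEOMETRIC_MEANS: dict[str, tuple[float, float, float]] = {
    "group": (438.4, 457.2, 64.5),
    "M": (426.9, 455.9, 77.2),
    "F": (448.2, 457.3, 54.4),
}

#: printed social-class category frequencies (I..V, III split), proportions
SOCIAL_CLASS_PROBS: tuple[float, ...] = (0.055, 0.361, 0.389, 0.015, 0.147, 0.033)


def _default_ilr_mean_by_sex() -> dict[str, np.ndarray]:
    return {
        sex: coda.ilr_pivot(np.asarray(TABLE_GEOMETRIC_MEANS[sex]))
        for sex in ("M", "F")
    }


def _default_ilr_cov_by_sex() -> dict[str, np.ndarray]:
    # Moment-matched to the printed arithmetic means/SDs of daily minutes
    # (CV ~0.20 ST, ~0.16 LPA, ~0.51 MVPA), assuming independent log parts.
    cov = np.array([[0.12, 0.0], [0.0, 0.14]])
    return {"M": cov.copy(), "F": cov.copy()}


def default_covariate_params() -> dict:
    """Distribution parameters for covariates and risk components.

    Values are the printed cohort means/SDs (sex-specific where the
    source table stratifies).  Skewed positive quantities use
    moment-matched log-normals.  Clinic time gaps are constants.
    """
    return {
        "age9": {"mean": 9.8, "sd": 0.3},
        "age10": {"mean": 10.6, "sd": 0.2},
        "aphv9": {"M": (-3.8, 0.9), "F": (-2.0, 0.9)},
        "aphv10": {"M": (-3.0, 0.9), "F": (-1.2, 0.9)},
        "body_mass": {"M": (34.0, 6.7), "F": (34.5, 7.4)},
        "lean_mass": {"M": (25.39, 2.88), "F": (23.49, 3.15)},
        "lean_mass_index": {"M": (12.97, 0.84), "F": (12.12, 0.90)},
        "fat_mass_index": {"M": (3.61, 2.15), "F": (4.79, 2.28), "lognormal": True},
        "baseline_diameter": {"M": (2.75, 0.29), "F": (2.58, 0.29)},
        "sbp9": {"mean": 102.0, "sd": 9.0},
        "dbp9": {"mean": 57.0, "sd": 6.0},
        "tag": {"mean": 1.12, "sd": 0.52, "lognormal": True},
        "chol_hdl": {"mean": 3.17, "sd": 0.79, "lognormal": True},
        # insulin printed as median (IQR): log-normal with matching quantiles
        "insulin": {"mu_log": 2.083, "sd_log": 0.903},
        # CRF scaled to lean mass ~10.0 +/- 1.3 W kg^-0.59; PWC170 is rebuilt
        # from the power law so the allometric fit has a recoverable exponent
        "crf_scaled_geomean": {"M": 10.3, "F": 9.8},
        "crf_scaled_sd_log": 0.12,
        "allometric_exponent": 0.59,
        "family_history_p": 0.302,
        "time_vasc_accel": {"mean": 1.1, "sd": 0.3},
        "time_cvd_accel": {"mean": 1.9, "sd": 0.3},
        "social_class_probs": SOCIAL_CLASS_PROBS,
    }


def default_outcome_betas() -> dict:
    """Per-outcome intercepts, ilr coefficients and residual SDs.

    ``beta`` is on canonical-order pivot coordinates (ST first).  The
    vascular outcomes default to no compositional effect (the published
    finding); clustered CVD risk defaults to the published first-pivot
    coefficient triple.  Intercepts and residual SDs track the printed
    outcome means/SDs.
    """
    cvd_beta = coda.canonical_betas_from_first_pivots(
        {"st": 0.136, "lpa": -0.010, "mvpa": -0.126}
    )
    return {
        "fmd": {"intercept": 8.13, "beta": (0.0, 0.0), "noise_sd": 3.39},
        "dc": {"intercept": 0.12, "beta": (0.0, 0.0), "noise_sd": 0.06},
        "pwv": {"intercept": 7.56, "beta": (0.0, 0.0), "noise_sd": 1.23},
        "cvd_risk": {
            "intercept": 0.0,
            "beta": tuple(float(b) for b in cvd_beta),
            "noise_sd": 0.61,
        },
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort draw.

    ``outcome_betas`` entries may additionally carry
    ``beta_female_delta`` (added to ``beta`` for girls, for interaction
    studies) and ``covariate_effects`` (a mapping of numeric cohort
    columns to linear coefficients).
    """

    n_participants: int = 1000
    sex_ratio_female: float = 2226 / 4277
    ilr_mean_by_sex: Mapping[str, np.ndarray] = field(
        default_factory=_default_ilr_mean_by_sex
    )
    ilr_cov_by_sex: Mapping[str, np.ndarray] = field(
        default_factory=_default_ilr_cov_by_sex
    )
    covariate_params: dict = field(default_factory=default_covariate_params)
    outcome_betas: dict = field(default_factory=default_outcome_betas)
    kappa: float = coda.WAKING_DAY_MINUTES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female must lie in [0, 1]")
        for sex in ("M", "F"):
            cov = np.asarray(self.ilr_cov_by_sex[sex], dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError(f"ilr covariance for sex {sex!r} must be symmetric 2x2")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"ilr covariance for sex {sex!r} is not positive definite: {cov}"
                ) from err


def _lognormal_from_moments(rng, mean, sd, size):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(size))


def _by_sex_normal(rng, female, params):
    """Draw a normal with sex-specific (mean, sd) using one shared N(0,1) draw."""
    n = female.size
    z = rng.standard_normal(n)
    mean_m, sd_m = params["M"]
    mean_f, sd_f = params["F"]
    mean = np.where(female, mean_f, mean_m)
    sd = np.where(female, sd_f, sd_m)
    return mean + sd * z


def _by_sex_lognormal(rng, female, params):
    n = female.size
    z = rng.standard_normal(n)
    out = np.empty(n)
    for sex, mask in (("M", ~female), ("F", female)):
        mean, sd = params[sex]
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        out[mask] = np.exp(mu + np.sqrt(sigma2) * z[mask])
    return out


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and return it with its generating truth.

    Identical specs (including seed) give identical tables.  The truth
    dict carries the ilr locations, the per-outcome coefficient vectors
    and their implied first-pivot coefficient for every rotation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    p = spec.covariate_params

    female = rng.random(n) < spec.sex_ratio_female
    sex = np.where(female, "F", "M")

    # --- composition: logistic-normal in pivot-ilr space -------------------
    eps = rng.standard_normal((n, 2))
    z = np.empty((n, 2))
    for s, mask in (("M", ~female), ("F", female)):
        mean = np.asarray(spec.ilr_mean_by_sex[s], dtype=float)
        chol = np.linalg.cholesky(np.asarray(spec.ilr_cov_by_sex[s], dtype=float))
        z[mask] = mean + eps[mask] @ chol.T
    comp = coda.ilr_inverse(z, kappa=spec.kappa)

    # --- covariates and risk components ------------------------------------
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "sex": sex,
        }
    )
    df["age9"] = p["age9"]["mean"] + p["age9"]["sd"] * rng.standard_normal(n)
    df["age10"] = p["age10"]["mean"] + p["age10"]["sd"] * rng.standard_normal(n)
    df["aphv9"] = _by_sex_normal(rng, female, p["aphv9"])
    df["aphv10"] = _by_sex_normal(rng, female, p["aphv10"])
    df["body_mass"] = np.clip(_by_sex_normal(rng, female, p["body_mass"]), 15.0, None)
    df["lean_mass"] = np.clip(_by_sex_normal(rng, female, p["lean_mass"]), 10.0, None)
    df["lean_mass_index"] = np.clip(
        _by_sex_normal(rng, female, p["lean_mass_index"]), 8.0, None
    )
    df["fat_mass_index"] = _by_sex_lognormal(rng, female, p["fat_mass_index"])
    df["baseline_diameter"] = np.clip(
        _by_sex_normal(rng, female, p["baseline_diameter"]), 1.5, None
    )
    df["dbp9"] = np.clip(
        p["dbp9"]["mean"] + p["dbp9"]["sd"] * rng.standard_normal(n), 35.0, None
    )
    sbp = p["sbp9"]["mean"] + p["sbp9"]["sd"] * rng.standard_normal(n)
    df["sbp9"] = np.maximum(sbp, df["dbp9"] + 5.0)  # physiologic ordering
    df["tag"] = _lognormal_from_moments(rng, p["tag"]["mean"], p["tag"]["sd"], n)
    df["chol_hdl"] = _lognormal_from_moments(
        rng, p["chol_hdl"]["mean"], p["chol_hdl"]["sd"], n
    )
    df["insulin"] = np.exp(
        p["insulin"]["mu_log"] + p["insulin"]["sd_log"] * rng.standard_normal(n)
    )
    crf_gm = np.where(female, p["crf_scaled_geomean"]["F"], p["crf_scaled_geomean"]["M"])
    crf_scaled = crf_gm * np.exp(p["crf_scaled_sd_log"] * rng.standard_normal(n))
    b_true = p["allometric_exponent"]
    df["pwc170"] = crf_scaled * df["lean_mass"] ** b_true
    df["crf_scaled_lean"] = crf_scaled
    df["social_class"] = rng.choice(
        SOCIAL_CLASS_LEVELS, size=n, p=np.asarray(p["social_class_probs"])
    )
    df["family_history"] = (rng.random(n) < p["family_history_p"]).astype(int)
    for gap in ("time_vasc_accel", "time_cvd_accel"):
        g = p[gap]
        if isinstance(g, dict):
            df[gap] = np.clip(
                g["mean"] + g["sd"] * rng.standard_normal(n), 0.1, None
            )
        else:  # constant override
            df[gap] = float(g)

    for j, part in enumerate(PARTS):
        df[PART_COLUMNS[part]] = comp[:, j]

    # --- outcomes: linear in ilr coordinates + Gaussian noise ---------------
    truth_outcomes: dict[str, dict] = {}
    for outcome, ob in spec.outcome_betas.items():
        beta = np.asarray(ob["beta"], dtype=float)
        lin = ob["intercept"] + z @ beta
        delta = np.asarray(ob.get("beta_female_delta", (0.0, 0.0)), dtype=float)
        if np.any(delta != 0.0):
            lin = lin + female * (z @ delta)
        for col, coef in ob.get("covariate_effects", {}).items():
            lin = lin + coef * df[col].to_numpy(dtype=float)
        noise_sd = float(ob["noise_sd"])
        if noise_sd > 0:
            lin = lin + noise_sd * rng.standard_normal(n)
        df[outcome] = lin
        truth_outcomes[outcome] = {
            "intercept": float(ob["intercept"]),
            "beta_canonical": [float(b) for b in beta],
            "beta_ilr1": coda.first_pivot_betas(beta),
            "beta_female_delta": [float(b) for b in delta],
            "noise_sd": noise_sd,
        }

    truth = {
        "seed": spec.seed,
        "n_participants": n,
        "kappa": spec.kappa,
        "ilr_mean_by_sex": {
            s: [float(v) for v in np.asarray(spec.ilr_mean_by_sex[s])]
            for s in ("M", "F")
        },
        "ilr_cov_by_sex": {
            s: np.asarray(spec.ilr_cov_by_sex[s]).tolist() for s in ("M", "F")
        },
        "allometric_exponent": b_true,
        "outcomes": truth_outcomes,
    }
    return df, truth


def truth_frame(truth: dict) -> pd.DataFrame:
    """Flatten a cohort truth dict into a tidy (outcome, parameter, value) table."""
    rows = []
    for outcome, t in truth["outcomes"].items():
        rows.append((outcome, "intercept", t["intercept"]))
        rows.append((outcome, "noise_sd", t["noise_sd"]))
        for k, b in enumerate(t["beta_canonical"]):
            rows.append((outcome, f"beta_z{k + 1}", b))
        for part, b in t["beta_ilr1"].items():
            rows.append((outcome, f"beta_ilr1_{part}", b))
    return pd.DataFrame(rows, columns=["outcome", "parameter", "value"])


# ---------------------------------------------------------------------------
# epoch streams
# ---------------------------------------------------------------------------


@dataclass
class StreamSpec:
    """Planted-truth accelerometer stream for one participant.

    ``target_minutes`` are per-day (ST, LPA, MVPA) wear minutes and must
    sum to ``wear_minutes_per_day``; ``nonwear_blocks`` is a sequence of
    ``(day, start_epoch, duration)`` zero-count blocks, each at least as
    long as the non-wear detection threshold so the planted truth stays
    exact.  ``day_target_sd`` adds integer day-to-day jitter to the
    targets (re-balanced to keep the wear total); the emulated cohort
    reports no within-person day variance, so it defaults to 0.
    """

    days: int = 1
    wear_minutes_per_day: int = 600
    target_minutes: tuple[int, int, int] = (350, 200, 50)
    nonwear_blocks: tuple[tuple[int, int, int], ...] = ()
    count_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"st": (1, 100), "lpa": (100, 2296), "mvpa": (2296, 5000)}
    )
    day_target_sd: float = 0.0
    nonwear_run_minutes: int = 60  # planted blocks must reach this length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.wear_minutes_per_day < 0:
            raise ValueError("wear minutes must be non-negative")
        t = tuple(int(v) for v in self.target_minutes)
        if any(v < 0 for v in t):
            raise ValueError("target minutes must be non-negative")
        if sum(t) != self.wear_minutes_per_day:
            raise ValueError(
                f"per-day behaviour minutes {t} must sum to wear minutes "
                f"{self.wear_minutes_per_day}"
            )
        for part, (lo, hi) in self.count_ranges.items():
            if lo >= hi:
                raise ValueError(f"count range for {part!r} is empty")
        for day, start, dur in self.nonwear_blocks:
            if not 0 <= day < self.days:
                raise ValueError(f"non-wear block on day {day} outside 0..{self.days - 1}")
            if dur < self.nonwear_run_minutes:
                raise ValueError(
                    "planted non-wear blocks must be at least "
                    f"{self.nonwear_run_minutes} min to be detectable"
                )
            if start < 0:
                raise ValueError("non-wear block start must be non-negative")
        # class bounds must respect the cut-point bands they are generated for
        if self.count_ranges["st"][1] > 100 or self.count_ranges["lpa"][0] < 100:
            raise ValueError("st/lpa count ranges cross the 100 counts min^-1 cut")
        if self.count_ranges["lpa"][1] > 2296 or self.count_ranges["mvpa"][0] < 2296:
            raise ValueError("lpa/mvpa count ranges cross the 2296 counts min^-1 cut")


def _jitter_targets(rng, base: np.ndarray, sd: float, wear: int) -> np.ndarray:
    if sd <= 0:
        return base.copy()
    t = np.clip(np.rint(base + sd * rng.standard_normal(3)).astype(int), 0, None)
    t[int(np.argmax(t))] += wear - t.sum()  # re-balance onto the largest part
    if t.min() < 0:
        raise ValueError("day_target_sd too large for these targets")
    return t


def generate_epoch_stream(
    spec: StreamSpec, participant_id: str = "SIM"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build an epoch stream with exact planted per-day behaviour minutes.

    Returns ``(epoch_df, truth_df)``: the long epoch table and the
    per-day (wear, st, lpa, mvpa) minutes actually planted.  Wear-epoch
    counts are drawn uniformly within each cut-point band (sedentary
    epochs default to >= 1 count so planted non-wear blocks remain the
    only zero runs).
    """
    rng = np.random.default_rng(spec.seed)
    blocks_by_day: dict[int, list[tuple[int, int]]] = {}
    for day, start, dur in spec.nonwear_blocks:
        blocks_by_day.setdefault(day, []).append((int(start), int(dur)))
    epoch_rows = []
    truth_rows = []
    base = np.asarray(spec.target_minutes, dtype=int)
    for day in range(spec.days):
        targets = _jitter_targets(rng, base, spec.day_target_sd, spec.wear_minutes_per_day)
        blocks = sorted(blocks_by_day.get(day, []))
        nonwear_total = sum(d for _, d in blocks)
        day_len = int(targets.sum()) + nonwear_total
        for (s1, d1), (s2, _) in zip(blocks, blocks[1:]):
            if s1 + d1 > s2:
                raise ValueError(f"overlapping non-wear blocks on day {day}")
        if blocks and blocks[-1][0] + blocks[-1][1] > day_len:
            raise ValueError(f"non-wear block exceeds day length on day {day}")

        labels = np.repeat(np.arange(3), targets)
        rng.shuffle(labels)
        wear_counts = np.empty(labels.size, dtype=int)
        for j, part in enumerate(PARTS):
            lo, hi = spec.count_ranges[part]
            sel = labels == j
            wear_counts[sel] = rng.integers(lo, hi, size=int(sel.sum()))

        counts = np.zeros(day_len, dtype=int)
        is_wear = np.ones(day_len, dtype=bool)
        for start, dur in blocks:
            is_wear[start:start + dur] = False
        counts[is_wear] = wear_counts
        epoch_rows.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "day": day,
                    "epoch_index": np.arange(day_len),
                    "counts": counts,
                }
            )
        )
        truth_rows.append(
            {
                "participant_id": participant_id,
                "day": day,
                "wear_minutes": int(targets.sum()),
                "st_minutes": int(targets[0]),
                "lpa_minutes": int(targets[1]),
                "mvpa_minutes": int(targets[2]),
            }
        )
    epoch_df = (
        pd.concat(epoch_rows, ignore_index=True)
        if epoch_rows
        else pd.DataFrame(columns=["participant_id", "day", "epoch_index", "counts"])
    )
    return epoch_df, pd.DataFrame(truth_rows)


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer split of ``total`` proportional to ``weights`` (largest remainder)."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def streams_for_cohort(
    cohort: pd.DataFrame,
    days: int = 4,
    wear_mean: float = 778.0,
    wear_sd: float = 60.0,
    nonwear_block_minutes: int = 60,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Epoch streams whose daily minutes reproduce each cohort composition.

    Each participant's closed composition is rescaled to an individual
    wear time (clipped to keep everyone over the inclusion thresholds)
    and apportioned to integer per-day targets; one non-wear block per
    day is planted at the day start.  Returns the concatenated epoch
    table and per-day truth.
    """
    rng = np.random.default_rng(seed)
    comp_cols = [PART_COLUMNS[p] for p in PARTS]
    epoch_frames = []
    truth_frames = []
    for _, row in cohort.iterrows():
        wear = int(np.clip(rng.normal(wear_mean, wear_sd), 620, 940))
        targets = _apportion(row[comp_cols].to_numpy(dtype=float), wear)
        blocks = tuple(
            (d, 0, nonwear_block_minutes) for d in range(days)
        ) if nonwear_block_minutes else ()
        spec = StreamSpec(
            days=days,
            wear_minutes_per_day=wear,
            target_minutes=tuple(int(t) for t in targets),
            nonwear_blocks=blocks,
            seed=int(rng.integers(2**31)),
        )
        e, t = generate_epoch_stream(spec, participant_id=str(row["participant_id"]))
        epoch_frames.append(e)
        truth_frames.append(t)
    return (
        pd.concat(epoch_frames, ignore_index=True),
        pd.concat(truth_frames, ignore_index=True),
    )
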