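"""Waist-worn accelerometer count processing for children.

Turns 60-s epoch count streams (counts min^-1) into per-participant
mean daily minutes of sedentary time (ST), light physical activity
(LPA) and moderate-to-vigorous physical activity (MVPA).

Processing rules (all configurable through :class:`WearRules`):

* non-wear: a maximal run of >= 60 min of zero counts, allowing up to
  2 min of non-zero interruptions;
* valid day: >= 500 min of wear after non-wear exclusion;
* inclusion: >= 3 valid days and mean valid-day wear >= 600 min day^-1
  (no weekend-day requirement);
* youth cut-points: ST < 100 counts min^-1, MVPA >= 2296 counts min^-1,
  LPA in between.

Intervals are half-open epoch index ranges ``[start, end)``, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WearRules",
    "EpochSeries",
    "DayRecord",
    "PersonSummary",
    "detect_nonwear",
    "classify_epoch",
    "classify_counts",
    "summarize_day",
    "person_summary",
    "process_epochs",
    "exclusion_report",
]

EXCLUSION_INSUFFICIENT_DAYS = "insufficient_valid_days"
EXCLUSION_INSUFFICIENT_WEAR = "insufficient_mean_wear"


@dataclass(frozen=True)
class WearRules:
    """Thresholds governing wear-time cleaning, day validity and cut-points.

    ``interruption_mode`` selects how "up to two min of interruptions"
    inside a candidate non-wear window is read: ``"total"`` caps the
    total number of non-zero epochs in the window at
    ``max_interruption_minutes`` (default, the common reading);
    ``"consecutive"`` caps each non-zero run instead, allowing any
    number of short interruptions.
    """

    nonwear_run_minutes: int = 60
    max_interruption_minutes: int = 2
    interruption_mode: str = "total"
    valid_day_minutes: int = 500
    min_valid_days: int = 3
    mean_wear_minutes: float = 600.0
    st_cutpoint: int = 100
    mvpa_cutpoint: int = 2296

    def __post_init__(self) -> None:
        for name in (
            "nonwear_run_minutes",
            "valid_day_minutes",
            "min_valid_days",
            "mean_wear_minutes",
            "st_cutpoint",
            "mvpa_cutpoint",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_interruption_minutes < 0:
            raise ValueError("max_interruption_minutes must be non-negative")
        if self.st_cutpoint >= self.mvpa_cutpoint:
            raise ValueError("st_cutpoint must be below mvpa_cutpoint")
        if self.interruption_mode not in ("total", "consecutive"):
            raise ValueError("interruption_mode must be 'total' or 'consecutive'")


@dataclass
class EpochSeries:
    """One participant-day of contiguous, ordered 60-s epoch counts."""

    participant_id: str
    day: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-d sequence of epochs")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DayRecord:
    """Per-day wear and behaviour minutes; ST+LPA+MVPA equals wear exactly."""

    participant_id: str
    day: int
    wear_minutes: int
    st_minutes: int
    lpa_minutes: int
    mvpa_minutes: int
    valid: bool


@dataclass(frozen=True)
class PersonSummary:
    """Inclusion decision and mean daily behaviour minutes over valid days."""

    participant_id: str
    included: bool
    reason: str | None
    n_valid_days: int
    mean_wear_minutes: float
    st_min: float = float("nan")
    lpa_min: float = float("nan")
    mvpa_min: float = float("nan")

    def composition(self) -> np.ndarray:
        if not self.included:
            raise ValueError(f"participant excluded: {self.reason}")
        return np.array([self.st_min, self.lpa_min, self.mvpa_min])


def _as_counts(series) -> np.ndarray:
    if isinstance(series, EpochSeries):
        return series.counts
    counts = np.asarray(series)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return counts


def detect_nonwear(series, rules: WearRules = WearRules()) -> list[tuple[int, int]]:
    """Maximal non-wear intervals as half-open epoch ranges.

    A window qualifies when it starts and ends on a zero epoch, spans at
    least ``nonwear_run_minutes`` epochs and its non-zero interruptions
    satisfy ``interruption_mode``.  Scanning is greedy left-to-right:
    the earliest feasible start wins and is extended as far as possible,
    so returned intervals are maximal and non-overlapping.
    """
    counts = _as_counts(series)
    n = len(counts)
    min_len = rules.nonwear_run_minutes
    max_int = rules.max_interruption_minutes
    total_mode = rules.interruption_mode == "total"
    nonzero = counts != 0
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if nonzero[i]:
            i += 1
            continue
        nz_total = 0
        run = 0
        end = i + 1  # window must end on a zero epoch
        j = i + 1
        while j < n:
            if nonzero[j]:
                nz_total += 1
                run += 1
                if (nz_total if total_mode else run) > max_int:
                    break
            else:
                run = 0
                end = j + 1
            j += 1
        if end - i >= min_len:
            intervals.append((i, end))
            i = end
        else:
            i += 1
    return intervals


def classify_epoch(count: float, rules: WearRules = WearRules()) -> str:
    """Behaviour class of a single wear epoch: ``"st"``/``"lpa"``/``"mvpa"``."""
    if count < 0:
        raise ValueError("counts must be non-negative")
    if count < rules.st_cutpoint:
        return "st"
    if count >= rules.mvpa_cutpoint:
        return "mvpa"
    return "lpa"


def classify_counts(counts: np.ndarray, rules: WearRules = WearRules()) -> np.ndarray:
    """Vectorised :func:`classify_epoch` returning a label array."""
    counts = _as_counts(counts)
    out = np.full(counts.shape, "lpa", dtype=object)
    out[counts < rules.st_cutpoint] = "st"
    out[counts >= rules.mvpa_cutpoint] = "mvpa"
    return out


def summarize_day(series: EpochSeries, rules: WearRules = WearRules()) -> DayRecord:
    """Wear minutes, per-behaviour minutes and validity flag for one day."""
    counts = series.counts
    wear = np.ones(len(counts), dtype=bool)
    for s, e in detect_nonwear(counts, rules):
        wear[s:e] = False
    worn = counts[wear]
    st = int(np.count_nonzero(worn < rules.st_cutpoint))
    mvpa = int(np.count_nonzero(worn >= rules.mvpa_cutpoint))
    wear_min = int(worn.size)
    return DayRecord(
        participant_id=series.participant_id,
        day=series.day,
        wear_minutes=wear_min,
        st_minutes=st,
        lpa_minutes=wear_min - st - mvpa,
        mvpa_minutes=mvpa,
        valid=wear_min >= rules.valid_day_minutes,
    )


def person_summary(
    days: Sequence[DayRecord], rules: WearRules = WearRules()
) -> PersonSummary:
    """Apply the inclusion rules and average behaviour minutes over valid days."""
    if len(days) == 0:
        raise ValueError("at least one day record is required")
    pid = days[0].participant_id
    valid = [d for d in days if d.valid]
    if len(valid) < rules.min_valid_days:
        return PersonSummary(
            pid, False, EXCLUSION_INSUFFICIENT_DAYS, len(valid),
            float(np.mean([d.wear_minutes for d in valid])) if valid else 0.0,
        )
    mean_wear = float(np.mean([d.wear_minutes for d in valid]))
    if mean_wear < rules.mean_wear_minutes:
        return PersonSummary(
            pid, False, EXCLUSION_INSUFFICIENT_WEAR, len(valid), mean_wear
        )
    return PersonSummary(
        pid,
        True,
        None,
        len(valid),
        mean_wear,
        st_min=float(np.mean([d.st_minutes for d in valid])),
        lpa_min=float(np.mean([d.lpa_minutes for d in valid])),
        mvpa_min=float(np.mean([d.mvpa_minutes for d in valid])),
    )


def process_epochs(
    epochs: pd.DataFrame, rules: WearRules = WearRules()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a long epoch table into day and person summary tables.

    ``epochs`` needs columns ``participant_id, day, epoch_index, counts``
    (the layout the synthetic stream generator writes).  Returns
    ``(day_df, person_df)``; ``person_df`` carries the inclusion flag
    and the machine-readable exclusion reason.
    """
    required = {"participant_id", "day", "epoch_index", "counts"}
    missing = required - set(epochs.columns)
    if missing:
        raise ValueError(f"epoch table missing columns: {sorted(missing)}")
    epochs = epochs.sort_values(["participant_id", "day", "epoch_index"])
    day_records: list[DayRecord] = []
    person_rows: list[PersonSummary] = []
    for pid, part in epochs.groupby("participant_id", sort=True):
        days = [
            summarize_day(
                EpochSeries(str(pid), int(day), grp["counts"].to_numpy()), rules
            )
            for day, grp in part.groupby("day", sort=True)
        ]
        day_records.extend(days)
        person_rows.append(person_summary(days, rules))
    day_df = pd.DataFrame([vars(d) for d in day_records])
    person_df = pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "included": p.included,
                "reason": p.reason,
                "n_valid_days": p.n_valid_days,
                "mean_wear_minutes": p.mean_wear_minutes,
                "st_min": p.st_min,
                "lpa_min": p.lpa_min,
                "mvpa_min": p.mvpa_min,
            }
            for p in person_rows
        ]
    )
    return day_df, person_df


def exclusion_report(person_df: pd.DataFrame) -> pd.DataFrame:
    """Participant counts per inclusion outcome (for the run log)."""
    out = (
        person_df.assign(outcome=person_df["reason"].fillna("included"))
        .groupby("outcome")
        .size()
        .rename("n_participants")
        .reset_index()
    )
    return out
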