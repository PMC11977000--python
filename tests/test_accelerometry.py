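"""Non-wear detection, cut-point classification and inclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coda_activity import accelerometry as acc
from coda_activity import synthetic

RULES = acc.WearRules()


def oracle_nonwear(counts, rules=RULES):
    """Set-based reference: enumerate every valid window, then select
    greedily (earliest feasible start, longest extent, non-overlapping).

    A window [s, e) is valid when it starts and ends on zero epochs,
    spans >= the run threshold, and its interruptions satisfy the mode.
    Independent of the scanning implementation under test.
    """
    counts = np.asarray(counts)
    n = len(counts)
    nz = (counts != 0).astype(int)
    csum = np.concatenate([[0], np.cumsum(nz)])
    zeros = np.flatnonzero(counts == 0)
    m = rules.max_interruption_minutes
    # starts of non-zero runs longer than m (they invalidate any window
    # containing them; windows are contiguous and zero-bounded, so a long
    # run intersecting a window lies fully inside it)
    long_run_starts = []
    i = 0
    while i < n:
        if nz[i]:
            j = i
            while j < n and nz[j]:
                j += 1
            if j - i > m:
                long_run_starts.append(i)
            i = j
        else:
            i += 1
    long_run_starts = np.asarray(long_run_starts, dtype=int)

    def longest_valid_end(s):
        ends = zeros[zeros >= s + rules.nonwear_run_minutes - 1] + 1
        if rules.interruption_mode == "total":
            ends = ends[csum[ends] - csum[s] <= m]
        else:
            after = long_run_starts[long_run_starts > s]
            if after.size:
                ends = ends[ends <= after[0]]
        return int(ends.max()) if ends.size else None

    out = []
    cursor = 0
    while cursor < n:
        starts = zeros[zeros >= cursor]
        found = None
        for s in starts:
            e = longest_valid_end(int(s))
            if e is not None:
                found = (int(s), e)
                break
        if found is None:
            break
        out.append(found)
        cursor = found[1]
    return out


def random_stream(rng, n=220, p_zero=0.6):
    counts = rng.integers(1, 3000, size=n)
    counts[rng.random(n) < p_zero] = 0
    return counts


class TestClassification:
    @pytest.mark.parametrize(
        "count, expected",
        [(0, "st"), (50, "st"), (99, "st"), (100, "lpa"), (2295, "lpa"),
         (2296, "mvpa"), (10000, "mvpa")],
    )
    def test_cutpoint_boundaries(self, count, expected):
        assert acc.classify_epoch(count) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            acc.classify_epoch(-1)

    def test_vectorised_matches_scalar(self, rng):
        counts = rng.integers(0, 4000, size=200)
        labels = acc.classify_counts(counts)
        assert all(labels[i] == acc.classify_epoch(int(c)) for i, c in enumerate(counts))

    @given(st.integers(min_value=2296, max_value=5000))
    def test_raising_mvpa_cutpoint_never_increases_mvpa(self, cut):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 5000, size=400)
        base = acc.summarize_day(
            acc.EpochSeries("p", 0, counts), acc.WearRules(mvpa_cutpoint=2296)
        )
        raised = acc.summarize_day(
            acc.EpochSeries("p", 0, counts), acc.WearRules(mvpa_cutpoint=cut)
        )
        assert raised.mvpa_minutes <= base.mvpa_minutes


class TestNonwearDetection:
    def test_pure_run_inside_wear_day(self):
        counts = np.r_[np.full(100, 500), np.zeros(70, int), np.full(100, 500)]
        assert acc.detect_nonwear(counts) == [(100, 170)]

    def test_run_below_threshold_is_wear(self):
        counts = np.r_[[500], np.zeros(59, int), [500]]
        assert acc.detect_nonwear(counts) == []

    def test_interruption_tolerated(self):
        counts = np.r_[np.zeros(30, int), [500, 500], np.zeros(30, int)]
        assert acc.detect_nonwear(counts) == [(0, 62)]

    def test_three_interruptions_split_window_in_total_mode(self):
        counts = np.r_[
            np.zeros(30, int), [500], np.zeros(5, int), [500], np.zeros(5, int),
            [500], np.zeros(30, int),
        ]
        assert acc.detect_nonwear(counts) == []
        # consecutive mode allows any number of 1-min interruptions
        consec = acc.WearRules(interruption_mode="consecutive")
        assert acc.detect_nonwear(counts, consec) == [(0, len(counts))]

    def test_long_interruption_run_terminates_window(self):
        counts = np.r_[np.zeros(40, int), [500, 500, 500], np.zeros(70, int)]
        assert acc.detect_nonwear(counts, acc.WearRules(interruption_mode="consecutive")) == [
            (43, 113)
        ]

    def test_empty_series(self):
        assert acc.detect_nonwear(np.array([], dtype=int)) == []

    @pytest.mark.parametrize("mode", ["total", "consecutive"])
    def test_agrees_with_window_enumeration_oracle(self, mode):
        rules = acc.WearRules(interruption_mode=mode)
        rng = np.random.default_rng(2024)
        for _ in range(150):
            counts = random_stream(rng, n=int(rng.integers(80, 260)))
            assert acc.detect_nonwear(counts, rules) == oracle_nonwear(counts, rules)

    def test_interval_contract(self, rng):
        # every interval: zero-bounded, >= 60 min, <= 2 interruptions, disjoint
        for _ in range(50):
            counts = random_stream(rng)
            prev_end = -1
            for s, e in acc.detect_nonwear(counts):
                assert counts[s] == 0 and counts[e - 1] == 0
                assert e - s >= 60
                assert np.count_nonzero(counts[s:e]) <= 2
                assert s >= prev_end
                prev_end = e


class TestDaySummary:
    def test_all_sedentary_day_with_short_zero_runs(self):
        # zero runs of 57 min separated by 3-min low-count bursts: every
        # candidate window is broken (>2 interruptions), so all 600 min are
        # wear and every epoch sits below the sedentary cut-point
        unit = np.r_[np.zeros(57, int), [50, 50, 50]]
        counts = np.tile(unit, 10)
        day = acc.summarize_day(acc.EpochSeries("p", 0, counts))
        assert day.wear_minutes == 600
        assert day.st_minutes == 600 and day.valid

    def test_conservation_and_validity(self, rng):
        for _ in range(30):
            counts = random_stream(rng, n=700, p_zero=0.3)
            day = acc.summarize_day(acc.EpochSeries("p", 0, counts))
            assert day.st_minutes + day.lpa_minutes + day.mvpa_minutes == day.wear_minutes
            assert day.valid == (day.wear_minutes >= 500)

    @pytest.mark.parametrize("wear, valid", [(499, False), (500, True)])
    def test_valid_day_boundary(self, wear, valid):
        day = acc.summarize_day(acc.EpochSeries("p", 0, np.full(wear, 150)))
        assert day.valid is valid

    def test_planted_stream_recovered_exactly(self):
        spec = synthetic.StreamSpec(
            days=1, wear_minutes_per_day=600, target_minutes=(350, 200, 50), seed=11
        )
        epochs, truth = synthetic.generate_epoch_stream(spec, "p")
        day = acc.summarize_day(acc.EpochSeries("p", 0, epochs["counts"].to_numpy()))
        assert (day.st_minutes, day.lpa_minutes, day.mvpa_minutes) == (350, 200, 50)

    def test_planted_nonwear_block_found_exactly(self):
        spec = synthetic.StreamSpec(
            days=1, wear_minutes_per_day=500, target_minutes=(300, 150, 50),
            nonwear_blocks=((0, 120, 70),), seed=5,
        )
        epochs, _ = synthetic.generate_epoch_stream(spec, "p")
        assert acc.detect_nonwear(epochs["counts"].to_numpy()) == [(120, 190)]


def _day(wear, valid=None, pid="p", day=0):
    st = wear
    return acc.DayRecord(pid, day, wear, st, 0, 0, wear >= 500 if valid is None else valid)


class TestPersonSummary:
    def test_constant_days_average_to_composition(self):
        days = [
            acc.DayRecord("p", d, 600, 350, 200, 50, True) for d in range(3)
        ]
        summary = acc.person_summary(days)
        assert summary.included
        assert np.allclose(summary.composition(), [350, 200, 50])

    def test_two_valid_days_excluded(self):
        days = [_day(610), _day(620), _day(400)]
        summary = acc.person_summary(days)
        assert not summary.included
        assert summary.reason == acc.EXCLUSION_INSUFFICIENT_DAYS

    def test_mean_wear_below_600_excluded(self):
        days = [_day(w, day=i) for i, w in enumerate((610, 610, 610, 550))]
        summary = acc.person_summary(days)
        assert not summary.included
        assert summary.reason == acc.EXCLUSION_INSUFFICIENT_WEAR
        assert summary.mean_wear_minutes == pytest.approx(595.0)

    def test_mean_wear_exactly_600_included(self):
        days = [_day(w, day=i) for i, w in enumerate((620, 600, 580))]
        assert acc.person_summary(days).included

    def test_requires_at_least_one_day(self):
        with pytest.raises(ValueError):
            acc.person_summary([])


class TestProcessEpochs:
    def test_round_trip_through_long_table(self):
        spec = synthetic.StreamSpec(
            days=4, wear_minutes_per_day=640, target_minutes=(380, 200, 60),
            nonwear_blocks=tuple((d, 0, 60) for d in range(4)), seed=9,
        )
        epochs, truth = synthetic.generate_epoch_stream(spec, "p1")
        day_df, person_df = acc.process_epochs(epochs)
        assert len(day_df) == 4
        merged = day_df.merge(truth, on=["participant_id", "day"], suffixes=("", "_t"))
        assert (merged["st_minutes"] == merged["st_minutes_t"]).all()
        assert (merged["wear_minutes"] == merged["wear_minutes_t"]).all()
        person = person_df.iloc[0]
        assert person["included"]
        assert person["st_min"] == pytest.approx(380.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            acc.process_epochs(pd.DataFrame({"participant_id": [], "day": []}))

    def test_exclusion_report_counts(self):
        person_df = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "included": [True, False, False],
                "reason": [None, acc.EXCLUSION_INSUFFICIENT_DAYS,
                           acc.EXCLUSION_INSUFFICIENT_DAYS],
            }
        )
        rep = acc.exclusion_report(person_df).set_index("outcome")["n_participants"]
        assert rep["included"] == 1
        assert rep[acc.EXCLUSION_INSUFFICIENT_DAYS] == 2
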