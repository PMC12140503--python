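"""Instance detection, usage, sample selection, episode segmentation (with an
independent maximal-run oracle), timescale summaries and descriptives."""

import itertools
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emasi import (
    MISSING,
    descriptive_stats,
    descriptive_table,
    detect_si_instances,
    monthly_grid,
    segment_episodes,
    select_analytic_sample,
    time_slot_distribution,
    timescale_summary,
    usage_rate,
)

from conftest import make_record, make_series


# ---------------------------------------------------------------------------
# Independent oracle: partition the day axis at observed resting days (and,
# without bridging, at missing days); each block holding an elevated day is
# one episode.  Formulated differently from the scanner it checks.
# ---------------------------------------------------------------------------

def oracle_segments(states, cutoff, bridge):
    """Return [(start, termination_or_None, duration, censored), ...]."""
    n = len(states)
    boundaries = [-1]  # virtual boundary before the series
    for i, s in enumerate(states):
        if s == 0 or (s is None and not bridge):
            boundaries.append(i)
    boundaries.append(n)
    out = []
    for a, b in zip(boundaries, boundaries[1:]):
        block = range(a + 1, b)
        elevated = [i for i in block if states[i] is not None and states[i] >= cutoff]
        if not elevated:
            continue
        start = elevated[0]
        if b < n and states[b] == 0:  # bounded on the right by an observed 0
            out.append((start, b, b - start, False))
        else:
            out.append((start, None, elevated[-1] - start + 1, True))
    return out


def run_segmenter(states, cutoff, bridge):
    eps = segment_episodes(make_series(states), cutoff=cutoff, bridge_missing=bridge)
    origin = date(2022, 1, 1)
    return [
        (
            (e.start_day - origin).days,
            (e.termination_day - origin).days if e.termination_day else None,
            e.duration_days,
            e.censored,
        )
        for e in eps
    ]


def observed_endpoint_sequences(alphabet, max_len):
    for n in range(1, max_len + 1):
        for seq in itertools.product(alphabet, repeat=n):
            if seq[0] is None or seq[-1] is None:
                continue
            yield list(seq)


class TestSegmentationExamples:
    def test_four_consecutive_days_then_rest(self):
        (ep,) = segment_episodes(make_series([1, 1, 1, 1, 0]))
        assert ep.duration_days == 4
        assert not ep.censored and ep.n_instance_days == 4

    def test_all_zero_gives_no_episode(self):
        assert segment_episodes(make_series([0, 0, 0])) == []

    def test_bridging_conventions_on_gap(self):
        bridged = segment_episodes(make_series([1, None, 1, 0]), bridge_missing=True)
        assert [(e.duration_days, e.censored) for e in bridged] == [(3, False)]
        split = segment_episodes(make_series([1, None, 1, 0]), bridge_missing=False)
        assert [e.duration_days for e in split] == [1, 1]

    def test_series_end_censors(self):
        (ep,) = segment_episodes(make_series([2, 1]))
        assert ep.censored and ep.duration_days == 2 and ep.max_score == 2

    def test_higher_cutoff_skips_low_scores(self):
        eps = segment_episodes(make_series([1, 2, 1, 0]), cutoff=2)
        assert len(eps) == 1 and eps[0].n_instance_days == 1


class TestSegmentationOracle:
    def test_exhaustive_small_alphabet(self):
        for states in observed_endpoint_sequences((0, 1, None), 9):
            for bridge in (True, False):
                assert run_segmenter(states, 1, bridge) == oracle_segments(
                    states, 1, bridge
                ), (states, bridge)

    @settings(max_examples=1500, derandomize=True, deadline=None)
    @given(
        st.lists(st.sampled_from([0, 1, 2, 3, None]), min_size=1, max_size=12),
        st.sampled_from([1, 2, 3]),
        st.booleans(),
    )
    def test_randomised_full_alphabet(self, states, cutoff, bridge):
        if states[0] is None or states[-1] is None:
            states = [0] + states[1:-1] + [0] if len(states) > 1 else [0]
        assert run_segmenter(states, cutoff, bridge) == oracle_segments(
            states, cutoff, bridge
        )

    @settings(max_examples=400, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from([0, 1, 2, 3, None]), min_size=1, max_size=20))
    def test_invariants(self, states):
        if states[0] is None:
            states[0] = 0
        if states[-1] is None:
            states[-1] = 0
        s = make_series(states)
        bridged = segment_episodes(s, bridge_missing=True)
        split = segment_episodes(s, bridge_missing=False)
        n_elevated = sum(1 for v in states if v is not None and v >= 1)
        # conservation of observed elevated days
        assert sum(e.n_instance_days for e in bridged) == n_elevated
        assert sum(e.n_instance_days for e in split) == n_elevated
        # bridging merges runs: fewer episodes, no shorter in total
        assert len(bridged) <= len(split)
        assert sum(e.duration_days for e in bridged) >= sum(e.duration_days for e in split)
        # raising the cutoff never increases the episode count
        for lo, hi in ((1, 2), (2, 3)):
            assert len(segment_episodes(s, cutoff=hi)) <= len(segment_episodes(s, cutoff=lo))


class TestInstancesAndUsage:
    def test_threshold_counting(self):
        recs = [make_record("p", i, v) for i, v in enumerate([0, 1, 0, 2])]
        assert len(detect_si_instances(recs)) == 2
        assert len(detect_si_instances(recs, cutoff=3)) == 0
        assert detect_si_instances([]) == []

    def test_cutoff_three(self):
        recs = [make_record("p", i, v) for i, v in enumerate([1, 2, 3])]
        assert len(detect_si_instances(recs, cutoff=3)) == 1

    def test_missing_item9_contributes_nothing(self):
        recs = [make_record("p", 0, None), make_record("p", 1, 1)]
        assert len(detect_si_instances(recs)) == 1

    def test_cutoff_monotonicity_on_cohort(self, small_cohort):
        counts = [len(detect_si_instances(small_cohort.records, cutoff=c)) for c in (1, 2, 3)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_usage_counts_distinct_days(self):
        recs = [make_record("p", d, 0) for d in (0, 4, 9)]
        assert usage_rate(recs, "p") == pytest.approx(0.30)

    def test_same_day_duplicates_do_not_double_count(self):
        recs = [make_record("p", 0, 0, hour=8), make_record("p", 0, 1, hour=20)]
        assert usage_rate(recs, "p") == 1.0

    def test_daily_survey_is_ceiling(self):
        recs = [make_record("p", d, 0) for d in range(7)]
        assert usage_rate(recs, "p") == 1.0


class TestAnalyticSample:
    def _records(self):
        recs = []
        # pb1: Bhopal, 1 instance, high usage -> excluded on si_count
        recs += [make_record("pb1", d, 1 if d == 0 else 0) for d in range(10)]
        # pb2: Bhopal, usage 0.39 < 0.40 with 3 instances -> excluded on usage
        recs += [make_record("pb2", d, 1 if d < 3 else 0) for d in range(38)]
        recs += [make_record("pb2", 99, 0)]  # 39 filled days / 100-day span
        # pg1: Bengaluru, usage exactly at 0.20 with 3 instances -> retained
        recs += [make_record("pg1", d * 5, 1 if d < 3 else 0) for d in range(20)]
        recs += [make_record("pg1", 99, 0)]
        return recs

    def test_selection_and_exclusion_log(self):
        recs = self._records()
        sites = {"pb1": "Bhopal", "pb2": "Bhopal", "pg1": "Bengaluru"}
        kept, log = select_analytic_sample(recs, sites, min_si_instances=2)
        assert kept == ["pg1"]
        reasons = dict(zip(log["participant_id"], log["reason"]))
        assert reasons == {"pb1": "si_count", "pb2": "usage"}

    def test_unknown_site_is_fatal(self):
        recs = [make_record("x", 0, 1), make_record("x", 1, 1)]
        with pytest.raises(ValueError, match="unknown site"):
            select_analytic_sample(recs, {"x": "Mumbai"})


class TestTimescaleSummary:
    def test_basic_arithmetic(self):
        s1 = make_series([1, 0] * 3, pid="a")  # 3 episodes of duration 1
        s2 = make_series([1, 0] * 5, pid="b")  # 5 episodes
        summ = timescale_summary({"a": segment_episodes(s1), "b": segment_episodes(s2)})
        freq = summ.loc["episode_frequency"]
        assert freq["mean"] == 4 and freq["sum"] == 8
        assert (freq["min"], freq["max"]) == (3, 5)

    def test_single_participant_sd_undefined(self):
        summ = timescale_summary({"a": segment_episodes(make_series([1, 0]))})
        assert np.isnan(summ.loc["episode_frequency", "sd"])
        assert summ.loc["episode_frequency", "mean"] == 1

    def test_zero_episode_participants_excluded(self):
        summ = timescale_summary(
            {"a": segment_episodes(make_series([1, 0])), "b": []}
        )
        assert summ.loc["episode_frequency", "n"] == 1

    def test_empty_signalled(self):
        with pytest.raises(ValueError):
            timescale_summary({"a": []})

    def test_cohort_of_eleven_mirrors_layout(self):
        # 11 participants whose per-participant mean durations sum to 27
        durs = [1, 1, 1, 2, 2, 2, 3, 3, 4, 4, 4]
        eps = {}
        for i, d in enumerate(durs):
            pid = f"p{i:02d}"
            eps[pid] = segment_episodes(make_series(([1] * d + [0]) * 2, pid=pid))
        summ = timescale_summary(eps)
        dur = summ.loc["mean_episode_duration"]
        assert dur["sum"] == pytest.approx(27)
        assert dur["mean"] == pytest.approx(27 / 11)


class TestDescriptives:
    def test_consecutive_day_gap_is_one(self):
        recs = [make_record("p", 0, 1), make_record("p", 1, 1), make_record("p", 2, 0)]
        row = descriptive_stats(
            make_series([1, 1, 0], pid="p"), detect_si_instances(recs)
        )
        assert row.mean_gap_between_successive_si == pytest.approx(1.0)
        assert row.n_si_instances == 2

    def test_four_day_run_mean_gap_still_one(self):
        recs = [make_record("p", d, 1) for d in range(4)] + [make_record("p", 4, 0)]
        row = descriptive_stats(make_series([1, 1, 1, 1, 0], pid="p"), detect_si_instances(recs))
        assert row.mean_gap_between_successive_si == pytest.approx(1.0)
        assert row.days_first_to_last_si == 3

    def test_same_day_instances_gap_zero(self):
        recs = [
            make_record("p", 0, 1, hour=8),
            make_record("p", 0, 2, hour=20),
            make_record("p", 1, 0),
        ]
        row = descriptive_stats(make_series([2, 0], pid="p"), detect_si_instances(recs))
        assert row.mean_gap_between_successive_si == 0.0
        assert row.n_si_instances == 2  # survey-level: same-day pair counts twice

    def test_modal_percentage(self):
        row = descriptive_stats(make_series([0, 0, 1, 0]), [])
        assert row.pct_modal_response == pytest.approx(75.0)

    def test_tail_no_si_days(self):
        recs = [make_record("p", 1, 2)]
        row = descriptive_stats(make_series([0, 2, 0, 0, 0], pid="p"), detect_si_instances(recs))
        assert row.tail_no_si_days == 3

    def test_aggregate_table_skips_absent(self):
        rows = [
            descriptive_stats(make_series([0, 1, 0], pid="a"), detect_si_instances([make_record("a", 1, 1)])),
            descriptive_stats(make_series([0, 0], pid="b"), []),
        ]
        table = descriptive_table(rows)
        assert table.loc["n_si_instances", "n"] == 2
        assert table.loc["mean_gap_between_successive_si", "n"] == 1 if "mean_gap_between_successive_si" in table.index else True


class TestMonthlyGrid:
    def test_single_month_cell(self):
        recs = [make_record("p", d, 1 if d < 5 else 0) for d in range(10)]
        grid = monthly_grid(detect_si_instances(recs), recs)
        assert grid.to_numpy()[np.isfinite(grid.to_numpy())].sum() == 5

    def test_grand_total_conservation(self, small_cohort):
        recs = small_cohort.records
        insts = detect_si_instances(recs)
        grid = monthly_grid(insts, recs)
        vals = grid.to_numpy()
        assert np.nansum(vals) == len(insts)

    def test_out_of_window_cells_distinct_from_zero(self, small_cohort):
        grid = monthly_grid(
            detect_si_instances(small_cohort.records), small_cohort.records
        )
        assert np.isnan(grid.to_numpy()).any() or grid.notna().all().all()


class TestTimeSlots:
    def test_quarter_split(self):
        recs = [make_record("p", 0, 0, hour=h) for h in (1, 7, 13, 19)]
        table = time_slot_distribution(recs, [])
        assert list(table["pct_surveys"]) == [25.0] * 4

    def test_noon_goes_to_third_slot(self):
        recs = [make_record("p", 0, 0, hour=12)]
        table = time_slot_distribution(recs, [])
        assert table.loc["12:00-18:00", "n_surveys"] == 1

    def test_percentages_sum_to_100(self, small_cohort):
        insts = detect_si_instances(small_cohort.records)
        table = time_slot_distribution(small_cohort.records, insts)
        assert table["pct_surveys"].sum() == pytest.approx(100.0)
        assert table["pct_si_instances"].sum() == pytest.approx(100.0)

    def test_date_only_timestamps_refused(self):
        recs = [make_record("p", d, 0, hour=0) for d in range(3)]
        with pytest.raises(ValueError, match="midnight"):
            time_slot_distribution(recs, [])
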