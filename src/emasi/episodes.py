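"""SI-instance detection, usage metrics, episode segmentation and timescale
summary statistics.

An *instance* of suicidal ideation (SI) is a survey whose PHQ-9 item-9 score
meets the cutoff (default >=1).  An *episode* is a maximal run of consecutive
grid days with SI state >= cutoff; it terminates on the first later day with
an observed resting state (score 0).  Because unobserved days between the
last elevated day and the first observed 0 are counted, the elapsed-time
duration is an upper bound on the true elevated period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import MISSING, DailySeries, SiInstance, SurveyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Episode:
    """One maximal run of elevated SI on the daily grid.

    ``duration_days`` equals ``termination_day - start_day`` when an observed
    resting day terminates the run; if the series ends first, the episode is
    censored and the duration runs through the last elevated day inclusive.
    """

    participant_id: str
    start_day: date
    termination_day: date | None
    duration_days: int
    censored: bool
    n_instance_days: int
    max_score: int

    def __post_init__(self) -> None:
        if self.duration_days < self.n_instance_days or self.n_instance_days < 1:
            raise ValueError("episode must satisfy duration >= n_instance_days >= 1")
        if not self.censored:
            if self.termination_day is None:
                raise ValueError("uncensored episode needs a termination day")
            if (self.termination_day - self.start_day).days != self.duration_days:
                raise ValueError("duration must equal termination - start")


def detect_si_instances(
    records: Iterable[SurveyRecord], cutoff: int = 1
) -> list[SiInstance]:
    """One instance per survey with item-9 score >= cutoff (survey level:
    two qualifying surveys on the same day yield two instances)."""
    if cutoff not in (1, 2, 3):
        raise ValueError("cutoff must be 1, 2 or 3")
    return [
        SiInstance(r.participant_id, r.timestamp, r.si_score)
        for r in records
        if r.si_score is not None and r.si_score >= cutoff
    ]


def usage_rate(records: Sequence[SurveyRecord], participant_id: str) -> float:
    """Fraction of calendar days in the first-to-last-survey span with >=1
    filled mood survey (only the first survey of a day counts)."""
    days = sorted({r.day for r in records if r.participant_id == participant_id})
    if not days:
        raise ValueError(f"no surveys for participant {participant_id!r}")
    span = (days[-1] - days[0]).days + 1
    return len(days) / span


def monthly_usage(
    records: Sequence[SurveyRecord], participant_id: str
) -> pd.Series:
    """Per-calendar-month usage: filled days / days of that month inside the
    participant's reporting span.  Index is a pandas PeriodIndex."""
    days = sorted({r.day for r in records if r.participant_id == participant_id})
    if not days:
        raise ValueError(f"no surveys for participant {participant_id!r}")
    first, last = days[0], days[-1]
    filled = pd.Series(1, index=pd.PeriodIndex([pd.Period(d, "M") for d in days]))
    filled = filled.groupby(level=0).sum()
    out = {}
    for period in pd.period_range(pd.Period(first, "M"), pd.Period(last, "M")):
        mstart = max(first, period.start_time.date())
        mend = min(last, period.end_time.date())
        n_days = (mend - mstart).days + 1
        out[period] = filled.get(period, 0) / n_days
    return pd.Series(out)


def select_analytic_sample(
    records: Sequence[SurveyRecord],
    site_by_participant: Mapping[str, str],
    min_si_instances: int = 2,
    usage_cutoff_by_site: Mapping[str, float] | None = None,
    cutoff: int = 1,
) -> tuple[list[str], pd.DataFrame]:
    """Retain participants with >= ``min_si_instances`` SI instances AND a
    usage rate at or above their site's cutoff.

    Default site cutoffs mirror the two-site design this analysis targets
    (0.40 for 'Bhopal', 0.20 for 'Bengaluru').  Returns the retained ids and
    an exclusion log with one row per dropped participant and the first
    criterion that excluded them.
    """
    if usage_cutoff_by_site is None:
        usage_cutoff_by_site = {"Bhopal": 0.40, "Bengaluru": 0.20}
    pids = sorted({r.participant_id for r in records})
    unknown = [p for p in pids if site_by_participant.get(p) not in usage_cutoff_by_site]
    if unknown:
        raise ValueError(f"participants with unknown site tag: {unknown}")
    instances = detect_si_instances(records, cutoff=cutoff)
    n_inst = {p: 0 for p in pids}
    for inst in instances:
        n_inst[inst.participant_id] += 1
    kept: list[str] = []
    log_rows = []
    for p in pids:
        u = usage_rate(records, p)
        site = site_by_participant[p]
        if n_inst[p] < min_si_instances:
            log_rows.append(
                {"participant_id": p, "reason": "si_count", "n_si_instances": n_inst[p], "usage_rate": u}
            )
        elif u < usage_cutoff_by_site[site]:
            log_rows.append(
                {"participant_id": p, "reason": "usage", "n_si_instances": n_inst[p], "usage_rate": u}
            )
        else:
            kept.append(p)
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason", "n_si_instances", "usage_rate"])
    return kept, log


# ---------------------------------------------------------------------------
# Episode segmentation
# ---------------------------------------------------------------------------

def segment_episodes(
    series: DailySeries, cutoff: int = 1, bridge_missing: bool = True
) -> list[Episode]:
    """Scan the daily grid for maximal runs of SI state >= cutoff.

    With ``bridge_missing`` (default) an episode runs until the first later
    day with an *observed* resting state 0; intervening MISSING days are
    bridged, making the elapsed duration an upper bound.  Without bridging,
    a MISSING day ends the run at the last observed elevated day.  If the
    series ends before an observed 0 the episode is censored, with duration
    through the last elevated day inclusive.
    """
    states = series.states
    n = len(states)
    episodes: list[Episode] = []
    i = 0
    while i < n:
        if states[i] < cutoff or states[i] == MISSING:
            i += 1
            continue
        start = i
        last_elevated = i
        term: int | None = None
        j = i + 1
        while j < n:
            s = states[j]
            if s == 0:
                term = j
                break
            if s == MISSING:
                if not bridge_missing:
                    break
            elif s >= cutoff:
                last_elevated = j
            j += 1
        inside = states[start : last_elevated + 1]
        n_instance_days = int(np.sum(inside >= cutoff))
        max_score = int(inside[inside >= cutoff].max())
        if term is not None:
            ep = Episode(
                series.participant_id,
                series.date_of(start),
                series.date_of(term),
                term - start,
                False,
                n_instance_days,
                max_score,
            )
            i = term
        else:
            ep = Episode(
                series.participant_id,
                series.date_of(start),
                None,
                last_elevated - start + 1,
                True,
                n_instance_days,
                max_score,
            )
            i = j if bridge_missing else max(j, last_elevated + 1)
        episodes.append(ep)
    return episodes


def _summary_block(values: np.ndarray) -> dict:
    """Mean/SD/range/sum/IQR block in the style of the timescale tables.
    SD is the sample SD and is NaN for a single value."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return {
        "n": int(len(values)),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "sum": float(np.sum(values)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def timescale_summary(episodes_by_participant: Mapping[str, Sequence[Episode]]) -> pd.DataFrame:
    """Cohort timescale statistics over participants with >=1 episode.

    Two rows: frequency of SI episodes (per-participant counts) and average
    SI episode duration (per-participant mean durations).  Columns are
    mean/SD/range/sum/IQR, so 'sum' for durations is the sum of per-
    participant means, matching how the cohort tables are laid out.
    """
    freqs, mean_durs = [], []
    for _, eps in sorted(episodes_by_participant.items()):
        if not eps:
            continue
        freqs.append(len(eps))
        mean_durs.append(float(np.mean([e.duration_days for e in eps])))
    if not freqs:
        raise ValueError("no participant has any episode")
    return pd.DataFrame(
        [
            {"statistic": "episode_frequency", **_summary_block(np.array(freqs))},
            {"statistic": "mean_episode_duration", **_summary_block(np.array(mean_durs))},
        ]
    ).set_index("statistic")


# ---------------------------------------------------------------------------
# Descriptive statistics (instance level, disregarding episodes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptiveRow:
    """Per-participant instance-level descriptives.

    Gap and span fields are None when the participant has no instance.
    Successive gaps are measured survey-to-survey in calendar days, so two
    same-day instances contribute a gap of 0.
    """

    participant_id: str
    n_si_instances: int
    days_first_to_last_si: int | None
    pct_modal_response: float
    tail_no_si_days: int | None
    mean_gap_between_successive_si: float | None


def descriptive_stats(
    series: DailySeries, instances: Sequence[SiInstance]
) -> DescriptiveRow:
    """Instance-level descriptives for one participant.

    ``pct_modal_response`` is the percentage of observed grid days in the
    resting state 0; the tail is the time from the last SI day to the end of
    the grid.
    """
    mine = sorted(
        (i for i in instances if i.participant_id == series.participant_id),
        key=lambda i: i.timestamp,
    )
    observed = series.states[series.states != MISSING]
    pct_modal = 100.0 * float(np.mean(observed == 0)) if len(observed) else float("nan")
    if not mine:
        return DescriptiveRow(series.participant_id, 0, None, pct_modal, None, None)
    first_day, last_day = mine[0].day, mine[-1].day
    span = (last_day - first_day).days
    tail = (series.end_date - last_day).days
    if len(mine) > 1:
        gaps = [
            (b.day - a.day).days for a, b in zip(mine, mine[1:])
        ]
        mean_gap = float(np.mean(gaps))
    else:
        mean_gap = None
    return DescriptiveRow(
        series.participant_id, len(mine), span, pct_modal, tail, mean_gap
    )


def descriptive_table(rows: Sequence[DescriptiveRow]) -> pd.DataFrame:
    """Cohort aggregate of the per-participant descriptives: mean/SD,
    median/IQR and range per field, skipping absent values."""
    fields = [
        "n_si_instances",
        "days_first_to_last_si",
        "pct_modal_response",
        "tail_no_si_days",
        "mean_gap_between_successive_si",
    ]
    out = []
    for f in fields:
        vals = np.array(
            [getattr(r, f) for r in rows if getattr(r, f) is not None], dtype=float
        )
        if len(vals) == 0:
            continue
        out.append({"statistic": f, **_summary_block(vals)})
    return pd.DataFrame(out).set_index("statistic")


# ---------------------------------------------------------------------------
# Monthly grid and time-of-day slots
# ---------------------------------------------------------------------------

def monthly_grid(
    instances: Sequence[SiInstance],
    records: Sequence[SurveyRecord],
    participants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Month x participant grid of SI-instance counts.

    Cells inside a participant's reporting window are integer counts
    (possibly 0); cells outside it are NaN, so absence-of-reporting is
    distinct from an observed zero.  The grand total equals the instance
    count.
    """
    if participants is None:
        participants = sorted({r.participant_id for r in records})
    spans = {}
    for p in participants:
        days = sorted({r.day for r in records if r.participant_id == p})
        if days:
            spans[p] = (pd.Period(days[0], "M"), pd.Period(days[-1], "M"))
    if not spans:
        return pd.DataFrame()
    lo = min(s[0] for s in spans.values())
    hi = max(s[1] for s in spans.values())
    months = pd.period_range(lo, hi)
    grid = pd.DataFrame(np.nan, index=months, columns=list(participants))
    for p, (a, b) in spans.items():
        grid.loc[a:b, p] = 0.0
    for inst in instances:
        if inst.participant_id in grid.columns:
            m = pd.Period(inst.day, "M")
            if not np.isnan(grid.at[m, inst.participant_id]):
                grid.at[m, inst.participant_id] += 1
            else:  # instance outside the survey span cannot happen, but be safe
                grid.at[m, inst.participant_id] = 1
    return grid


SLOT_LABELS = ("00:00-06:00", "06:00-12:00", "12:00-18:00", "18:00-24:00")


def time_slot_distribution(
    records: Sequence[SurveyRecord], instances: Sequence[SiInstance]
) -> pd.DataFrame:
    """Survey and SI-instance counts per 6-hour slot (half-open bins), with
    percentages of the respective totals.

    Refuses date-only data: if every timestamp falls exactly at midnight the
    time of day is presumed unrecorded.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    if all(r.timestamp.time() == datetime.min.time() for r in records):
        raise ValueError(
            "all timestamps are midnight; time-of-day appears unrecorded, "
            "cannot compute slot distribution"
        )

    def slot(t: datetime) -> int:
        return t.hour // 6

    surveys = np.zeros(4, dtype=int)
    si = np.zeros(4, dtype=int)
    for r in records:
        surveys[slot(r.timestamp)] += 1
    for i in instances:
        si[slot(i.timestamp)] += 1
    return pd.DataFrame(
        {
            "slot": SLOT_LABELS,
            "n_surveys": surveys,
            "pct_surveys": 100.0 * surveys / surveys.sum(),
            "n_si_instances": si,
            "pct_si_instances": (100.0 * si / si.sum()) if si.sum() else 0.0,
        }
    ).set_index("slot")


# ---------------------------------------------------------------------------
# Survey-level cohort summary
# ---------------------------------------------------------------------------

def survey_summary(records: Sequence[SurveyRecord]) -> dict:
    """Cohort survey counts: totals, per-participant distribution, reporting
    span, and item-9 missingness among filled surveys."""
    pids = sorted({r.participant_id for r in records})
    per = np.array([sum(1 for r in records if r.participant_id == p) for p in pids])
    n_missing_item9 = sum(1 for r in records if r.si_score is None)
    spans = []
    for p in pids:
        days = sorted({r.day for r in records if r.participant_id == p})
        spans.append((days[-1] - days[0]).days + 1)
    return {
        "n_participants": len(pids),
        "n_surveys": int(per.sum()),
        "surveys_per_participant": _summary_block(per) if len(per) else None,
        "reporting_days": _summary_block(np.array(spans)) if spans else None,
        "n_item9_missing": int(n_missing_item9),
        "pct_item9_missing": 100.0 * n_missing_item9 / per.sum() if per.sum() else float("nan"),
    }
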