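"""Alignment of monthly PANSS trajectories with the SI series.

The marker of beginning clinical improvement is the *first drop*: the
earliest assessment strictly lower than its predecessor (or, behind a flag,
than baseline).  The lag to the last reported SI instance inside the PANSS
reporting window is signed: negative lags mean the last SI preceded the
drop, positive lags mean SI persisted after improvement began.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PanssAssessment, SiInstance, SurveyRecord
from .episodes import monthly_usage

logger = logging.getLogger(__name__)

SUBSCALES = ("positive", "negative", "general")


@dataclass(frozen=True)
class FirstDrop:
    participant_id: str
    subscale: str
    drop_date: date
    previous_score: int
    drop_score: int
    baseline_relative: bool = False

    def __post_init__(self) -> None:
        if self.drop_score >= self.previous_score:
            raise ValueError("a drop requires a strictly lower score")


@dataclass(frozen=True)
class LagResult:
    """Signed lag (days) = date of last in-window SI instance − drop date."""

    participant_id: str
    subscale: str
    lag_days: int


def first_drop(
    assessments: Sequence[PanssAssessment],
    subscale: str,
    baseline_relative: bool = False,
) -> FirstDrop | None:
    """Earliest assessment strictly below its predecessor (default) or below
    the baseline assessment (``baseline_relative``).  Ties are not drops.
    Returns None when scores never decrease; raises with <2 assessments.
    """
    if subscale not in SUBSCALES:
        raise ValueError(f"unknown subscale {subscale!r}")
    mine = sorted(assessments, key=lambda a: a.date)
    if len(mine) < 2:
        raise ValueError("first_drop needs at least 2 assessments")
    ref = mine[0].score(subscale)
    for prev, cur in zip(mine, mine[1:]):
        threshold = ref if baseline_relative else prev.score(subscale)
        if cur.score(subscale) < threshold:
            return FirstDrop(
                cur.participant_id,
                subscale,
                cur.date,
                threshold,
                cur.score(subscale),
                baseline_relative=baseline_relative,
            )
    return None


def lag_to_last_si(
    drop: FirstDrop,
    instances: Sequence[SiInstance],
    window: tuple[date, date],
) -> LagResult:
    """Days from the first drop to the last SI instance inside the PANSS
    reporting window (negative when the last SI preceded the drop)."""
    lo, hi = window
    in_window = [
        i
        for i in instances
        if i.participant_id == drop.participant_id and lo <= i.day <= hi
    ]
    if not in_window:
        raise ValueError(
            f"no SI instance for {drop.participant_id} within the PANSS window"
        )
    last = max(i.day for i in in_window)
    return LagResult(drop.participant_id, drop.subscale, (last - drop.drop_date).days)


def lag_summary(lags: Sequence[LagResult]) -> pd.DataFrame:
    """Cohort lag summary per subscale: mean/SD, median/IQR, range, n, and
    the number of participants with a negative lag (SI before the drop)."""
    if not lags:
        raise ValueError("no lags to summarise")
    rows = []
    for sub in SUBSCALES:
        vals = np.array([l.lag_days for l in lags if l.subscale == sub], dtype=float)
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "subscale": sub,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n_negative": int((vals < 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("subscale")


def compute_lags(
    assessments: Sequence[PanssAssessment],
    instances: Sequence[SiInstance],
    baseline_relative: bool = False,
) -> tuple[list[LagResult], pd.DataFrame]:
    """Per-participant, per-subscale lags with pairwise exclusion.

    The PANSS reporting window is first-to-last assessment per participant.
    Participants with no drop on a subscale, fewer than two assessments, or
    no in-window SI are excluded for that subscale with a logged reason,
    which is why each subscale can have a different n.
    """
    by_pid: dict[str, list[PanssAssessment]] = {}
    for a in assessments:
        by_pid.setdefault(a.participant_id, []).append(a)
    lags: list[LagResult] = []
    log_rows = []
    for pid, mine in sorted(by_pid.items()):
        mine = sorted(mine, key=lambda a: a.date)
        window = (mine[0].date, mine[-1].date)
        for sub in SUBSCALES:
            if len(mine) < 2:
                log_rows.append({"participant_id": pid, "subscale": sub, "reason": "insufficient_assessments"})
                continue
            drop = first_drop(mine, sub, baseline_relative=baseline_relative)
            if drop is None:
                log_rows.append({"participant_id": pid, "subscale": sub, "reason": "no_drop"})
                continue
            try:
                lags.append(lag_to_last_si(drop, instances, window))
            except ValueError:
                log_rows.append({"participant_id": pid, "subscale": sub, "reason": "no_in_window_si"})
    log = pd.DataFrame(log_rows, columns=["participant_id", "subscale", "reason"])
    return lags, log


def panss_assessment_summary(assessments: Sequence[PanssAssessment]) -> dict:
    """Distribution of assessment counts per participant (mean/SD/range/sum)."""
    counts: dict[str, int] = {}
    for a in assessments:
        counts[a.participant_id] = counts.get(a.participant_id, 0) + 1
    if not counts:
        return {"n_participants": 0, "sum": 0}
    vals = np.array(sorted(counts.values()), dtype=float)
    return {
        "n_participants": len(vals),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "min": int(vals.min()),
        "max": int(vals.max()),
        "sum": int(vals.sum()),
    }


def usage_panss_correlation(
    records: Sequence[SurveyRecord],
    assessments: Sequence[PanssAssessment],
) -> pd.DataFrame:
    """Pearson correlations between monthly survey usage and adjacent-month
    PANSS subscale scores.

    Two pairing directions per subscale: previous-month PANSS score vs the
    succeeding month's usage, and previous-month usage vs the succeeding
    month's PANSS score.  Observations are (participant, month) pairs pooled
    across the cohort; each cell reports r, the two-sided p, and n.
    Zero-variance cells are flagged undefined.
    """
    pids = sorted({r.participant_id for r in records})
    usage_by_pid = {p: monthly_usage(records, p) for p in pids}
    panss_rows = []
    for a in assessments:
        panss_rows.append(
            {
                "participant_id": a.participant_id,
                "month": pd.Period(a.date, "M"),
                **{s: a.score(s) for s in SUBSCALES},
            }
        )
    if not panss_rows:
        raise ValueError("no PANSS assessments")
    pdf = (
        pd.DataFrame(panss_rows)
        .groupby(["participant_id", "month"])[list(SUBSCALES)]
        .mean()
    )
    rows = []
    for sub in SUBSCALES:
        for direction in ("panss_then_usage", "usage_then_panss"):
            xs, ys = [], []
            for p in pids:
                if p not in pdf.index.get_level_values(0):
                    continue
                um = usage_by_pid[p]
                pm = pdf.loc[p][sub]
                for month in um.index:
                    if direction == "panss_then_usage":
                        prev = month - 1
                        if prev in pm.index:
                            xs.append(float(pm.loc[prev]))
                            ys.append(float(um.loc[month]))
                    else:
                        nxt = month + 1
                        if nxt in pm.index:
                            xs.append(float(um.loc[month]))
                            ys.append(float(pm.loc[nxt]))
            n = len(xs)
            if n < 3 or np.std(xs) == 0 or np.std(ys) == 0:
                rows.append(
                    {"subscale": sub, "direction": direction, "r": float("nan"),
                     "p": float("nan"), "n": n, "defined": False}
                )
                continue
            r, p_val = stats.pearsonr(xs, ys)
            rows.append(
                {"subscale": sub, "direction": direction, "r": float(r),
                 "p": float(p_val), "n": n, "defined": True}
            )
    return pd.DataFrame(rows).set_index(["subscale", "direction"])
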