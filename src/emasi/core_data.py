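"""Domain types and delimited-text I/O for daily EMA mood surveys and PANSS.

The analysis substrate is a per-participant calendar-day grid of categorical
suicidal-ideation (SI) states taken from item 9 of the PHQ-9 mood survey
(scores 0-3, with 0 the "resting" state).  This module defines the record
types, validates them, builds the daily grid, and reads/writes the CSV
dialects used throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing categorical SI state on the daily grid.
MISSING: int = -1

#: Legal observed SI states (PHQ-9 item-9 scores).
STATE_SPACE: tuple[int, ...] = (0, 1, 2, 3)

PANSS_RANGES: Mapping[str, tuple[int, int]] = {
    "positive": (7, 49),
    "negative": (7, 49),
    "general": (16, 112),
}

DEFAULT_EMA_COLUMNS: Mapping[str, str] = {
    "participant_id": "participant_id",
    "timestamp": "timestamp",
    **{f"item{i}": f"item{i}" for i in range(1, 10)},
}


class ConfigurationError(ValueError):
    """Raised when an input file or column mapping cannot satisfy a contract."""


class NoSiDataError(ValueError):
    """Raised when a participant has no usable item-9 observations."""


@dataclass(frozen=True)
class SurveyRecord:
    """One filled PHQ-9 mood survey at a timestamp.

    ``items`` is the ordered 9-tuple of item scores; ``None`` marks an item
    the participant left blank.  ``total`` is the 0-27 sum when all nine
    items are present, else ``None``.  Item 9 (``items[8]``) is the SI item.
    """

    participant_id: str
    timestamp: datetime
    items: tuple[int | None, ...]
    site: str | None = None

    def __post_init__(self) -> None:
        if len(self.items) != 9:
            raise ValueError(f"expected 9 item scores, got {len(self.items)}")
        for v in self.items:
            if v is not None and v not in STATE_SPACE:
                raise ValueError(f"item score {v!r} outside 0-3")

    @property
    def total(self) -> int | None:
        if any(v is None for v in self.items):
            return None
        return sum(self.items)  # type: ignore[arg-type]

    @property
    def si_score(self) -> int | None:
        """PHQ-9 item-9 score (the SI item), or None if blank."""
        return self.items[8]

    @property
    def day(self) -> date:
        return self.timestamp.date()


@dataclass(frozen=True)
class SiInstance:
    """A survey whose item-9 score met the SI cutoff."""

    participant_id: str
    timestamp: datetime
    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3):
            raise ValueError(f"SI instance score must be in 1-3, got {self.score}")

    @property
    def day(self) -> date:
        return self.timestamp.date()


@dataclass
class DailySeries:
    """Calendar-day grid of SI states for one participant.

    ``states[k]`` is the state on ``start_date + k days``: an observed score
    in {0,1,2,3} or :data:`MISSING`.  The grid is gap-free and is trimmed so
    that the first and last days carry an observed state.
    """

    participant_id: str
    start_date: date
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.ndim != 1 or len(self.states) == 0:
            raise ValueError("states must be a non-empty 1-D sequence")
        valid = set(STATE_SPACE) | {MISSING}
        bad = set(np.unique(self.states).tolist()) - valid
        if bad:
            raise ValueError(f"illegal states {sorted(bad)}")
        if self.states[0] == MISSING or self.states[-1] == MISSING:
            raise ValueError("first and last grid days must be observed")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def end_date(self) -> date:
        return self.start_date + timedelta(days=len(self.states) - 1)

    def date_of(self, index: int) -> date:
        return self.start_date + timedelta(days=int(index))

    @property
    def observed_mask(self) -> np.ndarray:
        return self.states != MISSING

    def copy(self) -> "DailySeries":
        return DailySeries(self.participant_id, self.start_date, self.states.copy())


@dataclass(frozen=True)
class PanssAssessment:
    """One monthly PANSS assessment (positive/negative 7-49, general 16-112)."""

    participant_id: str
    date: date
    positive: int
    negative: int
    general: int

    def __post_init__(self) -> None:
        for sub in ("positive", "negative", "general"):
            lo, hi = PANSS_RANGES[sub]
            v = getattr(self, sub)
            if not lo <= v <= hi:
                raise ValueError(f"PANSS {sub}={v} outside {lo}-{hi}")

    def score(self, subscale: str) -> int:
        if subscale not in PANSS_RANGES:
            raise ValueError(f"unknown subscale {subscale!r}")
        return getattr(self, subscale)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_item(cell: object) -> int | None:
    """Parse one item cell; anything unparseable or out of range is missing."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    try:
        v = int(float(cell))
    except (TypeError, ValueError):
        return None
    return v if v in STATE_SPACE else None


def read_ema_csv(
    path,
    columns: Mapping[str, str] | None = None,
) -> list[SurveyRecord]:
    """Read long-format EMA mood surveys (one row per filled survey).

    ``columns`` maps logical names (``participant_id``, ``timestamp``,
    ``item1`` .. ``item9``, optionally ``site``) to the file's header names,
    accommodating export variants.  Unparseable item cells become missing;
    rows without a participant id or a parseable timestamp are rejected and
    counted in the log.
    """
    cols = dict(DEFAULT_EMA_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype={cols["participant_id"]: str})
    if df.empty and df.columns.size == 0:
        return []
    mandatory = [cols["participant_id"], cols["timestamp"]] + [
        cols[f"item{i}"] for i in range(1, 10)
    ]
    absent = [c for c in mandatory if c not in df.columns]
    if absent:
        raise ConfigurationError(f"EMA file {path} lacks mandatory columns {absent}")

    site_col = cols.get("site")
    has_site = site_col is not None and site_col in df.columns

    records: list[SurveyRecord] = []
    n_rejected = 0
    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce")
    for i, row in df.iterrows():
        pid = row[cols["participant_id"]]
        t = ts.iloc[i] if isinstance(i, int) else ts.loc[i]
        if pd.isna(pid) or str(pid).strip() == "" or pd.isna(t):
            n_rejected += 1
            continue
        items = tuple(_parse_item(row[cols[f"item{k}"]]) for k in range(1, 10))
        site = str(row[site_col]) if has_site and not pd.isna(row[site_col]) else None
        records.append(
            SurveyRecord(str(pid), t.to_pydatetime(), items, site=site)
        )
    if n_rejected:
        logger.warning("read_ema_csv: rejected %d rows lacking id/timestamp", n_rejected)
    return records


def write_ema_csv(records: Iterable[SurveyRecord], path) -> None:
    rows = []
    for r in records:
        row = {"participant_id": r.participant_id, "timestamp": r.timestamp.isoformat()}
        if r.site is not None:
            row["site"] = r.site
        for k in range(9):
            row[f"item{k + 1}"] = "" if r.items[k] is None else r.items[k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panss_csv(path) -> list[PanssAssessment]:
    """Read monthly PANSS assessments, validating subscale ranges.

    Out-of-range rows are rejected with a warning; duplicate
    (participant, date) pairs raise.  Output is sorted by (participant, date).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    needed = ["participant_id", "date", "panss_positive", "panss_negative", "panss_general"]
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise ConfigurationError(f"PANSS file {path} lacks columns {absent}")
    out: list[PanssAssessment] = []
    n_rejected = 0
    for _, row in df.iterrows():
        try:
            a = PanssAssessment(
                str(row["participant_id"]),
                pd.Timestamp(row["date"]).date(),
                int(row["panss_positive"]),
                int(row["panss_negative"]),
                int(row["panss_general"]),
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("read_panss_csv: rejected row (%s)", exc)
            continue
        out.append(a)
    if n_rejected:
        logger.warning("read_panss_csv: rejected %d out-of-range rows", n_rejected)
    seen = set()
    for a in out:
        key = (a.participant_id, a.date)
        if key in seen:
            raise ConfigurationError(f"duplicate PANSS assessment for {key}")
        seen.add(key)
    return sorted(out, key=lambda a: (a.participant_id, a.date))


def write_panss_csv(assessments: Iterable[PanssAssessment], path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "date": a.date.isoformat(),
                "panss_positive": a.positive,
                "panss_negative": a.negative,
                "panss_general": a.general,
            }
            for a in assessments
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Daily grid construction
# ---------------------------------------------------------------------------

def build_daily_series(
    records: Sequence[SurveyRecord],
    participant_id: str,
    aggregation: str = "max",
) -> DailySeries:
    """Collapse a participant's surveys onto a calendar-day SI-state grid.

    Days with >=1 observed item-9 value take the day aggregate: ``"max"``
    (default; conservative for SI detection) or ``"first"`` (first survey of
    the day).  Days with no survey, or none with an item-9 value, are
    MISSING.  The grid spans first-to-last filled survey, then is trimmed to
    the first/last day with an observed state so the edges are never MISSING.
    """
    if aggregation not in ("max", "first"):
        raise ValueError("aggregation must be 'max' or 'first'")
    mine = sorted(
        (r for r in records if r.participant_id == participant_id),
        key=lambda r: r.timestamp,
    )
    by_day: dict[date, list[SurveyRecord]] = {}
    for r in mine:
        by_day.setdefault(r.day, []).append(r)
    day_state: dict[date, int] = {}
    for d, rs in by_day.items():
        scores = [r.si_score for r in rs if r.si_score is not None]
        if not scores:
            continue
        day_state[d] = max(scores) if aggregation == "max" else scores[0]
    if not day_state:
        raise NoSiDataError(f"participant {participant_id!r} has no observed item-9 data")
    first, last = min(day_state), max(day_state)
    n = (last - first).days + 1
    states = np.full(n, MISSING, dtype=np.int16)
    for d, s in day_state.items():
        states[(d - first).days] = s
    return DailySeries(participant_id, first, states)


def write_daily_series_csv(series_list: Sequence[DailySeries], path) -> None:
    """Long-format export: participant_id,date,si_state with NA for MISSING."""
    rows = []
    for s in series_list:
        for k, v in enumerate(s.states):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "date": s.date_of(k).isoformat(),
                    "si_state": "NA" if v == MISSING else int(v),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_daily_series_csv(path) -> list[DailySeries]:
    df = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False)
    out: list[DailySeries] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("date")
        days = [pd.Timestamp(d).date() for d in grp["date"]]
        start = days[0]
        n = (days[-1] - start).days + 1
        if n != len(days):
            raise ConfigurationError(f"daily series for {pid} has gaps in the day index")
        states = np.array(
            [MISSING if str(v) == "NA" else int(v) for v in grp["si_state"]],
            dtype=np.int16,
        )
        out.append(DailySeries(str(pid), start, states))
    return out
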