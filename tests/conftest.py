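from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from emasi import CohortConfig, DailySeries, SurveyRecord, simulate_cohort

START = date(2022, 1, 1)


def make_series(states, pid="p1", start=START) -> DailySeries:
    """Daily series from a list using None for missing days."""
    from emasi import MISSING

    arr = np.array([MISSING if s is None else s for s in states], dtype=np.int16)
    return DailySeries(pid, start, arr)


def make_record(pid, day_offset, item9, hour=9, items=None, start=START):
    """Survey with all items 0 except item 9 (None = blank)."""
    base = [0] * 9 if items is None else list(items)
    base[8] = item9
    ts = datetime.combine(start + timedelta(days=day_offset), datetime.min.time())
    ts = ts.replace(hour=hour)
    return SurveyRecord(pid, ts, tuple(base))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared across tests (fixed seed)."""
    cfg = CohortConfig(n_participants=6, follow_up_days=(120, 240), seed=20240917)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully observed cohort: every day surveyed, nothing masked."""
    cfg = CohortConfig(
        n_participants=6,
        follow_up_days=(120, 240),
        daily_report_prob=(1.0, 1.0),
        gap_burst_rate=0.0,
        item_miss_prob=0.0,
        seed=77,
    )
    return simulate_cohort(cfg)
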