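"""Multiple imputation for the categorical daily SI series.

Internal gaps of MISSING days are filled recursively from their edges: the
gap's outermost positions are imputed first (alternating left edge, right
edge) so each draw can condition on the nearest available neighbour on both
sides.  The conditional model is a multinomial over the state space
{0,1,2,3} given the nearest left available state, the nearest right observed
state, and the log of the distance to that right edge; it is fitted by
pooling every observed day across participants.  Repeating the fill ``m``
times with independent random substreams and averaging the downstream
episode statistics gives the pooled (fractional) estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import MISSING, STATE_SPACE, DailySeries
from .episodes import (
    DescriptiveRow,
    descriptive_stats,
    descriptive_table,
    segment_episodes,
    timescale_summary,
)

logger = logging.getLogger(__name__)

#: Additive smoothing pseudo-count applied before normalisation; the highest
#: SI scores are rare, so unsmoothed cells would often be empty.
SMOOTHING = 0.5


@dataclass
class MictModel:
    """Fitted conditional multinomial for gap imputation.

    ``coef_`` holds per-category multinomial-logit coefficients over the
    design (intercept, one-hot left state, one-hot right state, log right
    distance); when the logit fit is degenerate the model falls back to the
    additive-smoothed (left, right) probability table ``table_``.
    """

    states: tuple[int, ...]
    table_: np.ndarray  # shape (n_states, n_states, n_states): left x right -> p
    coef_: np.ndarray | None = None
    n_transitions: int = 0
    collapsed: dict[int, int] = field(default_factory=dict)
    used_fallback: bool = False

    def conditional(self, left: int, right: int, right_distance: int) -> np.ndarray:
        """P(state | left neighbour, right neighbour, distance to right)."""
        k = len(self.states)
        li = self.states.index(left)
        ri = self.states.index(right)
        if self.coef_ is None:
            return self.table_[li, ri]
        x = _design_row(li, ri, right_distance, k)
        # multinomial logit with category 0 as reference
        logits = np.concatenate([[0.0], x @ self.coef_.T])
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()


def _design_row(li: int, ri: int, dist: int, k: int) -> np.ndarray:
    x = np.zeros(1 + 2 * (k - 1) + 1)
    x[0] = 1.0
    if li > 0:
        x[li] = 1.0
    if ri > 0:
        x[(k - 1) + ri] = 1.0
    x[-1] = np.log(max(dist, 1))
    return x


def _training_rows(series_set: Sequence[DailySeries]) -> pd.DataFrame:
    """Observed days with an observed left neighbour and a following observed
    day: (left state, target state, right state, distance to right)."""
    rows = []
    for s in series_set:
        st = s.states
        obs = np.flatnonzero(st != MISSING)
        for a, b in zip(obs, obs[1:]):
            if b - a != 1:
                continue  # left neighbour must be adjacent, as during filling
            # nearest observed day strictly after b
            later = obs[obs > b]
            if len(later) == 0:
                continue
            rows.append(
                {
                    "left": int(st[a]),
                    "target": int(st[b]),
                    "right": int(st[later[0]]),
                    "dist": int(later[0] - b),
                }
            )
    return pd.DataFrame(rows, columns=["left", "target", "right", "dist"])


def fit_mict_model(
    series_set: Sequence[DailySeries],
    min_transitions: int = 10,
    use_logit: bool = True,
) -> MictModel:
    """Fit the conditional multinomial by pooling all observed transitions.

    States never observed anywhere are collapsed into the nearest lower
    observed category (recorded in ``collapsed``) so the model only predicts
    states with empirical support.  If the multinomial-logit fit fails to
    converge (e.g. complete separation in a sparse cohort) the model keeps
    the additive-smoothed probability table, which ignores distance.
    """
    df = _training_rows(series_set)
    if len(df) < min_transitions:
        raise ValueError(
            f"only {len(df)} observed transitions (< {min_transitions}); "
            "too little observed data to fit an imputation model — pool more "
            "participants or lower min_transitions"
        )
    observed_states = set()
    for s in series_set:
        observed_states |= set(s.states[s.states != MISSING].tolist())
    collapsed: dict[int, int] = {}
    for c in STATE_SPACE:
        if c not in observed_states:
            lower = [o for o in sorted(observed_states) if o < c]
            collapsed[c] = lower[-1] if lower else min(observed_states)
    states = tuple(sorted(observed_states))
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}

    table = np.full((k, k, k), SMOOTHING)
    for _, r in df.iterrows():
        table[idx[r["left"]], idx[r["right"]], idx[r["target"]]] += 1.0
    table /= table.sum(axis=2, keepdims=True)

    model = MictModel(
        states=states, table_=table, n_transitions=len(df), collapsed=collapsed
    )
    if k == 1:
        # single-category limit: probability 1 on the only observed state
        model.table_ = np.ones((1, 1, 1))
        return model
    if not use_logit:
        model.used_fallback = True
        return model
    try:
        import statsmodels.api as sm

        X = np.stack(
            [
                _design_row(idx[r["left"]], idx[r["right"]], r["dist"], k)
                for _, r in df.iterrows()
            ]
        )
        y = np.array([idx[r["target"]] for _, r in df.iterrows()])
        if len(np.unique(y)) < 2:
            raise ValueError("single observed target category")
        fit = sm.MNLogit(y, X).fit(method="lbfgs", maxiter=200, disp=False)
        coef = np.asarray(fit.params).T  # (k-1, n_features)
        if not np.all(np.isfinite(coef)) or np.abs(coef).max() > 30:
            raise ValueError("degenerate coefficients (separation)")
        model.coef_ = coef
    except Exception as exc:  # fall back to the smoothed table
        logger.warning("MICT logit fit failed (%s); using smoothed table", exc)
        model.used_fallback = True
    return model


def _map_state(v: int, model: MictModel) -> int:
    return model.collapsed.get(v, v)


def impute_series(
    series: DailySeries, model: MictModel, rng: np.random.Generator
) -> DailySeries:
    """Fill every internal gap edge-inward; observed values are untouched.

    Positions in a gap are drawn alternately from the left and right edges;
    each draw conditions on the nearest available (observed or already
    imputed) left neighbour, the nearest observed right state, and the
    distance to it.
    """
    st = series.states.copy()
    gaps = _find_gaps(st)
    for lo, hi in gaps:  # inclusive bounds of the MISSING run
        order = _edge_inward_order(lo, hi)
        for pos in order:
            # nearest available left neighbour (observed or already imputed)
            l = pos - 1
            while st[l] == MISSING:
                l -= 1
            left = int(st[l])
            # nearest available right neighbour (observed or already imputed)
            r = pos + 1
            while st[r] == MISSING:
                r += 1
            right = int(st[r])
            dist = r - pos
            p = model.conditional(
                _map_state(left, model), _map_state(right, model), dist
            )
            st[pos] = model.states[rng.choice(len(model.states), p=p)]
    return DailySeries(series.participant_id, series.start_date, st)


def _find_gaps(states: np.ndarray) -> list[tuple[int, int]]:
    gaps = []
    n = len(states)
    i = 0
    while i < n:
        if states[i] == MISSING:
            j = i
            while j < n and states[j] == MISSING:
                j += 1
            gaps.append((i, j - 1))
            i = j
        else:
            i += 1
    return gaps


def _edge_inward_order(lo: int, hi: int) -> list[int]:
    """Alternating left-edge, right-edge fill order: lo, hi, lo+1, hi-1, ..."""
    left, right = lo, hi
    order = []
    while left <= right:
        order.append(left)
        if right != left:
            order.append(right)
        left += 1
        right -= 1
    return order


@dataclass
class ImputationRun:
    """Results of m-fold multiple imputation over a cohort of daily series."""

    m: int
    seed: int
    completed: list[list[DailySeries]]  # completed[i] = cohort for imputation i
    per_imputation: pd.DataFrame  # one row per (imputation, statistic)
    pooled: pd.DataFrame  # simple mean across imputations
    excluded: dict[str, str] = field(default_factory=dict)


def multiply_impute(
    series_set: Sequence[DailySeries],
    model: MictModel,
    m: int = 10,
    seed: int = 0,
    cutoff: int = 1,
    bridge_missing: bool = True,
) -> ImputationRun:
    """Draw ``m`` completed cohorts from independent substreams and pool the
    timescale statistics by simple averaging (fractional pooled counts are
    expected).

    Participants whose observed instances cannot form any episode on the
    daily grid (no elevated day at all) are excluded from episode pooling
    with a logged reason.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    excluded: dict[str, str] = {}
    usable: list[DailySeries] = []
    for s in series_set:
        if segment_episodes(s, cutoff=cutoff, bridge_missing=bridge_missing):
            usable.append(s)
        else:
            excluded[s.participant_id] = "no observable episode on the daily grid"
            logger.info("excluding %s from imputation pooling: no episode", s.participant_id)
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(c) for c in ss.spawn(m)]
    completed: list[list[DailySeries]] = []
    rows = []
    for i in range(m):
        cohort = [impute_series(s, model, streams[i]) for s in usable]
        completed.append(cohort)
        eps = {s.participant_id: segment_episodes(s, cutoff, bridge_missing) for s in cohort}
        summ = timescale_summary(eps)
        for stat, r in summ.iterrows():
            rows.append({"imputation": i, "statistic": stat, **r.to_dict()})
    per_imp = pd.DataFrame(rows)
    pooled = per_imp.drop(columns="imputation").groupby("statistic").mean()
    return ImputationRun(
        m=m, seed=seed, completed=completed, per_imputation=per_imp,
        pooled=pooled, excluded=excluded,
    )


def post_imputation_descriptives(run: ImputationRun) -> pd.DataFrame:
    """Instance-level descriptives recomputed on each completed cohort and
    averaged across imputations.

    On a completed grid an SI instance is a day with elevated state (survey
    multiplicity is not recoverable after imputation), so successive gaps are
    >= 1 day.
    """
    from .core_data import SiInstance
    from datetime import datetime, time

    tables = []
    for cohort in run.completed:
        rows = []
        for s in cohort:
            insts = [
                SiInstance(
                    s.participant_id,
                    datetime.combine(s.date_of(k), time(12, 0)),
                    int(v),
                )
                for k, v in enumerate(s.states)
                if v >= 1
            ]
            rows.append(descriptive_stats(s, insts))
        tables.append(descriptive_table(rows))
    stacked = pd.concat(tables)
    return stacked.groupby(level=0).mean().loc[tables[0].index]
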