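"""End-to-end orchestration: from EMA + PANSS CSVs to the report bundle.

Stage order follows the analysis it implements: reporting-period and usage
summary first, then instance-level descriptives, then episode timescale
statistics (pre- and post-imputation), then PANSS alignment.  Every number
written to the bundle comes from the underlying module operations — the
pipeline does no computation of its own beyond presentation rounding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .core_data import (
    DailySeries,
    NoSiDataError,
    SiInstance,
    SurveyRecord,
    read_ema_csv,
    read_panss_csv,
    write_daily_series_csv,
)
from .episodes import (
    descriptive_stats,
    descriptive_table,
    detect_si_instances,
    monthly_grid,
    segment_episodes,
    select_analytic_sample,
    survey_summary,
    time_slot_distribution,
    timescale_summary,
    usage_rate,
)
from .mict import fit_mict_model, multiply_impute, post_imputation_descriptives
from .panss import compute_lags, lag_summary, panss_assessment_summary, usage_panss_correlation
from .core_data import build_daily_series

logger = logging.getLogger(__name__)


class EmptySampleError(RuntimeError):
    """No participants survive the analytic-sample filter."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, for the manifest."""

    ema_path: str
    panss_path: str | None = None
    out_dir: str = "report"
    si_cutoff: int = 1
    min_si_instances: int = 2
    usage_cutoff_by_site: dict = field(
        default_factory=lambda: {"Bhopal": 0.40, "Bengaluru": 0.20}
    )
    bridge_missing: bool = True
    aggregation: str = "max"
    impute: bool = True
    m: int = 10
    seed: int = 1234
    baseline_relative_drop: bool = False

    def digest(self) -> str:
        # out_dir does not affect the bundle's content, only its location
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def spearman_phq_si(records: Sequence[SurveyRecord]) -> dict:
    """Spearman rho between PHQ-9 total and item-9 score over all surveys
    with both present, plus the binary variant (total >= 10 vs item-9 >= 1,
    a phi coefficient)."""
    pairs = [(r.total, r.si_score) for r in records if r.total is not None]
    if len(pairs) < 3:
        raise ValueError("need >= 3 surveys with complete totals")
    tot = np.array([p[0] for p in pairs], dtype=float)
    si = np.array([p[1] for p in pairs], dtype=float)
    out: dict = {"n": len(pairs)}
    if np.std(tot) == 0 or np.std(si) == 0:
        out.update(rho=float("nan"), p=float("nan"), defined=False)
    else:
        rho, p = stats.spearmanr(tot, si)
        out.update(rho=float(rho), p=float(p), defined=True)
    b_tot = (tot >= 10).astype(float)
    b_si = (si >= 1).astype(float)
    if np.std(b_tot) == 0 or np.std(b_si) == 0:
        out.update(rho_binary=float("nan"), p_binary=float("nan"), binary_defined=False)
    else:
        r_b, p_b = stats.pearsonr(b_tot, b_si)
        out.update(rho_binary=float(r_b), p_binary=float(p_b), binary_defined=True)
    return out


def _day_level_instances(series_list: Sequence[DailySeries], cutoff: int) -> list[SiInstance]:
    out = []
    for s in series_list:
        for k, v in enumerate(s.states):
            if v >= cutoff:
                out.append(
                    SiInstance(s.participant_id, datetime.combine(s.date_of(k), time(12, 0)), int(v))
                )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    failure is re-raised as :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "emasi",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "tables": [],
        "notes": [],
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.round(4).to_csv(path)
        manifest["tables"].append(f"{name}.csv")

    stage = "read_inputs"
    try:
        records = read_ema_csv(config.ema_path)
        assessments = read_panss_csv(config.panss_path) if config.panss_path else []
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "analytic_sample"
    try:
        site_map = {
            r.participant_id: (r.site or "default") for r in records
        }
        cutoffs = dict(config.usage_cutoff_by_site)
        if "default" in set(site_map.values()) and "default" not in cutoffs:
            cutoffs["default"] = 0.0
        kept, exclusion_log = select_analytic_sample(
            records,
            site_map,
            min_si_instances=config.min_si_instances,
            usage_cutoff_by_site=cutoffs,
            cutoff=config.si_cutoff,
        )
        emit("exclusion_log", exclusion_log.set_index("participant_id") if len(exclusion_log) else exclusion_log)
        if not kept:
            raise EmptySampleError("no participants retained after filtering")
        records = [r for r in records if r.participant_id in set(kept)]
        assessments = [a for a in assessments if a.participant_id in set(kept)]
    except EmptySampleError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "usage_summary"
    try:
        summ = survey_summary(records)
        usage = pd.DataFrame(
            [
                {"participant_id": p, "usage_rate": usage_rate(records, p), "site": site_map[p]}
                for p in kept
            ]
        ).set_index("participant_id")
        emit("usage_rates", usage)
        (out / "survey_summary.json").write_text(json.dumps(summ, indent=2))
        manifest["tables"].append("survey_summary.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "daily_series"
    try:
        series_list = []
        for p in kept:
            try:
                series_list.append(build_daily_series(records, p, aggregation=config.aggregation))
            except NoSiDataError:
                manifest["notes"].append(f"{p}: no observed item-9 data, dropped from grid")
        write_daily_series_csv(series_list, out / "daily_series.csv")
        manifest["tables"].append("daily_series.csv")
        instances = detect_si_instances(records, cutoff=config.si_cutoff)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "descriptives"
    try:
        rows = [descriptive_stats(s, instances) for s in series_list]
        emit("table_descriptives_observed", descriptive_table(rows))
        sp = spearman_phq_si(records)
        (out / "spearman_phq_si.json").write_text(json.dumps(sp, indent=2))
        manifest["tables"].append("spearman_phq_si.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "timescale"
    try:
        eps = {
            s.participant_id: segment_episodes(s, config.si_cutoff, config.bridge_missing)
            for s in series_list
        }
        emit("table_timescale_observed", timescale_summary(eps))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "monthly_grid"
    try:
        emit("si_monthly_grid", monthly_grid(instances, records, kept))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "time_slots"
    try:
        emit("time_slot_distribution", time_slot_distribution(records, instances))
    except ValueError as exc:
        manifest["notes"].append(f"time_slot_distribution skipped: {exc}")

    run = None
    if config.impute:
        stage = "imputation"
        try:
            model = fit_mict_model(series_list)
            run = multiply_impute(
                series_list, model, m=config.m, seed=config.seed,
                cutoff=config.si_cutoff, bridge_missing=config.bridge_missing,
            )
            emit("table_timescale_imputed", run.pooled)
            emit("table_descriptives_imputed", post_imputation_descriptives(run))
            manifest["imputation"] = {
                "m": run.m,
                "seed": run.seed,
                "model_fallback": model.used_fallback,
                "collapsed_categories": {str(k): v for k, v in model.collapsed.items()},
                "excluded": run.excluded,
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if assessments:
        stage = "panss"
        try:
            (out / "panss_summary.json").write_text(
                json.dumps(panss_assessment_summary(assessments), indent=2)
            )
            manifest["tables"].append("panss_summary.json")
            lags, lag_log = compute_lags(
                assessments, instances, baseline_relative=config.baseline_relative_drop
            )
            if lags:
                emit("table_lags_observed", lag_summary(lags))
            emit("lag_exclusion_log", lag_log.set_index("participant_id") if len(lag_log) else lag_log)
            corr = usage_panss_correlation(records, assessments)
            emit("usage_panss_correlation", corr)
            if run is not None:
                tables = []
                for cohort in run.completed:
                    day_inst = _day_level_instances(cohort, config.si_cutoff)
                    l_i, _ = compute_lags(
                        assessments, day_inst, baseline_relative=config.baseline_relative_drop
                    )
                    if l_i:
                        tables.append(lag_summary(l_i))
                if tables:
                    pooled_lags = pd.concat(tables).groupby(level=0).mean().loc[tables[0].index]
                    emit("table_lags_imputed", pooled_lags)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
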