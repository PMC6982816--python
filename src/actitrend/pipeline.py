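"""End-to-end glue: raw stream -> day records -> daily metrics -> trend ->
predictions -> evaluation.

Each stage is a pure function over the previous stage's output, mirroring
the file-based processing flow: every intermediate can be written to CSV and
the pipeline restarted from it.
"""
from __future__ import annotations

import logging
from datetime import date
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import activity, evaluate, ingest, predictor, synthgen, trend
from .config import RunConfig
from .records import ClinicalEvent, DayRecord, Prediction

logger = logging.getLogger(__name__)


def build_day_record(
    block, patient_id: str, config: Optional[RunConfig] = None
) -> DayRecord:
    """Non-wear detection + minute AI + validity for one day block."""
    config = config or RunConfig()
    wear = ingest.detect_nonwear(block, config.nonwear)
    minute_ai = activity.day_minute_ai(block, config.ai)
    minute_ai = np.where(wear, minute_ai, np.nan)
    record = DayRecord(
        patient_id=patient_id,
        day_index=block.day_index,
        window_start=block.window_start,
        minute_ai=minute_ai,
        wear_mask=wear,
        is_valid=True,  # provisional; set below from the wear mask
        partial=block.partial,
    )
    record.is_valid = ingest.is_valid_day(record, config.validity)
    return record


def process_stream(
    stream: pd.DataFrame,
    patient_id: str,
    discharge_date: date,
    config: Optional[RunConfig] = None,
) -> List[DayRecord]:
    """Raw sample stream -> per-day records."""
    config = config or RunConfig()
    blocks = ingest.slice_days(stream, discharge_date)
    days = [build_day_record(b, patient_id, config) for b in blocks]
    logger.info(
        "%s: %d day blocks, %d valid days",
        patient_id, len(days), sum(d.is_valid for d in days),
    )
    return days


def daily_metrics(
    days: Sequence[DayRecord], config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Per-day aggregate metrics for one patient's day records."""
    config = config or RunConfig()
    by_index = {d.day_index: d for d in days}
    out = []
    for d in sorted(by_index):
        day = by_index[d]
        if not day.is_valid:
            continue
        prev = by_index.get(d - 1)
        out.append(
            activity.compute_daily_metrics(
                day,
                day_prev=prev,
                ri_params=config.ri,
                sleep_params=config.sleep,
            )
        )
    return activity.metrics_frame(out)


def run_minute_cohort(
    cohort: synthgen.Cohort,
    profile="proposed",
    config: Optional[RunConfig] = None,
) -> Dict:
    """Run the pipeline on a minute-level synthetic cohort.

    Returns a dict with the pooled metrics frame, trend table, predictions
    and the evaluation report against the cohort's event log.
    """
    config = config or RunConfig()
    frames = []
    for scen in cohort.scenarios:
        matrix, _ = synthgen.generate_minute_ai(scen)
        days = synthgen.day_records_from_matrix(scen.patient_id, matrix, config.validity)
        frames.append(daily_metrics(days, config))
    metrics = pd.concat(frames, ignore_index=True) if frames else activity.metrics_frame([])
    trends = trend.build_trend_table(metrics, params=config.trend)
    preds = predictor.raise_predictions(trends, profile, merge=config.merge)
    report = evaluate.evaluate(preds, cohort.events, horizon=config.horizon)
    return {
        "metrics": metrics,
        "trend": trends,
        "predictions": preds,
        "report": report,
    }


def predictions_from_frame(df: pd.DataFrame) -> List[Prediction]:
    return [
        Prediction(
            patient_id=str(r.patient_id),
            day_index=int(r.day_index),
            profile=str(r.profile),
            episode_id=int(r.episode_id),
        )
        for r in df.itertuples(index=False)
    ]


def events_from_frame(df: pd.DataFrame) -> List[ClinicalEvent]:
    return [
        ClinicalEvent(
            patient_id=str(r.patient_id),
            day_index=int(r.day_index),
            kind=str(r.kind),
        )
        for r in df.itertuples(index=False)
    ]
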