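"""Quality-of-Activity (QoA) trend statistics.

The daily score is QoA = Total_AI * (1 + RI): the amount of activity scaled
by how regular it was relative to the day before ("act it right" matters as
much as "act it more").  Because every derived statistic is a percentage
change of the patient against themselves, the trend is invariant to the
patient's absolute activity scale.

Per-day statistics, all carried on the x100 percent scale:

* dQoA_i   = (QoA_i - QoA_{i-1}) / QoA_{i-1} * 100
* WQoA_i   = 0.4 QoA_i + 0.3 QoA_{i-1} + 0.2 QoA_{i-2} + 0.1 QoA_{i-3}
* dWQoA_i  = (WQoA_i - WQoA_{i-1}) / WQoA_{i-1} * 100
* sum_dQoA_i = sum of dQoA over days i-6 .. i (7-day cumulative change)

Missing-data propagation: a statistic exists only when every input exists,
and the day-over-day differences require calendar-consecutive valid days —
gaps suppress the statistics rather than bridging them.
"""
from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import ExperimentalTrendParams, TrendParams
from .records import DailyMetrics, TrendPoint, is_missing

NAN = float("nan")

#: Fixed weights of the 4-day weighted running average (most recent first).
WQOA_WEIGHTS = (0.4, 0.3, 0.2, 0.1)
#: Length of the cumulative percent-change window.
SUM_WINDOW = 7


def qoa(total_ai: float, ri: float) -> float:
    """QoA = Total_AI * (1 + RI); missing when RI is missing."""
    if is_missing(total_ai) or is_missing(ri):
        return NAN
    return float(total_ai) * (1.0 + float(ri))


def delta_qoa(qoa_i: float, qoa_prev: float) -> float:
    """Day-over-day percent change of QoA, on the x100 scale."""
    return _pct_change(qoa_i, qoa_prev)


def wqoa(qoa_i: float, qoa_im1: float, qoa_im2: float, qoa_im3: float,
         weights: Sequence[float] = WQOA_WEIGHTS) -> float:
    """Weighted running average of the last four daily QoA values."""
    vals = (qoa_i, qoa_im1, qoa_im2, qoa_im3)
    if any(is_missing(v) for v in vals):
        return NAN
    return float(sum(w * v for w, v in zip(weights, vals)))


def delta_wqoa(wqoa_i: float, wqoa_prev: float) -> float:
    """Day-over-day percent change of WQoA, on the x100 scale."""
    return _pct_change(wqoa_i, wqoa_prev)


def sum_delta_qoa(deltas: Sequence[float]) -> float:
    """Sum of the 7 most recent daily dQoA values (ending at day i)."""
    if len(deltas) != SUM_WINDOW or any(is_missing(d) for d in deltas):
        return NAN
    return float(sum(deltas))


def _pct_change(cur: float, prev: float) -> float:
    if is_missing(cur) or is_missing(prev) or prev == 0:
        return NAN
    return (float(cur) - float(prev)) / float(prev) * 100.0


def build_trend_series(
    metrics: Union[Sequence[DailyMetrics], pd.DataFrame],
    params: Optional[TrendParams] = None,
    experimental: Optional[ExperimentalTrendParams] = None,
) -> pd.DataFrame:
    """Apply the trend model to one patient's daily metrics.

    Accepts the DailyMetrics sequence (or equivalent frame with columns
    patient_id, day_index, total_ai, ri, valid) sorted by day_index and
    returns one row per day from the first to the last valid day with
    columns qoa, delta_qoa, wqoa, delta_wqoa, sum_delta_qoa (NaN = missing).
    Invalid or absent days yield all-NaN rows and break consecutiveness for
    every day-over-day statistic.
    """
    params = params or TrendParams()
    exp = experimental or ExperimentalTrendParams()
    weights = tuple(exp.wqoa_weights)
    window = int(exp.sum_window)

    if isinstance(metrics, pd.DataFrame):
        df = metrics
        rows = list(df.itertuples(index=False))
        patient_id = str(df["patient_id"].iloc[0]) if len(df) else ""
        per_day = {
            int(r.day_index): (float(r.total_ai), float(r.ri) if not pd.isna(r.ri) else NAN)
            for r in rows
            if bool(r.valid)
        }
    else:
        patient_id = metrics[0].patient_id if metrics else ""
        per_day = {m.day_index: (m.total_ai, m.ri) for m in metrics if m.valid}

    if not per_day:
        return trend_frame([])

    days = sorted(per_day)
    q: Dict[int, float] = {}
    for d in days:
        total_ai, ri = per_day[d]
        if is_missing(ri) and params.ri_default_zero:
            ri = 0.0
        q[d] = qoa(total_ai, ri)

    def qat(d: int) -> float:
        return q.get(d, NAN)

    points: List[TrendPoint] = []
    dq: Dict[int, float] = {}
    w: Dict[int, float] = {}
    for d in range(days[0], days[-1] + 1):
        dq[d] = delta_qoa(qat(d), qat(d - 1))
        w[d] = wqoa(qat(d), qat(d - 1), qat(d - 2), qat(d - 3), weights)
        dw = delta_wqoa(w[d], w.get(d - 1, NAN))
        sd = sum_delta_qoa([dq.get(d - j, NAN) for j in range(window)]) if window == SUM_WINDOW \
            else (NAN if any(is_missing(dq.get(d - j, NAN)) for j in range(window))
                  else float(sum(dq[d - j] for j in range(window))))
        points.append(
            TrendPoint(
                patient_id=patient_id,
                day_index=d,
                qoa=qat(d),
                delta_qoa=dq[d],
                wqoa=w[d],
                delta_wqoa=dw,
                sum_delta_qoa=sd,
            )
        )
    return trend_frame(points)


def trend_frame(points: Sequence[TrendPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series([p.patient_id for p in points], dtype=str),
            "day_index": pd.Series([p.day_index for p in points], dtype=int),
            "qoa": [p.qoa for p in points],
            "delta_qoa": [p.delta_qoa for p in points],
            "wqoa": [p.wqoa for p in points],
            "delta_wqoa": [p.delta_wqoa for p in points],
            "sum_delta_qoa": [p.sum_delta_qoa for p in points],
        }
    )


def build_trend_table(metrics: pd.DataFrame, **kw) -> pd.DataFrame:
    """Multi-patient wrapper: apply :func:`build_trend_series` per patient."""
    out = [
        build_trend_series(g.sort_values("day_index"), **kw)
        for _, g in metrics.groupby("patient_id", sort=True)
    ]
    if not out:
        return trend_frame([])
    return pd.concat(out, ignore_index=True)
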