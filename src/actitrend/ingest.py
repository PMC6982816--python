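"""Raw accelerometer ingestion: CSV reading, noon-to-noon day slicing,
non-wear detection and the valid-day rule.

The devices record tri-axial acceleration at a nominal 20 Hz; a full
noon-to-noon day therefore holds 24*60*60*20 = 1,728,000 samples.  Days are
clock constructs: the window for day ``d`` runs from 12:00 on calendar day
``discharge_date + d`` to 12:00 the next day, and daylight-saving shifts are
absorbed by mapping samples onto the 1440-minute grid by their local clock
labels.
"""
from __future__ import annotations

import logging
from datetime import date, datetime, time, timedelta
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import CsvDialect, NonwearParams, ValidityParams
from .records import MINUTES_PER_DAY, DayBlock, DayRecord

logger = logging.getLogger(__name__)

#: Slack when deciding whether a day block covers its full window: a block
#: whose first/last sample is within this many seconds of the window edge is
#: still "full" (the last 20 Hz sample of a full day sits 0.05 s before the
#: boundary).
_EDGE_TOLERANCE_S = 1.0


class SchemaError(ValueError):
    """Raised when an input file does not match the expected schema."""


def read_raw_csv(path, dialect: Optional[CsvDialect] = None) -> pd.DataFrame:
    """Read a raw accelerometer CSV into a (timestamp, x, y, z) frame.

    Rows must be in timestamp order; depending on ``dialect.out_of_order``
    unordered rows are either rejected (``"error"``) or sorted
    (``"sort"``).  An empty file yields an empty stream with a warning.
    """
    dialect = dialect or CsvDialect()
    cols = [dialect.timestamp_col, dialect.x_col, dialect.y_col, dialect.z_col]
    try:
        df = pd.read_csv(path, decimal=dialect.decimal, usecols=cols)
    except ValueError as exc:
        raise SchemaError(f"{path}: missing required column(s) {cols}: {exc}") from exc
    if df.empty:
        logger.warning("%s: empty raw file, returning empty stream", path)
        return pd.DataFrame(columns=["timestamp", "x", "y", "z"])

    ts = pd.to_datetime(
        df[dialect.timestamp_col], format=dialect.timestamp_format, errors="coerce"
    )
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise SchemaError(
            f"{path}: unparseable timestamp at data row {row}: "
            f"{df[dialect.timestamp_col].iloc[row]!r}"
        )
    out = pd.DataFrame(
        {
            "timestamp": ts,
            "x": df[dialect.x_col].astype(float),
            "y": df[dialect.y_col].astype(float),
            "z": df[dialect.z_col].astype(float),
        }
    )
    if not ts.is_monotonic_increasing:
        if dialect.out_of_order == "sort":
            out = out.sort_values("timestamp", kind="stable", ignore_index=True)
        else:
            row = int(np.argmax(np.diff(ts.to_numpy()) < np.timedelta64(0)))
            raise SchemaError(f"{path}: out-of-order timestamp at data row {row + 1}")
    logger.info("%s: read %d samples", path, len(out))
    return out


def slice_days(stream: pd.DataFrame, discharge_date: date) -> List[DayBlock]:
    """Slice a sample stream into noon-to-noon day blocks.

    Day ``d`` covers [12:00 of discharge_date+d, 12:00 of the next day).
    Blocks at the stream edges that do not cover their whole window are
    flagged partial.  Every sample lands in exactly one block.
    """
    if stream.empty:
        raise ValueError("cannot slice an empty stream")
    ts = stream["timestamp"]
    noon0 = datetime.combine(discharge_date, time(12, 0))
    first, last = ts.iloc[0], ts.iloc[-1]
    first_idx = (first - noon0) // timedelta(days=1)
    last_idx = (last - noon0) // timedelta(days=1)

    blocks: List[DayBlock] = []
    for d in range(int(first_idx), int(last_idx) + 1):
        w0 = noon0 + timedelta(days=d)
        w1 = w0 + timedelta(days=1)
        lo = int(ts.searchsorted(w0, side="left"))
        hi = int(ts.searchsorted(w1, side="left"))
        if hi == lo:
            continue
        block = stream.iloc[lo:hi]
        partial = (
            (block["timestamp"].iloc[0] - w0).total_seconds() > _EDGE_TOLERANCE_S
            or (w1 - block["timestamp"].iloc[-1]).total_seconds() > _EDGE_TOLERANCE_S
        )
        blocks.append(DayBlock(day_index=d, window_start=w0, samples=block, partial=partial))
    return blocks


def _per_minute_stats(block: DayBlock):
    """Sample count, per-axis sd and range for each of the 1440 minutes."""
    ts = block.samples["timestamp"]
    minute = ((ts - block.window_start) // timedelta(minutes=1)).to_numpy().astype(np.int64)
    minute = np.clip(minute, 0, MINUTES_PER_DAY - 1)
    xyz = block.samples[["x", "y", "z"]].to_numpy(dtype=float)

    n = np.bincount(minute, minlength=MINUTES_PER_DAY).astype(float)
    sd = np.zeros((MINUTES_PER_DAY, 3))
    rng = np.zeros((MINUTES_PER_DAY, 3))
    for a in range(3):
        v = xyz[:, a]
        s = np.bincount(minute, weights=v, minlength=MINUTES_PER_DAY)
        ss = np.bincount(minute, weights=v * v, minlength=MINUTES_PER_DAY)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), 0.0)
            var = np.where(n > 0, ss / np.maximum(n, 1) - mean**2, 0.0)
        sd[:, a] = np.sqrt(np.maximum(var, 0.0))
        hi = np.full(MINUTES_PER_DAY, -np.inf)
        lo = np.full(MINUTES_PER_DAY, np.inf)
        np.maximum.at(hi, minute, v)
        np.minimum.at(lo, minute, v)
        rng[:, a] = np.where(n > 0, hi - lo, 0.0)
    return n.astype(int), sd, rng


def detect_nonwear(block: DayBlock, params: Optional[NonwearParams] = None) -> np.ndarray:
    """Return the 1440-long wear mask (True = worn) for one day block.

    Off-wrist periods show as sustained near-zero movement: minutes where
    every axis is both low-variance and low-range are stationary candidates,
    and candidates inside runs of at least ``params.min_run`` consecutive
    minutes are non-wear.  Minutes with no samples are always non-wear.
    """
    params = params or NonwearParams()
    n, sd, rng = _per_minute_stats(block)
    stationary = (sd < params.sd_threshold).all(axis=1) & (
        rng < params.range_threshold
    ).all(axis=1)
    candidate = stationary | (n == 0)
    nonwear = _runs_at_least(candidate, params.min_run)
    nonwear |= n == 0
    return ~nonwear


def _runs_at_least(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only True entries belonging to runs of length >= min_run."""
    out = np.zeros_like(mask)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        if stop - start >= min_run:
            out[start:stop] = True
    return out


def nonwear_minutes(wear_mask: np.ndarray, count_mode: str = "cumulative") -> int:
    """Non-wear total under the chosen counting rule: cumulative sum of
    off-wrist minutes, or the longest consecutive off-wrist run."""
    off = ~np.asarray(wear_mask, dtype=bool)
    if count_mode == "cumulative":
        return int(off.sum())
    if count_mode == "consecutive":
        idx = np.flatnonzero(np.diff(np.concatenate(([0], off.view(np.int8), [0]))))
        runs = idx[1::2] - idx[::2]
        return int(runs.max()) if runs.size else 0
    raise ValueError(f"unknown count_mode: {count_mode!r}")


def is_valid_day(day: DayRecord, params: Optional[ValidityParams] = None) -> bool:
    """Valid-day rule: off-wrist for more than 60 minutes (strictly) makes
    the day invalid, as does a partial first/last window."""
    params = params or ValidityParams()
    if day.partial:
        return False
    return nonwear_minutes(day.wear_mask, params.count_mode) <= params.max_nonwear_minutes


def day_summary_frame(days: Sequence[DayRecord]) -> pd.DataFrame:
    """Day-summary table: one row per day with validity bookkeeping."""
    return pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in days],
            "day_index": [d.day_index for d in days],
            "valid": [bool(d.is_valid) for d in days],
            "nonwear_minutes": [d.nonwear_minutes for d in days],
            "partial": [bool(d.partial) for d in days],
        }
    )


def minute_ai_frame(days: Sequence[DayRecord]) -> pd.DataFrame:
    """Long-format per-minute table `patient_id,day_index,minute_of_day,ai,worn`."""
    frames = []
    for d in days:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": d.patient_id,
                    "day_index": d.day_index,
                    "minute_of_day": np.arange(MINUTES_PER_DAY),
                    "ai": d.minute_ai,
                    "worn": d.wear_mask,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
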