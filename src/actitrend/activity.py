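"""Minute-wise activity indices, sleep detection, and daily aggregates.

The activity index (AI) condenses raw tri-axial acceleration into one
non-negative number per minute; the regularity index (RI) measures how
similar today's minute-AI pattern is to yesterday's.  Both are strategy
points — the defaults below (a noise-corrected variance AI and a Pearson RI)
are standard actigraphy constructions and alternative definitions can be
plugged in through the registries at the bottom of the module.
"""
from __future__ import annotations

from datetime import timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AiParams, RiParams, SleepParams
from .records import MINUTES_PER_DAY, DailyMetrics, DayBlock, DayRecord

_SECONDS_PER_DAY = 86400


def epoch_activity_index(variances: Sequence[float], noise_sd: float = 0.0) -> float:
    """AI of one epoch from its per-axis sample variances:
    sqrt(max(0, mean(variances) - noise_sd^2))."""
    v = float(np.mean(variances)) - noise_sd**2
    return float(np.sqrt(max(0.0, v)))


def compute_minute_ai(
    xyz: np.ndarray,
    seconds_into_minute: np.ndarray,
    params: Optional[AiParams] = None,
) -> float:
    """Minute AI from the raw samples of a single minute.

    The minute is partitioned into one-second epochs; each epoch with at
    least two samples contributes its noise-corrected root-mean-variance and
    the minute AI is the sum of the 60 epoch values.  A minute with no
    samples is missing (NaN), not zero.
    """
    params = params or AiParams()
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[0] == 0:
        return float("nan")
    epoch = (np.asarray(seconds_into_minute, float) // params.epoch_seconds).astype(int)
    total = 0.0
    for e in np.unique(epoch):
        sel = xyz[epoch == e]
        if sel.shape[0] < 2:
            continue
        total += epoch_activity_index(sel.var(axis=0, ddof=1), params.noise_sd)
    return total


def day_minute_ai(block: DayBlock, params: Optional[AiParams] = None) -> np.ndarray:
    """Vectorized minute-AI vector (length 1440) for one day block.

    Equivalent to calling :func:`compute_minute_ai` minute by minute but
    computed with bincount accumulators over the day's ~1.7 M samples.
    """
    params = params or AiParams()
    ts = block.samples["timestamp"]
    off = ((ts - block.window_start) / timedelta(seconds=1)).to_numpy()
    n_epochs = int(_SECONDS_PER_DAY / params.epoch_seconds)
    epochs_per_min = n_epochs // MINUTES_PER_DAY
    epoch = np.clip((off // params.epoch_seconds).astype(np.int64), 0, n_epochs - 1)
    xyz = block.samples[["x", "y", "z"]].to_numpy(dtype=float)

    n = np.bincount(epoch, minlength=n_epochs).astype(float)
    var_sum = np.zeros(n_epochs)
    for a in range(3):
        v = xyz[:, a]
        s = np.bincount(epoch, weights=v, minlength=n_epochs)
        ss = np.bincount(epoch, weights=v * v, minlength=n_epochs)
        with np.errstate(invalid="ignore", divide="ignore"):
            # unbiased (ddof=1) per-epoch variance; epochs with <2 samples
            # carry no variance information and contribute 0
            var = np.where(n >= 2, (ss - s * s / np.maximum(n, 1)) / np.maximum(n - 1, 1), 0.0)
        var_sum += np.maximum(var, 0.0)
    ai_epoch = np.where(
        n >= 2, np.sqrt(np.maximum(var_sum / 3.0 - params.noise_sd**2, 0.0)), 0.0
    )
    minute_ai = ai_epoch.reshape(MINUTES_PER_DAY, epochs_per_min).sum(axis=1)
    minute_n = n.reshape(MINUTES_PER_DAY, epochs_per_min).sum(axis=1)
    return np.where(minute_n > 0, minute_ai, np.nan)


def compute_ri(
    day_i: DayRecord, day_prev: DayRecord, params: Optional[RiParams] = None
) -> float:
    """Regularity index of a day against the day before.

    Default model: Pearson correlation between the two 1440-long minute-AI
    vectors restricted to mutually worn minutes.  Missing when fewer than
    ``params.min_mutual_minutes`` minutes are mutually worn or either
    restricted vector is constant.
    """
    params = params or RiParams()
    mask = (
        day_i.wear_mask
        & day_prev.wear_mask
        & np.isfinite(day_i.minute_ai)
        & np.isfinite(day_prev.minute_ai)
    )
    if mask.sum() < params.min_mutual_minutes:
        return float("nan")
    a = day_i.minute_ai[mask]
    b = day_prev.minute_ai[mask]
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def detect_sleep(
    day: DayRecord, params: Optional[SleepParams] = None
) -> List[Tuple[int, int]]:
    """Detect sleep bouts as half-open minute intervals [start, stop).

    Minutes whose centered moving-average AI is below the threshold form
    candidate bouts; bouts separated by gaps shorter than ``merge_gap`` are
    merged, and only bouts of at least ``min_bout`` minutes are kept.
    Missing minutes count as zero activity for smoothing (an off-wrist
    device is still), so the rule is deterministic on any day.
    """
    params = params or SleepParams()
    ai = np.nan_to_num(day.minute_ai, nan=0.0)
    kernel = np.ones(params.smooth_window) / params.smooth_window
    smooth = np.convolve(ai, kernel, mode="same")
    low = smooth < params.threshold

    bouts: List[Tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        if bouts and start - bouts[-1][1] < params.merge_gap:
            bouts[-1] = (bouts[-1][0], int(stop))
        else:
            bouts.append((int(start), int(stop)))
    return [(s, e) for s, e in bouts if e - s >= params.min_bout]


def sleep_mask(bouts: Sequence[Tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    for s, e in bouts:
        mask[s:e] = True
    return mask


def compute_daily_metrics(
    day: DayRecord,
    day_prev: Optional[DayRecord] = None,
    sleep_bouts: Optional[Sequence[Tuple[int, int]]] = None,
    ri_params: Optional[RiParams] = None,
    sleep_params: Optional[SleepParams] = None,
) -> DailyMetrics:
    """Per-day aggregates: Total_AI, RI, sleep duration and the awake/sleep
    AI-per-hour rates.

    Total_AI sums the minute AIs over worn minutes (missing minutes inside a
    valid day contribute 0 — at most an hour, so the distortion is bounded —
    while RI excludes them so the correlation is not biased by zero-fill).
    RI is missing when the previous calendar day is absent or invalid.
    """
    if sleep_bouts is None:
        sleep_bouts = detect_sleep(day, sleep_params)
    asleep = sleep_mask(sleep_bouts)
    worn = day.wear_mask & np.isfinite(day.minute_ai)
    ai = np.nan_to_num(day.minute_ai, nan=0.0)

    total_ai = float(ai[worn].sum())
    ri = float("nan")
    if day_prev is not None and day_prev.is_valid and day.is_valid:
        if day_prev.day_index == day.day_index - 1:
            ri = compute_ri(day, day_prev, ri_params)

    sleep_worn = worn & asleep
    awake_worn = worn & ~asleep
    n_sleep, n_awake = int(sleep_worn.sum()), int(awake_worn.sum())
    awake_rate = float(ai[awake_worn].sum() / (n_awake / 60.0)) if n_awake else float("nan")
    sleep_rate = float(ai[sleep_worn].sum() / (n_sleep / 60.0)) if n_sleep else float("nan")

    return DailyMetrics(
        patient_id=day.patient_id,
        day_index=day.day_index,
        total_ai=total_ai,
        ri=ri,
        sleep_minutes=n_sleep,
        awake_ai_per_hour=awake_rate,
        sleep_ai_per_hour=sleep_rate,
        valid=day.is_valid,
    )


def metrics_frame(metrics: Sequence[DailyMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in metrics],
            "day_index": [m.day_index for m in metrics],
            "total_ai": [m.total_ai for m in metrics],
            "ri": [m.ri for m in metrics],
            "sleep_minutes": [m.sleep_minutes for m in metrics],
            "awake_ai_per_hour": [m.awake_ai_per_hour for m in metrics],
            "sleep_ai_per_hour": [m.sleep_ai_per_hour for m in metrics],
            "valid": [m.valid for m in metrics],
        }
    )


#: Pluggable model registries.  The published pipeline defines AI and RI
#: elsewhere; these defaults are the package's documented stand-ins and new
#: models can be registered under a name for the --ai-model/--ri-model flags.
AI_MODELS = {"variance": day_minute_ai}
RI_MODELS = {"pearson": compute_ri}
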