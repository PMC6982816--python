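"""Rule-based 30-day readmission alerting on the QoA trend series.

An alert is raised on a day when the recent trend shows sustained decline:
enough days of WQoA dropping within the trailing 7-day window AND a 7-day
cumulative QoA loss beyond a percent threshold.  Three named criteria
profiles are shipped:

* ``proposed``  — more than 4 of the past 7 days with dWQoA dropping, and
  sum_dQoA below -30.
* ``loosened``  — more than 3 drop-days and sum_dQoA below -25.
* ``stricter``  — the proposed rules plus three consecutive days of dWQoA
  dropping ending on the alert day.

"Dropping" means dWQoA_i < 0 (the weighted QoA decreased from the day
before).  Missing statistics never satisfy a criterion, so no alert can
arise during the 7-day warm-up after discharge or inside the shadow of a
data gap.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import math

import numpy as np
import pandas as pd

from .records import Prediction, is_missing

WINDOW = 7
#: Predictions start only once a full trailing window can exist.
WARMUP_DAYS = 7


@dataclass(frozen=True)
class CriteriaProfile:
    """A named alerting rule set.

    ``min_drop_days`` uses strict "more than" semantics: the count of
    dropping days in the window must exceed it.  ``sum_dqoa_threshold`` is
    on the x100 percent scale and the cumulative change must fall strictly
    below it.  ``require_consecutive_drops`` = n > 0 additionally requires
    dWQoA < 0 on the alert day and the n-1 days before it.
    """

    name: str
    min_drop_days: int
    sum_dqoa_threshold: float
    require_consecutive_drops: int = 0
    window: int = WINDOW

    def __post_init__(self) -> None:
        if not (0 < self.min_drop_days <= self.window):
            raise ValueError("min_drop_days must be in (0, window]")
        if not self.sum_dqoa_threshold < 0:
            raise ValueError("sum_dqoa_threshold must be negative")


PROFILES: Dict[str, CriteriaProfile] = {
    "proposed": CriteriaProfile("proposed", min_drop_days=4, sum_dqoa_threshold=-30.0),
    "loosened": CriteriaProfile("loosened", min_drop_days=3, sum_dqoa_threshold=-25.0),
    "stricter": CriteriaProfile(
        "stricter", min_drop_days=4, sum_dqoa_threshold=-30.0, require_consecutive_drops=3
    ),
}


def get_profile(name_or_profile) -> CriteriaProfile:
    if isinstance(name_or_profile, CriteriaProfile):
        return name_or_profile
    try:
        return PROFILES[str(name_or_profile)]
    except KeyError:
        raise KeyError(
            f"unknown profile {name_or_profile!r}; known: {sorted(PROFILES)}"
        ) from None


def drop_days_in_window(delta_wqoa_window: Sequence[float]) -> int:
    """Count dropping days (dWQoA < 0) in a 7-slot window ending at day i.

    Missing values count as non-dropping.
    """
    return sum(1 for v in delta_wqoa_window if not is_missing(v) and v < 0)


def criteria_met(
    day_index: int,
    delta_wqoa_window: Sequence[float],
    sum_delta_qoa_i: float,
    profile: CriteriaProfile,
) -> bool:
    """Evaluate the alert rule on one day.

    ``delta_wqoa_window`` holds the dWQoA values of days i-6 .. i in
    chronological order.  Both criteria must hold; a missing cumulative
    statistic (or missing consecutive-drop days) means no alert.
    """
    if day_index < WARMUP_DAYS:
        return False
    if drop_days_in_window(delta_wqoa_window) <= profile.min_drop_days:
        return False
    if is_missing(sum_delta_qoa_i) or not sum_delta_qoa_i < profile.sum_dqoa_threshold:
        return False
    n = profile.require_consecutive_drops
    if n > 0:
        recent = delta_wqoa_window[-n:]
        if len(recent) < n or any(is_missing(v) or not v < 0 for v in recent):
            return False
    return True


def qualifying_days(trend: pd.DataFrame, profile) -> List[int]:
    """All days of one patient's trend series on which the criteria hold."""
    profile = get_profile(profile)
    dw = dict(zip(trend["day_index"].astype(int), trend["delta_wqoa"].astype(float)))
    sd = dict(zip(trend["day_index"].astype(int), trend["sum_delta_qoa"].astype(float)))
    out = []
    for d in sorted(dw):
        window = [dw.get(d - j, float("nan")) for j in range(profile.window - 1, -1, -1)]
        if criteria_met(d, window, sd.get(d, float("nan")), profile):
            out.append(d)
    return out


def raise_predictions(
    trend: pd.DataFrame, profile="proposed", merge: bool = True
) -> List[Prediction]:
    """Scan a trend table (one or many patients) and raise alerts.

    With ``merge=True`` (default) a maximal run of consecutive qualifying
    days yields a single prediction anchored at the run's first day — a
    sustained decline is one alert episode, not one per day.  With
    ``merge=False`` every qualifying day emits its own prediction (all days
    of one run share an episode_id either way).
    """
    profile = get_profile(profile)
    preds: List[Prediction] = []
    if trend.empty:
        return preds
    for patient_id, g in trend.groupby("patient_id", sort=True):
        days = qualifying_days(g, profile)
        episode = -1
        prev = None
        for d in days:
            new_run = prev is None or d != prev + 1
            if new_run:
                episode += 1
            if new_run or not merge:
                preds.append(
                    Prediction(
                        patient_id=str(patient_id),
                        day_index=d,
                        profile=profile.name,
                        episode_id=episode,
                    )
                )
            prev = d
    return preds


def predictions_frame(preds: Sequence[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series([p.patient_id for p in preds], dtype=str),
            "day_index": pd.Series([p.day_index for p in preds], dtype=int),
            "profile": pd.Series([p.profile for p in preds], dtype=str),
            "episode_id": pd.Series([p.episode_id for p in preds], dtype=int),
        }
    )
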