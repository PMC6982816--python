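"""Core record types shared across the pipeline.

A deployment is processed as a sequence of noon-to-noon days ("day 0" starts
at 12:00 on the discharge date).  Each day carries a 1440-slot minute grid:
minute-wise activity indices (AI), a wear mask from non-wear detection, and a
validity flag from the >60-minute non-wear rule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np

MINUTES_PER_DAY = 1440

#: Clinical event kinds.  Emergency-room visits ("ER") and rehospitalizations
#: ("RH") are the endpoints predictions are scored against; routine
#: outpatient-department visits ("OPD") are annotations only.
EVENT_KINDS = ("ER", "RH", "OPD")
ENDPOINT_KINDS = frozenset({"ER", "RH"})


@dataclass
class DayBlock:
    """Raw samples falling inside one noon-to-noon window."""

    day_index: int
    window_start: datetime
    samples: "object"  # pandas.DataFrame with columns timestamp, x, y, z
    partial: bool

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class DayRecord:
    """One noon-to-noon day on the 1440-minute grid."""

    patient_id: str
    day_index: int
    window_start: Optional[datetime]
    minute_ai: np.ndarray  # float, NaN where missing
    wear_mask: np.ndarray  # bool
    is_valid: bool
    partial: bool = False

    def __post_init__(self) -> None:
        self.minute_ai = np.asarray(self.minute_ai, dtype=float)
        self.wear_mask = np.asarray(self.wear_mask, dtype=bool)
        if self.minute_ai.shape != (MINUTES_PER_DAY,):
            raise ValueError("minute_ai must have exactly 1440 entries")
        if self.wear_mask.shape != (MINUTES_PER_DAY,):
            raise ValueError("wear_mask must have exactly 1440 entries")

    @property
    def nonwear_minutes(self) -> int:
        return int((~self.wear_mask).sum())


@dataclass
class DailyMetrics:
    """Per-valid-day aggregates feeding the trend model."""

    patient_id: str
    day_index: int
    total_ai: float
    ri: float  # NaN when undefined (first valid day, post-gap, degenerate)
    sleep_minutes: int
    awake_ai_per_hour: float
    sleep_ai_per_hour: float
    valid: bool = True


@dataclass
class TrendPoint:
    """Daily quality-of-activity trend statistics.

    All percentage quantities are carried on the x100 scale (a 20% drop is
    -20.0).  NaN marks a statistic whose inputs are not all available.
    """

    patient_id: str
    day_index: int
    qoa: float
    delta_qoa: float
    wqoa: float
    delta_wqoa: float
    sum_delta_qoa: float


@dataclass
class Prediction:
    """A readmission alert raised on a given day under a criteria profile."""

    patient_id: str
    day_index: int
    profile: str
    episode_id: int


@dataclass
class ClinicalEvent:
    patient_id: str
    day_index: int
    kind: str  # one of EVENT_KINDS

    def __post_init__(self) -> None:
        kind = normalize_event_kind(self.kind)
        if kind is None:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        self.kind = kind

    @property
    def is_endpoint(self) -> bool:
        return self.kind in ENDPOINT_KINDS


def normalize_event_kind(kind: str) -> Optional[str]:
    k = str(kind).strip().upper()
    aliases = {
        "ER": "ER",
        "EMERGENCY": "ER",
        "RH": "RH",
        "REHOSPITALIZATION": "RH",
        "REHOSP": "RH",
        "READMISSION": "RH",
        "OPD": "OPD",
        "OUTPATIENT": "OPD",
    }
    return aliases.get(k)


def is_missing(x: float) -> bool:
    """True for None or NaN."""
    return x is None or (isinstance(x, float) and math.isnan(x))
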