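"""Configuration objects for every pipeline stage.

All parameters are plain dataclasses so a full run configuration can be
serialized to YAML and echoed into output directories for provenance.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml


@dataclass
class CsvDialect:
    """Column/format mapping for raw accelerometer CSV exports.

    Defaults match a GeneActiv-style export converted to CSV: one row per
    sample, ISO-8601 timestamps, axes in units of g.
    """

    timestamp_col: str = "timestamp"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str = "z"
    timestamp_format: Optional[str] = None  # None -> flexible ISO parsing
    decimal: str = "."
    #: "error" rejects out-of-order rows, "sort" reorders them.
    out_of_order: str = "error"


@dataclass
class NonwearParams:
    """Stationary-run heuristic for off-wrist detection.

    A minute is a stationary candidate when every axis has standard
    deviation below ``sd_threshold`` and peak-to-peak range below
    ``range_threshold`` (both in g).  Candidates only count as non-wear
    inside runs of at least ``min_run`` consecutive minutes; minutes with no
    samples at all are always non-wear.
    """

    min_run: int = 30  # minutes
    sd_threshold: float = 0.013  # g
    range_threshold: float = 0.05  # g


@dataclass
class ValidityParams:
    """The valid-day rule: a day is invalid when the device was off-wrist
    for more than ``max_nonwear_minutes`` (strictly greater), counted
    cumulatively by default, or by the longest consecutive run when
    ``count_mode`` is "consecutive".  Partial first/last days are invalid.
    """

    max_nonwear_minutes: int = 60
    count_mode: str = "cumulative"  # or "consecutive"


@dataclass
class AiParams:
    """Variance-based minute activity index.

    The minute is split into one-second epochs; each epoch contributes
    sqrt(max(0, mean-over-axes(variance - noise_sd^2))) and the minute AI is
    the sum of its 60 epoch values.  ``noise_sd`` (g) removes the device
    noise floor; 0 disables the correction.
    """

    noise_sd: float = 0.0  # g
    epoch_seconds: float = 1.0


@dataclass
class RiParams:
    """Day-to-day regularity index: Pearson correlation of consecutive
    days' minute-AI vectors over mutually worn minutes."""

    min_mutual_minutes: int = 720


@dataclass
class SleepParams:
    """Threshold-bout sleep detection on the minute-AI series.

    Minutes whose centered ``smooth_window``-minute moving-average AI falls
    below ``threshold`` form candidate bouts; bouts separated by gaps
    shorter than ``merge_gap`` minutes are merged and only bouts of at least
    ``min_bout`` minutes are kept.
    """

    threshold: float = 2.0  # AI units
    smooth_window: int = 11  # minutes, centered
    merge_gap: int = 20  # minutes
    min_bout: int = 60  # minutes


@dataclass
class TrendParams:
    """Trend-model options.

    ``ri_default_zero`` substitutes RI=0 on days where RI is undefined so a
    QoA still exists there (off by default: the quality score has no
    regularity term to fall back on).  The weighted-average weights and the
    7-day summation window are part of the published model; they are only
    overridable through the ``experimental`` namespace for sensitivity
    studies.
    """

    ri_default_zero: bool = False


@dataclass
class ExperimentalTrendParams:
    wqoa_weights: tuple = (0.4, 0.3, 0.2, 0.1)
    sum_window: int = 7


@dataclass
class RunConfig:
    """Full pipeline configuration; serializable and echoed into outputs."""

    dialect: CsvDialect = field(default_factory=CsvDialect)
    nonwear: NonwearParams = field(default_factory=NonwearParams)
    validity: ValidityParams = field(default_factory=ValidityParams)
    ai: AiParams = field(default_factory=AiParams)
    ri: RiParams = field(default_factory=RiParams)
    sleep: SleepParams = field(default_factory=SleepParams)
    trend: TrendParams = field(default_factory=TrendParams)
    profile: str = "proposed"
    horizon: int = 30  # days
    merge: bool = True
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        sub = {
            "dialect": CsvDialect,
            "nonwear": NonwearParams,
            "validity": ValidityParams,
            "ai": AiParams,
            "ri": RiParams,
            "sleep": SleepParams,
            "trend": TrendParams,
        }
        for f in fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name in sub and isinstance(val, dict):
                kwargs[f.name] = sub[f.name](**val)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)
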