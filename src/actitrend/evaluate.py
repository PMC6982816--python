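"""Prediction-vs-event evaluation under the 30-day rule.

A prediction raised on day d is a true positive when an ER visit or
rehospitalization follows within the next 30 days (d < e <= d+30), otherwise
a false positive.  An event on day e is a false negative when no prediction
preceded it within 30 days (no d with e-30 <= d < e).  Several predictions
may be credited to the same event — counting is prediction-level for TP/FP
and event-level for FN, so TP + FN need not equal the number of events.

There is no true-negative count: "no alert and no event" days are not
enumerable in this design, so specificity, negative predictive value and
fall-out are deliberately never computed.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .records import ClinicalEvent, Prediction

HORIZON = 30  # days


@dataclass
class EvaluationReport:
    """Pooled confusion counts and derived percentages.

    Percentages are exact rationals internally; the float fields are their
    values on the 0-100 scale (NaN when undefined).
    """

    tp: int
    fp: int
    fn: int

    @property
    def n_predictions(self) -> int:
        return self.tp + self.fp

    def _pct(self, num: int, den: int) -> Optional[Fraction]:
        if den == 0:
            return None
        return Fraction(100 * num, den)

    @property
    def sensitivity_exact(self) -> Optional[Fraction]:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def precision_exact(self) -> Optional[Fraction]:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def miss_rate_exact(self) -> Optional[Fraction]:
        return self._pct(self.fn, self.tp + self.fn)

    @property
    def false_discovery_rate_exact(self) -> Optional[Fraction]:
        return self._pct(self.fp, self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        return _as_float(self.sensitivity_exact)

    @property
    def precision(self) -> float:
        return _as_float(self.precision_exact)

    @property
    def miss_rate(self) -> float:
        return _as_float(self.miss_rate_exact)

    @property
    def false_discovery_rate(self) -> float:
        return _as_float(self.false_discovery_rate_exact)

    def rounded(self, ndigits: int = 2) -> dict:
        """Reporting view: percentages rounded half-up at ``ndigits``."""
        out = {"tp": self.tp, "fp": self.fp, "fn": self.fn}
        for name in ("sensitivity", "precision", "miss_rate", "false_discovery_rate"):
            exact = getattr(self, f"{name}_exact")
            out[name] = None if exact is None else round_half_up(exact, ndigits)
        return out


def _as_float(x: Optional[Fraction]) -> float:
    return float("nan") if x is None else float(x)


def round_half_up(x, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Fraction(x) * 10**ndigits
    n = q.numerator
    d = q.denominator
    # floor(q + 1/2) for positive values, mirrored for negative
    if n >= 0:
        r = (2 * n + d) // (2 * d)
    else:
        r = -((-2 * n + d) // (2 * d))
    return r / 10**ndigits


def compute_metrics(tp: int, fp: int, fn: int) -> EvaluationReport:
    """Confusion counts -> evaluation metrics.

    sensitivity = 100*TP/(TP+FN); precision = 100*TP/(TP+FP);
    miss_rate = 100 - sensitivity; false_discovery_rate = 100 - precision.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    return EvaluationReport(tp=int(tp), fp=int(fp), fn=int(fn))


def classify_predictions(
    preds: Sequence[Prediction],
    events: Sequence[ClinicalEvent],
    horizon: int = HORIZON,
) -> pd.DataFrame:
    """Label every prediction TP/FP under the 30-day rule.

    Adds an ``opd_within_horizon`` annotation: whether a routine outpatient
    visit fell in the window (a documented source of false positives when
    the physician adjusts treatment), without ever reclassifying the label.
    """
    endpoint = [(e.patient_id, e.day_index) for e in events if e.is_endpoint]
    opd = [(e.patient_id, e.day_index) for e in events if e.kind == "OPD"]
    rows = []
    for p in preds:
        hit = any(
            pid == p.patient_id and p.day_index < e <= p.day_index + horizon
            for pid, e in endpoint
        )
        has_opd = any(
            pid == p.patient_id and p.day_index < e <= p.day_index + horizon
            for pid, e in opd
        )
        rows.append(
            {
                "patient_id": p.patient_id,
                "day_index": p.day_index,
                "profile": p.profile,
                "episode_id": p.episode_id,
                "label": "TP" if hit else "FP",
                "opd_within_horizon": has_opd,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "day_index", "profile", "episode_id", "label",
            "opd_within_horizon",
        ],
    )


def find_unpredicted_events(
    preds: Sequence[Prediction],
    events: Sequence[ClinicalEvent],
    horizon: int = HORIZON,
) -> List[ClinicalEvent]:
    """ER/RH events with no prediction in the 30 days before them (FN)."""
    out = []
    for e in events:
        if not e.is_endpoint:
            continue
        predicted = any(
            p.patient_id == e.patient_id
            and e.day_index - horizon <= p.day_index < e.day_index
            for p in preds
        )
        if not predicted:
            out.append(e)
    return out


def evaluate(
    preds: Sequence[Prediction],
    events: Sequence[ClinicalEvent],
    horizon: int = HORIZON,
) -> EvaluationReport:
    """Pooled evaluation of a prediction set against an event log."""
    labels = classify_predictions(preds, events, horizon)
    tp = int((labels["label"] == "TP").sum()) if len(labels) else 0
    fp = int((labels["label"] == "FP").sum()) if len(labels) else 0
    fn = len(find_unpredicted_events(preds, events, horizon))
    return compute_metrics(tp, fp, fn)


def patient_summary(
    preds: Sequence[Prediction],
    events: Sequence[ClinicalEvent],
    horizon: int = HORIZON,
) -> pd.DataFrame:
    """Per-patient summary table with a pooled Total row.

    Columns: actual ER/RH events, predictions made, truly/falsely predicted,
    and events not predicted — the shape clinicians review patient by
    patient.
    """
    labels = classify_predictions(preds, events, horizon)
    fns = find_unpredicted_events(preds, events, horizon)
    patients = sorted(
        {p.patient_id for p in preds} | {e.patient_id for e in events}
    )
    rows = []
    for pid in patients:
        sub = labels[labels["patient_id"] == pid] if len(labels) else labels
        rows.append(
            {
                "patient_id": pid,
                "actual_events": sum(
                    1 for e in events if e.patient_id == pid and e.is_endpoint
                ),
                "predicted": int(len(sub)),
                "truly_predicted": int((sub["label"] == "TP").sum()) if len(sub) else 0,
                "falsely_predicted": int((sub["label"] == "FP").sum()) if len(sub) else 0,
                "not_predicted": sum(1 for e in fns if e.patient_id == pid),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "actual_events", "predicted", "truly_predicted",
            "falsely_predicted", "not_predicted",
        ],
    )
    total = df.drop(columns="patient_id").sum()
    total["patient_id"] = "Total"
    return pd.concat([df, total.to_frame().T[df.columns]], ignore_index=True)


def metrics_table(reports: dict, ndigits: int = 2) -> pd.DataFrame:
    """Profile-comparison table from {profile_name: EvaluationReport}."""
    rows = []
    for name, rep in reports.items():
        r = rep.rounded(ndigits)
        r["profile"] = name
        rows.append(r)
    return pd.DataFrame(
        rows,
        columns=["profile", "tp", "fp", "fn", "sensitivity", "precision",
                 "miss_rate", "false_discovery_rate"],
    )
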