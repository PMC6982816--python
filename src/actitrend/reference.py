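"""Published reference counts from the original clinical evaluation.

The model behind this package was developed on a 16-patient COPD cohort
monitored after hospital discharge (21 ER-visit/rehospitalization events
over 1761 valid days).  The raw recordings are not public, but the study's
printed prediction/event confusion counts are, and they let the metric
arithmetic be recomputed and cross-checked exactly.  This module embeds
those counts as data.
"""
from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

from .evaluate import EvaluationReport, compute_metrics, metrics_table

#: Per-patient reference summary: (actual ER/RH events, predictions made,
#: truly predicted, falsely predicted, events not predicted), under the
#: proposed criteria.  Patient ids are anonymized ordinals.
REFERENCE_PATIENT_ROWS: Tuple[Tuple[str, int, int, int, int, int], ...] = (
    ("1", 0, 3, 0, 3, 0),
    ("2", 2, 1, 1, 0, 1),
    ("3", 1, 2, 2, 0, 0),
    ("4", 0, 4, 0, 4, 0),
    ("5", 0, 1, 0, 1, 0),
    ("6", 0, 0, 0, 0, 0),
    ("7", 0, 0, 0, 0, 0),
    ("8", 0, 0, 0, 0, 0),
    ("9", 3, 7, 1, 6, 2),
    ("10", 1, 3, 0, 3, 1),
    ("11", 0, 0, 0, 0, 0),
    ("12", 3, 5, 3, 2, 1),
    ("13", 5, 7, 6, 1, 3),
    ("14", 0, 3, 0, 3, 0),
    ("15", 0, 4, 0, 4, 0),
    ("16", 6, 5, 4, 1, 2),
)

#: Pooled confusion counts (TP, FP, FN) per criteria profile.
REFERENCE_COUNTS: Dict[str, Tuple[int, int, int]] = {
    "loosened": (24, 42, 9),
    "proposed": (17, 28, 10),
    "stricter": (9, 13, 15),
}


def reference_patient_table() -> pd.DataFrame:
    """The per-patient reference summary with its pooled Total row."""
    df = pd.DataFrame(
        REFERENCE_PATIENT_ROWS,
        columns=[
            "patient_id", "actual_events", "predicted", "truly_predicted",
            "falsely_predicted", "not_predicted",
        ],
    )
    total = df.drop(columns="patient_id").sum()
    total["patient_id"] = "Total"
    return pd.concat([df, total.to_frame().T[df.columns]], ignore_index=True)


def reference_reports() -> Dict[str, EvaluationReport]:
    """Recompute the evaluation metrics from the reference counts."""
    return {name: compute_metrics(*counts) for name, counts in REFERENCE_COUNTS.items()}


def reference_metrics_table(ndigits: int = 2) -> pd.DataFrame:
    """Profile-comparison metrics recomputed from the reference counts."""
    return metrics_table(reference_reports(), ndigits=ndigits)
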