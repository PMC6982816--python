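import numpy as np
import pytest

from actitrend.records import MINUTES_PER_DAY, DayRecord


def make_day(
    ai,
    patient_id="p",
    day_index=0,
    wear=None,
    valid=True,
    partial=False,
):
    """Build a DayRecord from a minute-AI vector (scalar broadcasts)."""
    ai = np.broadcast_to(np.asarray(ai, dtype=float), (MINUTES_PER_DAY,)).copy()
    if wear is None:
        wear = np.isfinite(ai)
    return DayRecord(
        patient_id=patient_id,
        day_index=day_index,
        window_start=None,
        minute_ai=ai,
        wear_mask=np.asarray(wear, dtype=bool),
        is_valid=valid,
        partial=partial,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
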