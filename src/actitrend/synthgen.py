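"""Synthetic actigraphy cohorts with known ground truth.

No real patient recordings ship with this package, so every end-to-end test
runs on simulated patients.  The generator emulates the data regime of a
post-discharge wrist-actigraphy deployment:

* a circadian minute-AI template (day-high / night-low) scaled by a
  per-patient amplitude, with multiplicative lognormal minute noise;
* day-to-day irregularity as a random circular time shift of the template —
  small when the patient keeps a regular routine, growing when regularity
  deteriorates;
* non-wear gaps (off-wrist periods) as missing minutes;
* clinical events (ER visits / rehospitalizations), a configurable fraction
  of which are preceded by a gradual deterioration window: exponential decay
  of the daytime activity amplitude and/or exponential growth of the
  time-warp jitter (falling day-to-day regularity) — the remainder strike
  abruptly with no warning in the signal.

Worn sleep is modelled with a small but non-zero activity floor (wrist
micro-movement), which is what distinguishes it from an off-wrist device
lying still; deterioration decays the activity above that floor, not the
floor itself.

Everything is deterministic given the scenario seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import MINUTES_PER_DAY, ClinicalEvent, DayRecord
from .config import ValidityParams
from .ingest import nonwear_minutes

SAMPLE_RATE_HZ = 20
#: Upper bound on the deterioration time-warp jitter (minutes): beyond a
#: quarter-day shift consecutive days are essentially uncorrelated.
_MAX_JITTER_MIN = 360.0


@dataclass(frozen=True)
class Deterioration:
    """A pre-event decline window.

    From ``onset_days_before`` days before ``event_day`` up to the event,
    the daytime amplitude is multiplied by exp(-amplitude_decay_rate * t)
    and the day-shift jitter grows as exp(+regularity_decay_rate * t), with
    t = days since onset (1-based).  Rates are per day.
    """

    event_day: int
    onset_days_before: int = 21
    amplitude_decay_rate: float = 0.08
    regularity_decay_rate: float = 0.15


@dataclass
class PatientScenario:
    """Everything needed to generate one synthetic patient."""

    patient_id: str
    n_days: int
    base_amplitude: float = 10.0  # daytime minute-AI scale
    night_floor: float = 1.0  # worn-sleep minute-AI floor
    noise_sigma: float = 0.15  # lognormal sigma of minute noise
    jitter_sd: float = 5.0  # baseline day-shift sd, minutes
    circadian_profile: Optional[np.ndarray] = None  # 1440 template in [0,1]
    nonwear_gaps: Sequence[Tuple[int, int, int]] = ()  # (day, start_min, length)
    events: Sequence[Tuple[int, str]] = ()  # (day, kind)
    deterioration: Sequence[Deterioration] = ()
    seed: int = 0


def default_circadian_profile() -> np.ndarray:
    """Activity template over the noon-to-noon grid (minute 0 = 12:00).

    Active from ~07:00 to ~22:00 with raised-cosine ramps into a quiescent
    night (23:00-06:30); values in [0, 1].
    """
    m = np.arange(MINUTES_PER_DAY)
    profile = np.zeros(MINUTES_PER_DAY)
    # clock minute-of-day, window starts at noon
    clock = (m + 720) % MINUTES_PER_DAY

    def ramp(x):  # smooth 0->1 on [0, 1]
        return 0.5 * (1 - np.cos(np.pi * np.clip(x, 0, 1)))

    evening = ramp((23 * 60 - clock) / 60.0)  # fall 22:00 -> 23:00
    morning = ramp((clock - 6.5 * 60) / 60.0)  # rise 06:30 -> 07:30
    profile = np.where(clock >= 12 * 60, evening, morning)
    # mild mid-day modulation so the profile is not flat (helps correlation
    # be informative within the active period)
    profile = profile * (0.85 + 0.15 * np.sin(2 * np.pi * clock / MINUTES_PER_DAY) ** 2)
    return profile


def _deterioration_t(day: int, det: Deterioration) -> int:
    """Days into the onset window (0 when outside it)."""
    onset = det.event_day - det.onset_days_before
    if onset <= day < det.event_day:
        return day - onset + 1
    return 0


def generate_minute_ai(scenario: PatientScenario) -> Tuple[np.ndarray, Dict]:
    """Generate the per-day minute-AI matrix and its ground-truth log.

    Returns ``(matrix, truth)`` where ``matrix`` is (n_days, 1440) with NaN
    in non-wear gaps, and ``truth`` records the per-day amplitude factor,
    jitter sd, applied shift, and the planted gaps.
    """
    rng = np.random.default_rng(scenario.seed)
    profile = (
        np.asarray(scenario.circadian_profile, float)
        if scenario.circadian_profile is not None
        else default_circadian_profile()
    )
    if profile.shape != (MINUTES_PER_DAY,):
        raise ValueError("circadian_profile must have 1440 entries")

    n = scenario.n_days
    amp = np.ones(n)
    jit = np.full(n, float(scenario.jitter_sd))
    for det in scenario.deterioration:
        for d in range(n):
            t = _deterioration_t(d, det)
            if t > 0:
                amp[d] *= np.exp(-det.amplitude_decay_rate * t)
                jit[d] = min(
                    jit[d] * np.exp(det.regularity_decay_rate * t), _MAX_JITTER_MIN
                )

    shifts = np.rint(rng.normal(0.0, jit)).astype(int)
    matrix = np.empty((n, MINUTES_PER_DAY))
    for d in range(n):
        shifted = np.roll(profile, shifts[d])
        noise = np.exp(scenario.noise_sigma * rng.standard_normal(MINUTES_PER_DAY))
        matrix[d] = (scenario.night_floor + scenario.base_amplitude * amp[d] * shifted) * noise

    gaps = []
    for day, start, length in scenario.nonwear_gaps:
        if not (0 <= day < n):
            continue
        stop = min(start + length, MINUTES_PER_DAY)
        matrix[day, start:stop] = np.nan
        gaps.append((int(day), int(start), int(stop - start)))

    truth = {
        "amplitude_factor": amp,
        "jitter_sd": jit,
        "shifts": shifts,
        "gaps": gaps,
    }
    return matrix, truth


def day_records_from_matrix(
    patient_id: str,
    matrix: np.ndarray,
    validity: Optional[ValidityParams] = None,
) -> List[DayRecord]:
    """Wrap a minute-AI matrix as DayRecords (missing minutes = non-worn)."""
    validity = validity or ValidityParams()
    records = []
    for d in range(matrix.shape[0]):
        ai = matrix[d]
        wear = np.isfinite(ai)
        valid = nonwear_minutes(wear, validity.count_mode) <= validity.max_nonwear_minutes
        records.append(
            DayRecord(
                patient_id=patient_id,
                day_index=d,
                window_start=None,
                minute_ai=ai,
                wear_mask=wear,
                is_valid=valid,
            )
        )
    return records


def render_raw_stream(
    minute_ai_day: np.ndarray,
    window_start: datetime,
    rate: int = SAMPLE_RATE_HZ,
    seed: int = 0,
) -> pd.DataFrame:
    """Render one day's minute-AI vector as a raw 20 Hz sample stream.

    Each worn minute emits zero-mean tri-axial Gaussian noise around the
    gravity vector with per-axis standard deviation AI/60, so the default
    variance-based AI model recovers the target minute AI (one-second epochs
    each contribute ~AI/60).  Non-wear (NaN) minutes render as a constant
    gravity vector — a motionless device on a table.
    """
    ai = np.asarray(minute_ai_day, dtype=float)
    if ai.shape != (MINUTES_PER_DAY,):
        raise ValueError("minute_ai_day must have 1440 entries")
    rng = np.random.default_rng(seed)
    per_min = rate * 60
    n_total = MINUTES_PER_DAY * per_min

    sd = np.repeat(np.nan_to_num(ai, nan=0.0) / 60.0, per_min)
    xyz = rng.standard_normal((n_total, 3)) * sd[:, None]
    xyz[:, 2] += 1.0  # gravity

    ts = pd.Timestamp(window_start) + pd.to_timedelta(np.arange(n_total) / rate, unit="s")
    return pd.DataFrame({"timestamp": ts, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]})


@dataclass
class Cohort:
    """A generated cohort with its ground truth."""

    scenarios: List[PatientScenario]
    events: List[ClinicalEvent]
    #: (patient_id, event_day) -> whether a deterioration window precedes it
    predictable: Dict[Tuple[str, int], bool] = field(default_factory=dict)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": pd.Series([e.patient_id for e in self.events], dtype=str),
                "day_index": pd.Series([e.day_index for e in self.events], dtype=int),
                "kind": pd.Series([e.kind for e in self.events], dtype=str),
            }
        )


def generate_cohort(
    n_patients: int,
    n_days: int = 110,
    event_rate: float = 1.3,
    predictable_fraction: float = 0.67,
    seed: int = 0,
    onset_days_before: int = 21,
    amplitude_decay_rate: float = 0.08,
    regularity_decay_rate: float = 0.15,
    nonwear_day_rate: float = 0.05,
) -> Cohort:
    """Generate a cohort of synthetic patients with an event log.

    ``event_rate`` is the mean number of ER/RH events per patient (events
    are spaced at least 45 days apart and never before day 40 so every event
    has a full monitoring history).  A ``predictable_fraction`` of events is
    preceded by a deterioration window with the given onset length and decay
    rates; the rest are abrupt.  ``nonwear_day_rate`` is the per-day
    probability of a long off-wrist gap (which invalidates that day).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    scenarios: List[PatientScenario] = []
    events: List[ClinicalEvent] = []
    predictable: Dict[Tuple[str, int], bool] = {}

    for i in range(n_patients):
        pid = f"P{i:03d}"
        base_amp = rng.uniform(5.0, 20.0)

        candidate_days = np.arange(40, n_days)
        # capacity under the >=45-day spacing with the first event >= day 40
        capacity = 0 if len(candidate_days) == 0 else 1 + (n_days - 41) // 45
        n_events = min(rng.poisson(event_rate), capacity)
        event_days: List[int] = []
        tries = 0
        while len(event_days) < n_events and tries < 100:
            d = int(rng.choice(candidate_days))
            if all(abs(d - e) >= 45 for e in event_days):
                event_days.append(d)
            tries += 1
        event_days.sort()

        dets: List[Deterioration] = []
        for d in event_days:
            kind = "ER" if rng.random() < 0.5 else "RH"
            is_pred = bool(rng.random() < predictable_fraction)
            events.append(ClinicalEvent(patient_id=pid, day_index=d, kind=kind))
            predictable[(pid, d)] = is_pred
            if is_pred:
                dets.append(
                    Deterioration(
                        event_day=d,
                        onset_days_before=onset_days_before,
                        amplitude_decay_rate=amplitude_decay_rate,
                        regularity_decay_rate=regularity_decay_rate,
                    )
                )

        gaps: List[Tuple[int, int, int]] = []
        if nonwear_day_rate > 0:
            for d in np.flatnonzero(rng.random(n_days) < nonwear_day_rate):
                start = int(rng.integers(0, MINUTES_PER_DAY - 600))
                length = int(rng.integers(90, 600))
                gaps.append((int(d), start, length))

        scenarios.append(
            PatientScenario(
                patient_id=pid,
                n_days=n_days,
                base_amplitude=float(base_amp),
                nonwear_gaps=gaps,
                events=[(e.day_index, e.kind) for e in events if e.patient_id == pid],
                deterioration=dets,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )

    return Cohort(scenarios=scenarios, events=events, predictable=predictable)
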