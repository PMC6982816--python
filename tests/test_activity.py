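"""Minute activity index, regularity index, sleep detection, daily aggregates."""
import math
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from conftest import make_day

from actitrend import activity
from actitrend.config import AiParams, RiParams, SleepParams
from actitrend.records import MINUTES_PER_DAY, DayBlock


def scalar_ai_oracle(xyz, seconds, noise_sd=0.0):
    """Straightforward non-vectorized reimplementation of the minute AI:
    for each 1-s epoch take per-axis sample variance (ddof=1), subtract the
    noise floor from the axis mean, clip, sqrt, and sum the 60 epochs."""
    total = 0.0
    for e in range(60):
        sel = [i for i, s in enumerate(seconds) if e <= s < e + 1]
        if len(sel) < 2:
            continue
        block = xyz[sel]
        variances = [np.var(block[:, a], ddof=1) for a in range(3)]
        v = sum(variances) / 3.0 - noise_sd**2
        total += math.sqrt(max(0.0, v))
    return total


def sample_minute(rng, sd=0.1, rate=20):
    n = 60 * rate
    seconds = np.arange(n) / rate
    xyz = rng.standard_normal((n, 3)) * sd
    return xyz, seconds


class TestMinuteAi:
    def test_constant_signal_has_zero_ai(self):
        xyz = np.ones((1200, 3)) * [0.1, -0.2, 0.97]
        seconds = np.arange(1200) / 20.0
        assert activity.compute_minute_ai(xyz, seconds) == pytest.approx(0.0, abs=1e-12)

    def test_noise_floor_calibration_nulls_white_noise(self, rng):
        xyz, seconds = sample_minute(rng, sd=0.05)
        ai = activity.compute_minute_ai(xyz, seconds, AiParams(noise_sd=0.05))
        # unbiased epoch variances scatter around the floor; residual is small
        assert ai < 0.05 * 60 * 0.35

    def test_sinusoid_matches_scalar_oracle(self, rng):
        seconds = np.arange(1200) / 20.0
        xyz = np.zeros((1200, 3))
        xyz[:, 0] = np.sin(2 * np.pi * seconds)  # 1 g amplitude on one axis
        expected = scalar_ai_oracle(xyz, seconds)
        got = activity.compute_minute_ai(xyz, seconds)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 0

    def test_homogeneity_under_amplitude_scaling(self, rng):
        xyz, seconds = sample_minute(rng)
        base = activity.compute_minute_ai(xyz, seconds)
        scaled = activity.compute_minute_ai(3.5 * xyz, seconds)
        assert scaled == pytest.approx(3.5 * base, rel=1e-9)

    def test_empty_minute_is_missing_not_zero(self):
        assert math.isnan(activity.compute_minute_ai(np.empty((0, 3)), np.empty(0)))

    def test_day_pipeline_agrees_with_scalar_oracle(self, rng):
        """Vectorized whole-day computation == per-minute oracle to 1e-9."""
        n_min, rate = 40, 20
        n = n_min * 60 * rate
        ws = datetime(2021, 5, 1, 12, 0)
        seconds = np.arange(n) / rate
        xyz = rng.standard_normal((n, 3)) * np.repeat(rng.uniform(0.01, 0.3, n_min), 60 * rate)[:, None]
        stream = pd.DataFrame({
            "timestamp": pd.Timestamp(ws) + pd.to_timedelta(seconds, unit="s"),
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2] + 1.0,
        })
        block = DayBlock(0, ws, stream, partial=True)
        vec = activity.day_minute_ai(block)
        for m in range(n_min):
            lo, hi = m * 60 * rate, (m + 1) * 60 * rate
            expected = scalar_ai_oracle(
                stream[["x", "y", "z"]].to_numpy()[lo:hi], seconds[lo:hi] - m * 60
            )
            assert vec[m] == pytest.approx(expected, rel=1e-9)
        assert np.isnan(vec[n_min:]).all()


class TestRegularityIndex:
    def test_identical_days_have_ri_one(self, rng):
        ai = rng.uniform(0.5, 10.0, MINUTES_PER_DAY)
        day = make_day(ai)
        assert activity.compute_ri(day, day) == pytest.approx(1.0)

    def test_additive_shift_leaves_ri_one(self, rng):
        ai = rng.uniform(0.5, 10.0, MINUTES_PER_DAY)
        assert activity.compute_ri(make_day(ai), make_day(ai + 4.2)) == pytest.approx(1.0)

    def test_half_day_rotation_of_sinusoid_gives_minus_one(self):
        m = np.arange(MINUTES_PER_DAY)
        ai = 5 + 4 * np.sin(2 * np.pi * m / MINUTES_PER_DAY)
        rotated = np.roll(ai, MINUTES_PER_DAY // 2)
        assert activity.compute_ri(make_day(ai), make_day(rotated)) == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self, rng):
        a = make_day(rng.uniform(0, 10, MINUTES_PER_DAY))
        b = make_day(rng.uniform(0, 10, MINUTES_PER_DAY))
        assert activity.compute_ri(a, b) == pytest.approx(activity.compute_ri(b, a))

    def test_missing_when_too_few_mutual_minutes(self, rng):
        ai = rng.uniform(0, 10, MINUTES_PER_DAY)
        wear = np.zeros(MINUTES_PER_DAY, dtype=bool)
        wear[:719] = True
        a = make_day(ai)
        b = make_day(ai, wear=wear)
        assert math.isnan(activity.compute_ri(a, b))

    def test_missing_for_constant_day(self):
        assert math.isnan(activity.compute_ri(make_day(1.0), make_day(2.0)))


class TestSleepDetection:
    def test_all_zero_day_is_one_long_bout(self):
        assert activity.detect_sleep(make_day(0.0)) == [(0, MINUTES_PER_DAY)]

    def test_uniformly_active_day_has_no_sleep(self):
        assert activity.detect_sleep(make_day(10.0)) == []

    def test_planted_quiescence_recovered(self, rng):
        # 02:00-08:00 quiescence on the noon-to-noon grid = minutes 840-1200
        ai = rng.uniform(8, 12, MINUTES_PER_DAY)
        ai[840:1200] = rng.uniform(0.0, 0.5, 360)
        bouts = activity.detect_sleep(make_day(ai))
        mask = activity.sleep_mask(bouts)
        overlap = mask[840:1200].sum() / 360
        assert overlap >= 0.9
        assert mask[:820].sum() == 0

    def test_short_bouts_dropped_and_nearby_merged(self):
        ai = np.full(MINUTES_PER_DAY, 10.0)
        ai[100:150] = 0.0  # 50 min < min_bout
        ai[400:470] = 0.0
        ai[480:560] = 0.0  # 10-min gap < merge_gap: merges with previous
        bouts = activity.detect_sleep(make_day(ai), SleepParams(smooth_window=1))
        assert bouts == [(400, 560)]


class TestDailyMetrics:
    def test_uniform_day_arithmetic(self):
        day = make_day(1.0)
        m = activity.compute_daily_metrics(day, sleep_bouts=[])
        assert m.total_ai == pytest.approx(1440.0)
        assert m.awake_ai_per_hour == pytest.approx(60.0)
        assert m.sleep_minutes == 0
        assert math.isnan(m.ri)

    def test_sleep_partition_rates(self):
        day = make_day(1.0)
        m = activity.compute_daily_metrics(day, sleep_bouts=[(0, 480)])
        assert m.sleep_minutes == 480
        assert m.sleep_ai_per_hour == pytest.approx(60.0)
        assert m.awake_ai_per_hour == pytest.approx(60.0)

    def test_metrics_match_bruteforce_recomputation(self, rng):
        ai = rng.uniform(0, 10, MINUTES_PER_DAY)
        wear = rng.random(MINUTES_PER_DAY) > 0.02
        ai_masked = np.where(wear, ai, np.nan)
        day = make_day(ai_masked, wear=wear)
        bouts = [(840, 1200)]
        m = activity.compute_daily_metrics(day, sleep_bouts=bouts)

        sleep = np.zeros(MINUTES_PER_DAY, bool)
        sleep[840:1200] = True
        total = sum(ai[i] for i in range(MINUTES_PER_DAY) if wear[i])
        sleep_ai = sum(ai[i] for i in range(MINUTES_PER_DAY) if wear[i] and sleep[i])
        awake_ai = sum(ai[i] for i in range(MINUTES_PER_DAY) if wear[i] and not sleep[i])
        n_sleep = int((wear & sleep).sum())
        n_awake = int((wear & ~sleep).sum())
        assert m.total_ai == pytest.approx(total, rel=1e-12)
        assert m.sleep_minutes == n_sleep
        assert m.sleep_ai_per_hour == pytest.approx(sleep_ai / (n_sleep / 60), rel=1e-12)
        assert m.awake_ai_per_hour == pytest.approx(awake_ai / (n_awake / 60), rel=1e-12)
        assert m.sleep_minutes + n_awake == int(wear.sum())

    def test_total_ai_permutation_invariant_but_ri_not(self, rng):
        ai = rng.uniform(0, 10, MINUTES_PER_DAY)
        perm = rng.permutation(MINUTES_PER_DAY)
        base = make_day(ai, day_index=1)
        # yesterday resembles today: high RI unless the time-locking breaks
        prev = make_day(ai + rng.normal(0, 0.5, MINUTES_PER_DAY), day_index=0)
        shuffled = make_day(ai[perm], day_index=1)
        m1 = activity.compute_daily_metrics(base, day_prev=prev, sleep_bouts=[])
        m2 = activity.compute_daily_metrics(shuffled, day_prev=prev, sleep_bouts=[])
        assert m1.total_ai == pytest.approx(m2.total_ai, rel=1e-12)
        assert m1.ri > 0.9 and abs(m2.ri) < 0.3
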