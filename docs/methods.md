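# Methods

This note documents how `actitrend` defines each stage of the pipeline, the
defaults it ships, the choices that were genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Day grid and the valid-day rule

Days run noon to noon on the local clock, indexed from the discharge date
(day 0 starts at 12:00 on the discharge day). The noon boundary keeps whole
nights inside single days and matches the clinical routine of swapping
devices at daytime check-ups. Timestamps are treated as clock labels:
daylight-saving transitions produce physically 23/25-hour days that are
mapped onto the 1440-minute grid by their labels, since the day construct is
a clock convention, not an elapsed-time one.

A day is **invalid** when the device was off-wrist for more than 60 minutes
— read strictly (60 minutes is still valid, 61 is not) — or when the
recording does not cover the whole window (partial first/last days), because
a Total_AI over fewer than 1440 minutes is not comparable day to day.
Off-wrist time is counted cumulatively by default; a
`ValidityParams(count_mode="consecutive")` switch counts the longest single
gap instead, since the wording "removed for more than one hour" admits
either reading.

## Non-wear detection

Only the >60-minute consequence of device removal is part of the published
model; how removal is detected is left to the implementation. We use the
standard stationary-run heuristic from actigraphy practice: a minute is a
stationary candidate when each axis has standard deviation < 0.013 g *and*
peak-to-peak range < 0.05 g; candidates count as non-wear only inside runs
of ≥ 30 consecutive minutes (short still periods — watching television — are
wear); minutes with no samples at all are always non-wear. All three
thresholds are configurable (`NonwearParams`). The detector is invariant to
time translation and to constant per-axis offsets, so device orientation
does not matter.

## Activity index (AI)

The published pipeline takes its AI and RI definitions from earlier device
modelling work whose internal formulas are not restated; both are therefore
pluggable strategy points here (`activity.AI_MODELS` / `RI_MODELS`) with
documented defaults.

Default AI: partition each minute into 60 one-second epochs; for each epoch
take the per-axis sample variance (ddof 1), subtract the squared device
noise floor `noise_sd` (default 0 g, i.e. no correction), average over the
three axes, clip at zero, take the square root; the minute AI is the sum of
the 60 epoch values. This is a parameter-light, positively homogeneous
movement-intensity measure: scaling all accelerations by k scales every AI
by k (with `noise_sd = 0`), and a signal with per-axis noise exactly at the
floor yields ≈ 0. A minute with no samples is *missing*, not zero. Epochs
with fewer than two samples carry no variance information and contribute 0.

## Regularity index (RI)

Default RI: Pearson correlation between today's and yesterday's 1440-long
minute-AI vectors, restricted to mutually worn minutes, requiring at least
720 mutually worn minutes (half a day) and non-constant vectors; otherwise
missing. RI is missing on the first valid day and after any gap (the
preceding calendar day must be valid). This default is consistent with the
(1 + RI) factor of the quality score spanning [0, 2].

Missing minutes inside a valid day contribute 0 to Total_AI (bounded
distortion: at most an hour) but are *excluded* from the correlation, which
zero-filling would bias.

## Sleep detection

Sleep outputs (duration, awake/sleep AI per hour) are reported by the
pipeline but feed nothing downstream, so any deterministic documented rule
suffices. We use a threshold-bout rule: minutes whose centered 11-minute
moving-average AI falls below 2.0 form candidate bouts; bouts separated by
gaps shorter than 20 minutes merge; bouts shorter than 60 minutes are
dropped. The threshold is in AI units and sits between the generator's
worn-sleep floor (≈ 1) and daytime levels (≈ 10); for real devices it should
be calibrated per deployment (`SleepParams`).

## Trend statistics and missing-data propagation

QoA, ΔQoA, WQoA, ΔWQoA and ΣΔQoA are computed exactly as defined in the
README, with percentages carried on the ×100 scale the alert thresholds use.
The WQoA weights (0.4/0.3/0.2/0.1) and the 7-day summation window are part
of the published model and are not ordinary configuration; they can only be
overridden through an explicitly experimental namespace
(`ExperimentalTrendParams`) for sensitivity studies.

Propagation rules: a statistic exists only when all of its inputs exist, and
day-over-day differences require calendar-consecutive valid days. A single
invalid day therefore suppresses ΔQoA for two days and ΣΔQoA for eight —
gaps silence the alarm rather than bridging it, which mirrors the clinical
observation that discontinuous monitoring causes missed events. When RI is
missing, QoA is missing for that day; `TrendParams(ri_default_zero=True)`
substitutes RI = 0 instead for users who want a day-one QoA, at the price of
mixing regularity-free scores into the series.

Division guards: ΔQoA/ΔWQoA are missing when the denominator day is missing
or exactly 0 (a degenerate all-zero day).

## Alerting profiles

"More than 4 days" / "more than 3 days" are strict counts (≥ 5 and ≥ 4
dropping days out of 7); "ΣΔQoA drops more than 30%" is ΣΔQoA < −30 on the
percent scale; "ΔWQoA dropping" means ΔWQoA < 0, i.e. the weighted score
decreased from the day before. Missing statistics never satisfy a criterion,
so no alert can be raised in the first 7 days after discharge or inside the
7-day shadow of a data gap. The three profiles are strictly nested by
construction (stricter ⊆ proposed ⊆ loosened as qualifying-day sets, for any
series).

Consecutive qualifying days are merged into one alert *episode* anchored at
the run's first day (default `merge=True`): a sustained decline is one
clinical alert, and episode-level counting is consistent with the reference
cohort's 45 predictions over ~1761 valid days. `merge=False` emits one
prediction per qualifying day for studying the alternative; the false-
negative set is unaffected by the toggle.

## Evaluation

A prediction on day *d* is a true positive iff an ER/rehospitalization event
occurs at day *e* with d < e ≤ d + 30 — strictly after the alert (a same-day
event is a concurrent admission, not a prediction) and within the 30-day
horizon. The false-negative window mirrors it (e − 30 ≤ d < e). Multiple
predictions may be credited to one event, so TP + FN need not equal the
event count. Outpatient (OPD) visits are annotations only: a false positive
with an OPD inside its horizon is flagged (treatment changes after routine
visits are a documented false-alarm mechanism) but never reclassified.
Percentages are exact rationals internally; reported values are rounded
half-up at two decimals (one decimal in the profile-comparison view, which
is the precision the reference comparison table uses).

No true negatives exist in this design, so specificity, negative predictive
value and fall-out are deliberately not computed.

## Synthetic cohort generator

The generator emulates the post-discharge monitoring regime: a circadian
minute-AI template (active ~07:00–22:00, quiescent night with raised-cosine
transitions), scaled by a per-patient amplitude drawn from 5–20 AI units,
with per-minute lognormal noise (σ = 0.15) and a per-day random circular
time shift (sd 5 minutes) representing ordinary routine variation. These
defaults put a regular patient's day-to-day RI at ≥ 0.9 on average.
Worn sleep keeps a non-zero activity floor (≈ 1 AI unit ≈ 0.017 g epoch sd):
real wrists move during sleep, and this is precisely what separates worn
sleep from an off-wrist device for the stationary-run detector.

Pre-event deterioration has two independent knobs, because the motivating
clinical case deteriorated in regularity while total activity stayed level:
exponential decay of the daytime amplitude (default 0.08/day over a 21-day
onset) and exponential growth of the time-shift jitter (default 0.15/day,
capped at 360 minutes), which drags the day-to-day correlation down. Decay
applies to the activity *above* the sleep floor, so a deteriorating patient
is not misread as non-wear. Cohort defaults: 110 days per patient (the
reference cohort's mean valid follow-up), 1.3 events per patient, 67% of
events preceded by deterioration (the reference false negatives were mostly
data-coverage failures, not silent events), 5% of days carrying a long
off-wrist gap. Under these defaults the proposed profile's cohort
sensitivity lands in the low-to-mid 60s percent, the same regime as the
reference evaluation.

Raw rendering draws, for each worn minute, 20 Hz zero-mean Gaussian
tri-axial samples around the gravity vector with per-axis sd = AI/60, so the
default AI model recovers the planted minute AI; the round-trip mean
relative error is ≈ 1% (sampling error of 60 variance estimates per minute),
and planted gaps are recovered exactly at minute resolution.

**What the synthetic validation does not show.** The generator's days are
stationary within the active period, its noise is independent across
minutes, its non-wear is perfectly still, and deterioration is exactly
exponential. Real actigraphy has posture artifacts, device noise floors,
naps, shift-work schedules, and deterioration of irregular shape. Passing
the synthetic suite demonstrates that the pipeline computes its definitions
correctly and detects the signal class it targets — not that the shipped
thresholds generalize clinically beyond the cohort they were developed on.

## Numerical and reproducibility choices

- Per-epoch variances use one-pass accumulators with clipping at zero;
  constant signals may yield AIs at the 1e-15 level rather than exactly 0.
- All randomness flows through `numpy.random.default_rng` seeded per
  scenario; cohorts, rendering and the whole pipeline are bit-reproducible
  for a given seed, and repeated CLI runs produce byte-identical CSVs.
- Problem sizes in the test and acceptance runs (200-patient cohort for
  profile ordering, 16-patient cohorts for the detectability extremes,
  2-day raw round trips) were chosen as the smallest sizes at which the
  cohort-level proportions are stable across seeds.

## Known limitations

- The AI/RI defaults are this package's documented constructions, not the
  original device-specific formulas; absolute AI values are not comparable
  across AI models, though all percent-based trend statistics are
  scale-invariant by construction.
- Alerts are binary rules, not calibrated risks; no survival modelling.
- The 7-day windows run on calendar days with fail-silent missing values;
  an alternative valid-day-indexed windowing is not implemented.
- OPD-triggered treatment changes are annotated but never reset the
  evaluation window.
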