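# Methods

This note documents the models and numerical choices behind the toolkit:
how repetitions are recognised in a gravity trace, what the synthetic trace
generator does and does not emulate, how the agreement statistics are
defined, and where genuinely open design decisions were resolved.

## Gravity traces

The input signal is the Android *gravity* virtual sensor: a software-fused
three-vector (x, y, z) in m/s² whose magnitude is nominally g = 9.81 m/s².
When the phone is strapped to a moving body segment (thigh for the chair
stand and step tests, forearm for the arm curl), the segment's orientation
is read off the y component alone: y ≈ 0 when the segment is horizontal,
y ≈ −g when it is vertical with the phone upside down, y positive when the
phone's y axis points downward (forearm past vertical during a curl).

Traces are plain CSV (`t,x,y,z`, seconds and m/s², `#key=value` metadata
comments). Timestamps must be strictly increasing and are the time base for
every algorithm; `sample_rate_hz` is advisory metadata only. A sample whose
magnitude leaves the band [8.8, 10.8] m/s² (±10% around g) is *flagged* in
metadata rather than rejected: the fused sensor is noisy, and a hard error
would discard usable recordings, but a systematic violation signals a bad
mounting or a unit mistake.

Pre-filtering is a centred moving average with shrunken windows at the
edges (length-preserving, linear). For signals that are constant near both
ends — every test trace starts and ends on a still plateau — this edge
policy also preserves the channel mean to numerical precision.

## Repetition detection

Each sensor-scored item is one movement cycle between two postures, so
counting is a two-state hysteresis machine on smoothed y:

* `chair_stand` — baseline |y| < 2.0 (seated, phone near-horizontal),
  active y < −8.0 (standing), 30 s limit;
* `arm_curl` — baseline y < −5.0 (arm extended), active y > +7.5 (curled),
  30 s limit;
* `two_min_step` — baseline y < −8.0 (standing), active y > −2.0 (knee
  raised, thigh near-horizontal), 120 s limit.

A transition fires only after its predicate holds continuously for
`min_phase_s` (default 0.15 s); a repetition is credited when the signal
re-enters the baseline band — the movement is complete on return to the
starting posture, not at the apex. The gap between the two thresholds is
the hysteresis band: a signal oscillating entirely inside it can never
produce a count, which is what makes the counter robust to sensor noise
and hesitation at mid-movement.

Numerical choices, all exposed in `DetectorConfig`:

* The active threshold for the vertical postures is −8.0 m/s² (≈35° from
  vertical) rather than the −9.8 m/s² physical extreme, because a noisy
  signal rarely attains the exact extremum; the resulting ≥6 m/s²
  hysteresis gap still separates the phases by a wide margin.
* `min_phase_s` = 0.15 s rejects single-sample spikes; the fastest
  plausible sit-to-stand or knee-raise phase is far longer.
* `smooth_window` = 5 samples at the 50 Hz default rate (0.1 s) — enough
  to suppress white noise of SD ≲ 1 m/s² without rounding plateau entries
  past the dwell requirement.
* Samples after `max_duration_s` (relative to the first timestamp) are
  discarded before processing, so the time-limit contract is exact: a
  repetition completing after the limit is never counted, and a trace cut
  mid-active-phase reports `incomplete_final_phase`.
* Threshold-based detection was chosen over trained classifiers
  deliberately: the decision rule must run in real time on low-cost
  hardware and be auditable by the practitioner.

The stopwatch item (8-foot up-and-go) records, per trial, the elapsed time
rounded **half-up** to 0.1 s, then takes the minimum across trials
(rounding before the minimum; ties at the half go up). The protocol's
"fastest of two attempts to the nearest tenth" does not fix this order of
operations; rounding first matches how times are read off a stopwatch.

## Synthetic traces

The simulator produces the idealised waveform of each item: y alternates
between the item's baseline and active plateaus through raised-cosine
ramps (smooth transitions, as real recordings show; square waves would
make detection trivially easy at the wrong frequencies). Defaults: rep
period 2 s, 30% of each period spent ramping, 50 Hz, noise SD 0.2 m/s²,
1 s still lead-in/out. The arm-curl active plateau is +8.5 m/s² — a
forearm slightly past vertical — so the +7.5 m/s² threshold is crossed
with margin. A mounting-tilt parameter (±20°) rotates the baseline
orientation in the y–z plane; x is noise only, since the lateral axis
stays near zero for these mountings. z always carries the complement
√(g² − y²), so noiseless traces conserve |g| = 9.81 m/s² exactly;
i.i.d. Gaussian noise is then added per axis, making the noisy magnitude
fluctuate around g the way the fused sensor does.

`simulate_battery` draws one repetition count per sensor item uniformly
from the 60–69 reference band (mean ± 2 SD, bounds rounded), with cycle
lengths (1.5 s chair stand, 1.0 s arm curl and step) chosen so that even a
count two SDs above the reference mean fits inside the item's time limit.

What the generator does **not** emulate: imperfect or asymmetric movement
(partial stands, tremor), autocorrelated or spectrally coloured sensor
noise, sample-rate jitter, or drifting mounting. Passing the
simulator-inversion tests therefore shows the detector is correct for
well-executed movements under white noise — the regime the idealised
detection rules are designed for — not that it is robust to pathological
movement, which a clinical deployment would need to assess separately.

## Normative scoring

The packaged reference table holds the sex-pooled mean (SD) per decade
band 60–69 / 70–79 / 80–89 for all six items. "Within the normal range" is
operationalised as |z| ≤ 1 with z = (value − mean)/SD; the band width is a
parameter. Ages outside 60–89 clamp to the nearest band and the
classification carries a `clamped_age` flag so reports disclose the
extrapolation (the toolkit is routinely applied to people in their 50s).
For the timed item the z sign keeps its arithmetic meaning and the result
carries a `lower_is_better` direction note. Sex-specific tables are a
drop-in replacement (same CSV schema), not a reimplementation.

## Agreement statistics

Validating sensor-assisted against manual administration is a two-rater
agreement design: n subjects × k = 2 methods. From the one-way and two-way
ANOVA mean squares (MSB between subjects, MSW within subjects, MSE the
two-way residual; all with the textbook n−1-style degrees of freedom):

* one-way random: ICC(1,1) = (MSB − MSW)/(MSB + (k−1) MSW),
  ICC(1,k) = (MSB − MSW)/MSB;
* two-way consistency: ICC(C,1) = (MSB − MSE)/(MSB + (k−1) MSE),
  ICC(C,k) = (MSB − MSE)/MSB;
* Cronbach's α = k/(k−1) · (1 − Σ item variances / total-score variance),
  which is algebraically identical to ICC(C,k) — the identity is enforced
  to 1e−12 in the test suite.

Confidence bounds use the standard F-quantile constructions on
F = MSB/denominator with (n−1, n(k−1)) or (n−1, (n−1)(k−1)) degrees of
freedom. Degenerate inputs raise a dedicated error (zero between-subject
variance) or return the exact boundary (perfect agreement → estimate 1
with a degenerate upper bound) rather than emitting NaNs.

The default report form is **two-way consistency, average measures**. The
source case study's table footnote names a one-way random model, but its
printed per-item coefficients equal Cronbach's α exactly — i.e. the
consistency/average form — while the one-way single-measures coefficient
on the same chair-stand data is ≈ 0.56. Both forms are implemented, the
report always states which was used, and the test suite pins the
divergence so it cannot be silently "fixed" in either direction. Printed
reliability values are compared at their printed precision (one unit in
the second decimal): two fixture items compute to 0.998, which a strict
round would display as 1.00 while the study prints 0.99.

Bland–Altman analysis takes differences manual − sensor, their mean and
n−1 SD, and limits of agreement at mean ± 1.96 SD; the plot shows
difference vs pair mean with the mean line in black and the limits in
red. On simulated Gaussian paired data the limits cover 95% ± 1% of
differences, which the suite checks at n = 5000.

Interpretation bands follow the conventional cut-offs: ICC ≤ 0.4 poor,
0.4–0.75 fair-to-good, > 0.75 excellent; α ≤ 0.5 unacceptable, 0.5–0.9
poor-to-good, > 0.9 excellent. The prose cut-offs are ambiguous exactly at
the boundaries; boundary values fall in the **lower** band, a documented
choice applied uniformly.

## Usability scoring

The System Usability Scale: ten 5-point items of alternating polarity;
odd items contribute (answer − 1), even items (5 − answer); 2.5 × the sum
gives a 0–100 score. Complementing every answer (v → 6 − v) maps a score
s to 100 − s, a symmetry the suite enforces. Aggregation is the mean
across raters, labelled unacceptable below 50 and good above 70; the
closed middle [50, 70] is "marginal". The module is validated by
construction and symmetry — published mean scores from surveys whose raw
responses are unpublished cannot be recomputed, only compared.

## Records and interfaces

The record store mirrors the entity model of the mobile app it supports:
person profiles, sessions holding at most one result per item, and sensor
buffers referencing trace files — kept in a single versioned JSON document
(human-diffable, trivially portable, fully offline; atomic
write-temp-then-rename persistence). Age is derived from birth date at the
session date rather than stored, so it can never go stale. An embedded
relational backend would honour the same contract but is not required at
this scale. The CLI (`msft simulate|count|classify|score-session|
reliability|sus|history|export`) emits machine-readable JSON first, CSV on
request; the long-format export is directly consumable by the reliability
command.

## Problem sizes

The suite's stochastic checks use deliberately desk-scale sizes chosen to
make failures attributable: 50 seeds × 3 noise levels × 3 items for the
simulator-inversion check (counts of 12–20 reps at 50 Hz), 100 random
matrices (n ∈ [5, 9), k ∈ [2, 4)) for the ANOVA-oracle and α-identity
checks, and 5000 pairs for limits-of-agreement coverage. The packaged
case-study fixture is the full published table: 7 subjects × 6 items × 2
methods.

## Known limitations

* Detection assumes biomechanically clean movement; degraded patterns
  (incomplete stands, shuffling steps) will undercount, and the simulator
  cannot currently generate them.
* The white-noise model is a stand-in; the real fused sensor's noise
  spectrum is uncharacterised here.
* Flexibility distances are manual entry by design — no automatic distance
  measurement is attempted.
* Reference values are sex-pooled; sex-specific classification requires
  supplying an alternative norms table.
* Only two-method (inter-rater) agreement designs are supported, not
  test–retest reliability of a single method.
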