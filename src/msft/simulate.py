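"""Seeded gravity-trace simulator with known ground-truth repetition counts.

Each sensor-based Senior Fitness Test item produces a characteristic
y-gravity waveform when the phone is strapped to the moving segment:

* ``chair_stand`` — sitting holds the phone near-horizontal (y ≈ 0); standing
  turns it vertical, upside down (y ≈ −g).
* ``arm_curl`` — arm extended, phone upside down on the forearm (y ≈ −g);
  at the top of the curl the forearm points up and y swings positive, past
  the +7.5 m/s² detection threshold (the simulator's active plateau is
  +8.5 m/s², a forearm slightly past vertical).
* ``two_min_step`` — standing baseline (y ≈ −g); raising the knee brings the
  thigh toward horizontal (y ≈ 0).

The waveform alternates between the two plateaus through raised-cosine ramps,
x carries noise only, and z takes the complement so the noiseless magnitude
is exactly g = 9.81 m/s².  Gaussian noise is added per axis afterwards, so a
noisy trace fluctuates around g the way the fused software sensor does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .trace import GravityTrace, STANDARD_GRAVITY

SENSOR_TEST_KINDS = ("chair_stand", "arm_curl", "two_min_step")

#: arm-curl active plateau: forearm slightly past vertical, comfortably above
#: the +7.5 m/s² threshold.
ARM_CURL_ACTIVE_Y = 8.5


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated test execution.

    rep_period_s is the duration of a full baseline→active→baseline cycle;
    transition_frac is the fraction of the period spent in the two ramps
    combined; tilt_deg models a mounting that is not perfectly aligned with
    the body segment; lead_s is the still plateau before and after the reps.
    """

    test_kind: str
    n_reps: int
    rep_period_s: float = 2.0
    transition_frac: float = 0.3
    sample_rate_hz: float = 50.0
    noise_sd: float = 0.2
    tilt_deg: float = 0.0
    lead_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_kind not in SENSOR_TEST_KINDS:
            raise ValidationError(
                f"unknown test_kind {self.test_kind!r}; expected one of {SENSOR_TEST_KINDS}"
            )
        if self.n_reps < 1:
            raise ValidationError("n_reps must be a positive integer")
        if self.rep_period_s <= 0 or self.sample_rate_hz <= 0:
            raise ValidationError("rep_period_s and sample_rate_hz must be positive")
        if not 0 <= self.transition_frac <= 0.9:
            raise ValidationError("transition_frac must lie in [0, 0.9]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not -20 <= self.tilt_deg <= 20:
            raise ValidationError("tilt_deg must lie in [-20, 20]")


@dataclass
class SimResult:
    """A simulated trace plus its ground truth."""

    trace: GravityTrace
    true_reps: int
    rep_boundaries: list[tuple[float, float, float]] = field(default_factory=list)


def _plateaus(test_kind: str, tilt_deg: float) -> tuple[float, float]:
    """(baseline_y, active_y) for a given item and mounting tilt."""
    g = STANDARD_GRAVITY
    tilt = np.deg2rad(tilt_deg)
    if test_kind == "chair_stand":
        return -g * np.sin(tilt), -g * np.cos(tilt)
    if test_kind == "arm_curl":
        return -g * np.cos(tilt), ARM_CURL_ACTIVE_Y
    # two_min_step
    return -g * np.cos(tilt), -g * np.sin(tilt)


def _cycle_y(phase: np.ndarray, baseline: float, active: float, frac: float) -> np.ndarray:
    """y over one rep cycle; ``phase`` in [0, 1).

    Layout: ramp up (frac/2), active hold, ramp down (frac/2), baseline hold;
    the two holds share the remaining (1 − frac) equally.  Ramps are raised
    cosines, matching the smooth transitions real traces show.
    """
    ramp = frac / 2.0
    hold = (1.0 - frac) / 2.0
    y = np.full(phase.shape, baseline, dtype=float)
    rise = phase < ramp
    if ramp > 0:
        u = phase[rise] / ramp
        y[rise] = baseline + (active - baseline) * (1 - np.cos(np.pi * u)) / 2
    top = (phase >= ramp) & (phase < ramp + hold)
    y[top] = active
    fall = (phase >= ramp + hold) & (phase < 2 * ramp + hold)
    if ramp > 0:
        u = (phase[fall] - ramp - hold) / ramp
        y[fall] = active + (baseline - active) * (1 - np.cos(np.pi * u)) / 2
    return y


def simulate(spec: SimSpec) -> SimResult:
    """Generate one seeded trace with exact rep boundaries as ground truth."""
    baseline, active = _plateaus(spec.test_kind, spec.tilt_deg)
    period = spec.rep_period_s
    active_total = spec.n_reps * period
    total = active_total + 2 * spec.lead_s
    n = int(round(total * spec.sample_rate_hz)) + 1
    t = np.arange(n) / spec.sample_rate_hz

    y = np.full(n, baseline, dtype=float)
    in_reps = (t >= spec.lead_s) & (t < spec.lead_s + active_total)
    phase = ((t[in_reps] - spec.lead_s) % period) / period
    y[in_reps] = _cycle_y(phase, baseline, active, spec.transition_frac)

    # z carries the norm complement (body rotation stays in the y–z plane for
    # the leg/forearm mountings); x is noise only.
    z = np.sqrt(np.maximum(STANDARD_GRAVITY**2 - y**2, 0.0))
    g = np.column_stack([np.zeros(n), y, z])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        g = g + rng.normal(0.0, spec.noise_sd, size=g.shape)

    ramp = spec.transition_frac / 2.0
    hold = (1.0 - spec.transition_frac) / 2.0
    boundaries = []
    for i in range(spec.n_reps):
        start = spec.lead_s + i * period
        mid = start + (ramp + hold / 2.0) * period
        boundaries.append((start, mid, start + period))

    trace = GravityTrace(
        t,
        g,
        sample_rate_hz=spec.sample_rate_hz,
        meta={"test_kind": spec.test_kind, "simulated": "true", "seed": str(spec.seed)},
    )
    return SimResult(trace=trace, true_reps=spec.n_reps, rep_boundaries=boundaries)


#: default cycle lengths used by :func:`simulate_battery`, chosen so that a
#: count two SDs above the 60–69 reference mean still fits the item's time
#: limit (30 s strength items, 120 s step test).
BATTERY_REP_PERIODS_S = {"chair_stand": 1.5, "arm_curl": 1.0, "two_min_step": 1.0}


def simulate_battery(seed: int, noise_sd: float = 0.2) -> dict[str, SimResult]:
    """One default simulation per sensor item, counts drawn from the 60–69
    reference band (mean ± 2 SD, bounds rounded) of the normative table."""
    from .norms import lookup_norm

    rng = np.random.default_rng(seed)
    out: dict[str, SimResult] = {}
    for kind in SENSOR_TEST_KINDS:
        entry = lookup_norm(kind, 65)
        lo = int(round(entry.mean - 2 * entry.sd))
        hi = int(round(entry.mean + 2 * entry.sd))
        n_reps = int(rng.integers(lo, hi + 1))
        spec = SimSpec(
            test_kind=kind,
            n_reps=n_reps,
            rep_period_s=BATTERY_REP_PERIODS_S[kind],
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out[kind] = simulate(spec)
    return out
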