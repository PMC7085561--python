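"""Repetition counting on the y-gravity channel.

Every sensor-based item is a two-phase movement: a baseline posture and an
active posture, each mapping to a distinct y-gravity level.  Counting is a
hysteresis finite-state machine: the smoothed y signal must satisfy the
active predicate continuously for a minimum dwell to enter the ACTIVE state,
and the baseline predicate likewise to return — at which point one
repetition is credited.  The gap between the two thresholds is the
hysteresis band; a signal oscillating inside it can never produce a count.

Default thresholds sit short of the physical extremes (e.g. −8.0 m/s² for
the near-vertical −9.8 m/s² datum of the chair stand) because a noisy fused
sensor rarely attains the exact extremum; all thresholds are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .errors import ValidationError
from .trace import GravityTrace, smooth_channel

_OPS = ("lt", "gt", "abs_lt")


def _interval(op: str, threshold: float) -> tuple[float, float]:
    """y-range (open interval) where a predicate holds."""
    if op == "lt":
        return (-math.inf, threshold)
    if op == "gt":
        return (threshold, math.inf)
    return (-abs(threshold), abs(threshold))  # abs_lt


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and timing of the two-phase hysteresis detector.

    ``active_op``/``baseline_op`` compare smoothed y against the matching
    threshold: ``lt`` (below), ``gt`` (above) or ``abs_lt`` (within ±band).
    The two predicate regions must be disjoint with a positive gap.
    """

    test_kind: str
    active_enter: float
    active_op: str
    baseline_enter: float
    baseline_op: str
    min_phase_s: float = 0.15
    smooth_window: int = 5
    max_duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.active_op not in _OPS or self.baseline_op not in _OPS:
            raise ValidationError(f"comparison ops must be one of {_OPS}")
        if self.min_phase_s < 0:
            raise ValidationError("min_phase_s must be >= 0")
        if self.max_duration_s <= 0:
            raise ValidationError("max_duration_s must be positive")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be a positive odd integer")
        a_lo, a_hi = _interval(self.active_op, self.active_enter)
        b_lo, b_hi = _interval(self.baseline_op, self.baseline_enter)
        if max(a_lo, b_lo) < min(a_hi, b_hi):
            raise ValidationError(
                "active and baseline predicate bands overlap; hysteresis gap required"
            )
        if max(a_lo, b_lo) == min(a_hi, b_hi):
            raise ValidationError("hysteresis gap must be positive")

    def active_holds(self, y: float) -> bool:
        return _compare(y, self.active_op, self.active_enter)

    def baseline_holds(self, y: float) -> bool:
        return _compare(y, self.baseline_op, self.baseline_enter)

    def with_(self, **changes) -> "DetectorConfig":
        return replace(self, **changes)


def _compare(y: float, op: str, threshold: float) -> bool:
    if op == "lt":
        return y < threshold
    if op == "gt":
        return y > threshold
    return abs(y) < abs(threshold)


_DEFAULTS = {
    # chair stand: sitting |y| < 2 (phone near-horizontal), standing y < -8
    "chair_stand": dict(
        active_enter=-8.0, active_op="lt", baseline_enter=2.0, baseline_op="abs_lt",
        max_duration_s=30.0,
    ),
    # arm curl: extended arm y < -5, curled forearm y > +7.5
    "arm_curl": dict(
        active_enter=7.5, active_op="gt", baseline_enter=-5.0, baseline_op="lt",
        max_duration_s=30.0,
    ),
    # step in place: standing y < -8, knee raised y > -2
    "two_min_step": dict(
        active_enter=-2.0, active_op="gt", baseline_enter=-8.0, baseline_op="lt",
        max_duration_s=120.0,
    ),
}


def default_config(test_kind: str) -> DetectorConfig:
    """The per-item default detector configuration."""
    try:
        params = _DEFAULTS[test_kind]
    except KeyError:
        raise ValidationError(
            f"unknown test_kind {test_kind!r}; expected one of {tuple(_DEFAULTS)}"
        ) from None
    return DetectorConfig(test_kind=test_kind, **params)


@dataclass
class DetectionResult:
    reps: int = 0
    rep_times: list[float] = field(default_factory=list)
    incomplete_final_phase: bool = False
    truncated_at_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "reps": self.reps,
            "rep_times": [round(t, 6) for t in self.rep_times],
            "incomplete_final_phase": self.incomplete_final_phase,
            "truncated_at_s": self.truncated_at_s,
        }


def count_repetitions(trace: GravityTrace, config: DetectorConfig) -> DetectionResult:
    """Run the hysteresis state machine over a trace.

    The trace is truncated to ``max_duration_s`` (relative to its first
    timestamp) before processing, then the y channel is smoothed.  A rep is
    credited at the timestamp where the signal re-enters the baseline band
    (the completion of the movement cycle), once the baseline predicate has
    held for ``min_phase_s``.  A trace ending while in the active phase
    leaves the final repetition uncounted and flags it.
    """
    rel_t = trace.t - trace.t[0]
    keep = rel_t <= config.max_duration_s
    truncated = None
    if not keep.all():
        truncated = config.max_duration_s
    t = rel_t[keep]
    y = smooth_channel(trace.y[keep], config.smooth_window)

    result = DetectionResult(truncated_at_s=truncated)
    state = "BASELINE"
    run_start: float | None = None  # onset of the current target-predicate streak
    for ti, yi in zip(t, y):
        target_holds = (
            config.active_holds(yi) if state == "BASELINE" else config.baseline_holds(yi)
        )
        if not target_holds:
            run_start = None
            continue
        if run_start is None:
            run_start = ti
        if ti - run_start >= config.min_phase_s:
            if state == "BASELINE":
                state = "ACTIVE"
            else:
                state = "BASELINE"
                result.reps += 1
                result.rep_times.append(float(run_start))
            run_start = None
    result.incomplete_final_phase = state == "ACTIVE"
    return result


def stopwatch_time(trials: Sequence[tuple[float, float]]) -> float:
    """Best (fastest) elapsed time over stopwatch trials.

    Each trial is (start_s, stop_s); elapsed times are rounded half-up to
    0.1 s first, then the minimum is taken — the protocol records the fastest
    of the timed attempts to the nearest tenth of a second.
    """
    if not trials:
        raise ValidationError("at least one trial required")
    rounded = []
    for start, stop in trials:
        if stop <= start:
            raise ValidationError(f"trial stop ({stop}) must exceed start ({start})")
        elapsed = Decimal(repr(stop)) - Decimal(repr(start))
        rounded.append(float(elapsed.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)))
    return min(rounded)
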