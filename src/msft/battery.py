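"""The six-item Senior Fitness Test battery and session-level scoring.

Three items are counted automatically from a gravity trace (chair stand,
arm curl, 2-min step), two flexibility distances are measured by the
practitioner and entered manually in signed centimetres (sit-and-reach,
back-scratch), and the 8-foot up-and-go is a stopwatch time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import norms
from .detect import DetectorConfig, count_repetitions, default_config
from .errors import ModeError, ValidationError
from .trace import GravityTrace

#: sanity bands for manual entry; counts must be non-negative integers
CM_BAND = (-60.0, 60.0)
TIME_BAND_S = (0.0, 120.0)


@dataclass(frozen=True)
class TestItem:
    code: str
    measure: str
    unit: str  # count | cm | s
    mode: str  # sensor | manual | stopwatch
    default_duration_s: float | None = None
    equipment_note: str = ""


ITEMS: Mapping[str, TestItem] = {
    item.code: item
    for item in (
        TestItem(
            "chair_stand",
            "lower-limb strength: full sit-to-stand cycles in 30 s",
            "count",
            "sensor",
            30.0,
        ),
        TestItem(
            "arm_curl",
            "upper-limb strength: full biceps curls in 30 s",
            "count",
            "sensor",
            30.0,
            equipment_note="hand weight 5 lb (2.27 kg) women / 8 lb (3.63 kg) men",
        ),
        TestItem(
            "two_min_step",
            "aerobic endurance: knee raises to mid-thigh height in 2 min",
            "count",
            "sensor",
            120.0,
        ),
        TestItem(
            "sit_reach",
            "lower-body flexibility: fingertip-to-toe distance, signed cm",
            "cm",
            "manual",
        ),
        TestItem(
            "back_scratch",
            "upper-body flexibility: middle-finger gap behind the back, signed cm",
            "cm",
            "manual",
        ),
        TestItem(
            "up_and_go",
            "agility/dynamic balance: time to stand, walk 8 ft around a cone, sit",
            "s",
            "stopwatch",
        ),
    )
}

SENSOR_ITEMS = tuple(c for c, it in ITEMS.items() if it.mode == "sensor")


@dataclass(frozen=True)
class ItemResult:
    test_code: str
    value: float
    source: str  # detector | manual
    trace_ref: str | None = None

    def __post_init__(self) -> None:
        _validate_value(self.test_code, self.value)


def _validate_value(test_code: str, value: float) -> None:
    try:
        item = ITEMS[test_code]
    except KeyError:
        raise ValidationError(
            f"unknown test_code {test_code!r}; expected one of {tuple(ITEMS)}"
        ) from None
    if item.unit == "count":
        if value < 0 or value != int(value):
            raise ValidationError(
                f"{test_code}: count must be a non-negative integer, got {value}"
            )
    elif item.unit == "cm":
        lo, hi = CM_BAND
        if not lo <= value <= hi:
            raise ValidationError(
                f"{test_code}: distance {value} cm outside sanity band [{lo}, {hi}] cm"
            )
    else:  # seconds
        lo, hi = TIME_BAND_S
        if not lo < value <= hi:
            raise ValidationError(
                f"{test_code}: time {value} s outside sanity band ({lo}, {hi}] s"
            )


def run_sensor_item(
    test_code: str,
    trace: GravityTrace,
    config: DetectorConfig | None = None,
    trace_ref: str | None = None,
) -> ItemResult:
    """Count repetitions for a sensor item and wrap them as a result."""
    item = ITEMS.get(test_code)
    if item is None:
        raise ValidationError(f"unknown test_code {test_code!r}")
    if item.mode != "sensor":
        raise ModeError(f"{test_code} is a {item.mode} item, not sensor-based")
    detection = count_repetitions(trace, config or default_config(test_code))
    return ItemResult(
        test_code=test_code,
        value=float(detection.reps),
        source="detector",
        trace_ref=trace_ref,
    )


def enter_manual_item(test_code: str, value: float) -> ItemResult:
    """Validate and record a practitioner-entered value (cm or stopwatch s)."""
    item = ITEMS.get(test_code)
    if item is None:
        raise ValidationError(f"unknown test_code {test_code!r}")
    if item.mode == "sensor":
        raise ModeError(f"{test_code} is sensor-based; use run_sensor_item")
    return ItemResult(test_code=test_code, value=float(value), source="manual")


@dataclass
class SessionReport:
    classifications: dict[str, norms.NormClassification]
    completion: float  # fraction of the six items present
    missing: list[str] = field(default_factory=list)
    age: float | None = None


def session_summary(results: Sequence[ItemResult], age: float) -> SessionReport:
    """Classify each completed item against the age-band norms.

    Partially completed sessions are first-class: missing items are listed,
    never an error, so a resumed session can be summarised at any point.
    """
    if not results:
        raise ValidationError("at least one result required")
    seen: dict[str, ItemResult] = {}
    for res in results:
        if res.test_code in seen:
            raise ValidationError(f"duplicate result for {res.test_code}")
        seen[res.test_code] = res
    classifications = {
        code: norms.classify(code, age, res.value) for code, res in seen.items()
    }
    missing = [code for code in ITEMS if code not in seen]
    return SessionReport(
        classifications=classifications,
        completion=len(seen) / len(ITEMS),
        missing=missing,
        age=age,
    )
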