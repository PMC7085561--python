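"""Age-band reference values for the Senior Fitness Test and classification.

The reference table (Rikli–Jones community sample, sex-pooled mean and SD per
decade band 60–69 / 70–79 / 80–89) ships as a packaged CSV so alternative
tables — e.g. sex-specific ones — can be dropped in.  A result is labelled
below / within / above the normative band, operationalised as mean ± 1 SD by
default.  Ages outside 60–89 clamp to the nearest band and the
classification discloses the extrapolation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .errors import ValidationError

AGE_BANDS = ("60-69", "70-79", "80-89")

#: items where a larger value means worse performance (completion time)
LOWER_IS_BETTER = frozenset({"up_and_go"})


@dataclass(frozen=True)
class NormEntry:
    test_code: str
    age_band: str
    mean: float
    sd: float


@dataclass(frozen=True)
class NormClassification:
    test_code: str
    band_used: str
    z: float
    label: str  # below | within | above
    clamped_age: bool
    direction: str  # higher_is_better | lower_is_better


def _load_table(path=None) -> dict[tuple[str, str], NormEntry]:
    if path is None:
        src = resources.files("msft.data").joinpath("norms.csv")
        text = src.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    table: dict[tuple[str, str], NormEntry] = {}
    for row in csv.DictReader(text.splitlines()):
        entry = NormEntry(
            test_code=row["test_code"],
            age_band=row["age_band"],
            mean=float(row["mean"]),
            sd=float(row["sd"]),
        )
        if entry.sd <= 0:
            raise ValidationError(f"non-positive sd in norms table: {entry}")
        table[(entry.test_code, entry.age_band)] = entry
    return table


_TABLE = _load_table()
NORM_TEST_CODES = tuple(sorted({code for code, _ in _TABLE}))


def _band_for_age(age: float) -> tuple[str, bool]:
    if age < 60:
        return "60-69", True
    if age < 70:
        return "60-69", False
    if age < 80:
        return "70-79", False
    if age < 90:
        return "80-89", False
    return "80-89", True


def lookup_norm(test_code: str, age: float) -> NormEntry:
    """Reference mean/SD for an item at a given age (clamped outside 60–89)."""
    if not 18 <= age <= 110:
        raise ValidationError(f"age {age} outside supported range [18, 110]")
    band, _ = _band_for_age(age)
    try:
        return _TABLE[(test_code, band)]
    except KeyError:
        raise ValidationError(
            f"unknown test_code {test_code!r}; expected one of {NORM_TEST_CODES}"
        ) from None


def classify(
    test_code: str, age: float, value: float, band_width_sd: float = 1.0
) -> NormClassification:
    """z-score a result against its age band and label it.

    ``within`` means |z| ≤ band_width_sd.  For time-scored items the z sign
    keeps its arithmetic meaning (positive = slower); ``direction`` lets the
    caller render "lower is better" correctly.
    """
    entry = lookup_norm(test_code, age)
    band, clamped = _band_for_age(age)
    z = (value - entry.mean) / entry.sd
    if abs(z) <= band_width_sd:
        label = "within"
    elif z < 0:
        label = "below"
    else:
        label = "above"
    direction = "lower_is_better" if test_code in LOWER_IS_BETTER else "higher_is_better"
    return NormClassification(
        test_code=test_code,
        band_used=band,
        z=z,
        label=label,
        clamped_age=clamped,
        direction=direction,
    )
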