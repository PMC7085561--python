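"""System Usability Scale scoring.

Ten Likert items (1 = strongly disagree … 5 = strongly agree) of alternating
polarity.  Odd-numbered items contribute (answer − 1), even-numbered ones
(5 − answer); the sum of contributions times 2.5 yields a 0–100 score.
A mean below 50 is labelled unacceptable and above 70 good; the open middle,
including both boundaries, is marginal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError

N_ITEMS = 10


@dataclass(frozen=True)
class SusResponse:
    rater_id: str
    items: tuple

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValidationError(
                f"SUS response must have exactly {N_ITEMS} items, got {len(self.items)}"
            )
        for i, item in enumerate(self.items, start=1):
            if item != int(item) or not 1 <= item <= 5:
                raise ValidationError(
                    f"item {i}: answers must be integers in [1, 5], got {item!r}"
                )


@dataclass(frozen=True)
class SusSummary:
    per_rater_scores: tuple
    mean_score: float
    label: str  # unacceptable | marginal | good


def sus_score(resp: SusResponse) -> float:
    """Score one questionnaire on the 0–100 scale."""
    contributions = 0
    for i, answer in enumerate(resp.items, start=1):
        contributions += (answer - 1) if i % 2 == 1 else (5 - answer)
    return 2.5 * contributions


def sus_label(mean_score: float) -> str:
    if mean_score < 50:
        return "unacceptable"
    if mean_score > 70:
        return "good"
    return "marginal"


def sus_aggregate(responses: Sequence[SusResponse]) -> SusSummary:
    """Mean score across raters with the acceptability label."""
    if not responses:
        raise ValidationError("at least one response required")
    scores = tuple(sus_score(r) for r in responses)
    mean_score = sum(scores) / len(scores)
    return SusSummary(
        per_rater_scores=scores, mean_score=mean_score, label=sus_label(mean_score)
    )


def read_responses(path) -> list[SusResponse]:
    """Read a ``rater_id,q1..q10`` CSV of questionnaire answers."""
    responses = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                items = tuple(int(row[f"q{i}"]) for i in range(1, N_ITEMS + 1))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValidationError(
                    f"rater {row.get('rater_id')!r}: need integer columns q1..q{N_ITEMS}"
                ) from exc
            responses.append(SusResponse(rater_id=str(row["rater_id"]), items=items))
    if not responses:
        raise ValidationError("no responses in file")
    return responses
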