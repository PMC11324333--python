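"""Scoring of the five self-report instruments and the immersion rating.

Five instruments are administered on a seven-point Likert scale: the
Simulator Sickness Questionnaire (SSQ, 16 symptom items, before and after
training), the Immersive Tendency Questionnaire (ITQ, before), and the
Presence (PQ), Game Engagement (GEQ) and Universal Enjoyment (UEQ)
questionnaires (after).  Each answer sheet is normalized uniformly: the sum
of item scores divided by the total possible score (7 x number of items).
Note that under 1-7 anchoring the attainable floor of the normalized score
is 1/7, not 0.

The objective immersion rating of each system (a checklist-derived raw
score out of a maximum) is normalized to [0, 1] to position the system on
the reality-virtuality continuum; the physical-reality arm defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "INSTRUMENTS",
    "LIKERT_MIN",
    "LIKERT_MAX",
    "QuestionnaireResponse",
    "ImmersionRating",
    "normalize_likert",
    "normalize_immersion",
]

INSTRUMENTS: tuple[str, ...] = ("SSQ", "ITQ", "PQ", "GEQ", "UEQ")
LIKERT_MIN = 1
LIKERT_MAX = 7
SSQ_N_ITEMS = 16


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One completed answer sheet: instrument, phase, and item scores (1-7)."""

    instrument: str
    phase: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise ConfigurationError(
                f"unknown instrument {self.instrument!r}; expected one of {INSTRUMENTS}"
            )
        if self.phase not in ("pre", "post"):
            raise ConfigurationError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        items = tuple(int(i) for i in self.items)
        object.__setattr__(self, "items", items)
        if len(items) == 0:
            raise ConfigurationError("questionnaire has no items")
        if any(i < LIKERT_MIN or i > LIKERT_MAX for i in items):
            raise ConfigurationError(
                f"item scores must lie in [{LIKERT_MIN}, {LIKERT_MAX}]"
            )
        if self.instrument == "SSQ" and len(items) != SSQ_N_ITEMS:
            raise ConfigurationError(
                f"SSQ has {SSQ_N_ITEMS} symptom items, got {len(items)}"
            )


@dataclass(frozen=True)
class ImmersionRating:
    """Checklist-derived immersion points for one system."""

    raw_score: float
    max_score: float
    group: str

    def __post_init__(self) -> None:
        if self.group not in ("PR", "AR", "VR"):
            raise ConfigurationError(f"group must be PR/AR/VR, got {self.group!r}")
        if self.max_score < 0 or not 0 <= self.raw_score <= max(self.max_score, 0):
            raise ConfigurationError("require 0 <= raw_score <= max_score")
        if self.group == "PR" and self.raw_score != 0:
            raise ConfigurationError("the physical-reality system has immersion 0")


def normalize_likert(resp: QuestionnaireResponse | Sequence[int]) -> float:
    """Normalized questionnaire score: sum of items over 7 x item count.

    Accepts a :class:`QuestionnaireResponse` or a bare item sequence.  The
    result lies in (0, 1]; the floor under 1-7 anchoring is 1/7.
    """
    items = resp.items if isinstance(resp, QuestionnaireResponse) else tuple(resp)
    if len(items) == 0:
        raise ConfigurationError("questionnaire has no items")
    arr = np.asarray(items)
    if arr.min() < LIKERT_MIN or arr.max() > LIKERT_MAX:
        raise ConfigurationError(f"item scores must lie in [{LIKERT_MIN}, {LIKERT_MAX}]")
    return float(arr.sum() / (LIKERT_MAX * arr.size))


def normalize_immersion(rating: ImmersionRating) -> float:
    """Immersion score normalized to [0, 1]; the PR system returns 0."""
    if rating.group == "PR":
        return 0.0
    if rating.max_score == 0:
        raise ConfigurationError("max_score must be positive")
    return float(rating.raw_score / rating.max_score)
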