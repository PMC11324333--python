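"""Functional reach metrics for the eight-direction seated star reach test.

Subjects sit without foot support and reach as far as possible in eight
principal directions: front (F), front-dominant (FD), dominant (D),
back-dominant (BD), back (B), back-nondominant (BND), nondominant (ND) and
front-nondominant (FND).  The functional reach test score (FRTS) for a
direction is the distance between the start and the farthest fingertip
position reached in that trial.  Training targets per direction are placed
at the baseline FRTS (basic), 10 % farther (medium) and 20 % farther (hard);
reaching them scores 1, 2 and 3 points per bout, accumulated over the
96 training bouts (12 rounds x 8 directions).

Coordinate frame: origin at the neutral seated trunk position, x toward the
dominant side, y forward, units meters; the eight directions sit at 45
degree increments with F along +y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, DataQualityError
from .preprocess import TimeSeriesPlanar

__all__ = [
    "DIRECTIONS",
    "direction_unit_vector",
    "ReachTrial",
    "FrtsResult",
    "TargetSet",
    "frts",
    "place_targets",
    "reach_task_score",
    "N_TRAINING_BOUTS",
    "MAX_TASK_SCORE",
]

#: The eight reach directions in counterclockwise order starting at front.
DIRECTIONS: tuple[str, ...] = ("F", "FND", "ND", "BND", "B", "BD", "D", "FD")

#: Angle of each direction from the +x (dominant-side) axis, degrees.
DIRECTION_ANGLES_DEG: dict[str, float] = {
    "F": 90.0,
    "FD": 45.0,
    "D": 0.0,
    "BD": -45.0,
    "B": -90.0,
    "BND": -135.0,
    "ND": 180.0,
    "FND": 135.0,
}

N_TRAINING_ROUNDS = 12
N_TRAINING_BOUTS = 96  # 12 rounds x 8 directions
MAX_TASK_SCORE = 3 * N_TRAINING_BOUTS

#: Target level multipliers relative to the baseline FRTS.
TARGET_LEVEL_FACTORS: dict[str, float] = {"basic": 1.0, "medium": 1.10, "hard": 1.20}


def direction_unit_vector(direction: str) -> np.ndarray:
    """Unit vector of a reach direction in the seated frame (x dominant, y forward)."""
    try:
        angle = np.deg2rad(DIRECTION_ANGLES_DEG[direction])
    except KeyError:
        raise ConfigurationError(
            f"unknown direction {direction!r}; expected one of {sorted(DIRECTIONS)}"
        ) from None
    return np.array([np.cos(angle), np.sin(angle)])


@dataclass(frozen=True)
class ReachTrial:
    """One directional reach: fingertip and trunk center-of-mass trajectories.

    ``start_position`` is the first fingertip sample; the trunk COM series
    covers the same time span as the fingertip series.
    """

    direction: str
    fingertip: TimeSeriesPlanar
    com: TimeSeriesPlanar
    start_position: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in DIRECTION_ANGLES_DEG:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        object.__setattr__(
            self, "start_position", np.asarray(self.start_position, dtype=float)
        )


@dataclass(frozen=True)
class FrtsResult:
    """FRTS value with the index of the farthest sample (earliest on ties)."""

    distance: float
    index: int


def frts(
    trial: ReachTrial,
    use: str = "fingertip",
    mode: str = "euclidean",
) -> FrtsResult:
    """Functional reach test score of one trial.

    The score is the maximum over samples of the distance from the start
    position to the chosen trajectory (``use`` = ``"fingertip"`` or
    ``"com"``).  ``mode="euclidean"`` (default) uses the straight-line
    distance; ``mode="projection"`` uses the displacement projected onto the
    trial's nominal direction vector.  Ties are broken by the earliest
    sample.
    """
    if use not in ("fingertip", "com"):
        raise ConfigurationError(f"use must be 'fingertip' or 'com', got {use!r}")
    series = trial.fingertip if use == "fingertip" else trial.com
    if series.n_samples == 0:
        raise DataQualityError("empty trajectory")
    start = series.values[0] if use == "com" else trial.start_position
    disp = series.values - start
    if mode == "euclidean":
        dist = np.linalg.norm(disp, axis=1)
    elif mode == "projection":
        u = direction_unit_vector(trial.direction)
        dist = disp[:, : u.size] @ u
    else:
        raise ConfigurationError(f"mode must be 'euclidean' or 'projection', got {mode!r}")
    idx = int(np.argmax(dist))  # argmax returns the first maximizer
    return FrtsResult(distance=float(dist[idx]), index=idx)


@dataclass(frozen=True)
class TargetSet:
    """Per-direction basic/medium/hard target positions and distances.

    ``distances[direction]`` maps level name to the along-direction distance
    from the start (m); ``positions[direction]`` to the planar target point.
    Hard > medium > basic for every direction by construction.
    """

    distances: Mapping[str, Mapping[str, float]]
    positions: Mapping[str, Mapping[str, np.ndarray]]
    start: np.ndarray

    def level_reached(self, direction: str, reach_distance: float) -> int:
        """Highest target level (1 basic, 2 medium, 3 hard) whose distance is
        covered by ``reach_distance``; 0 if even the basic target is missed."""
        level = 0
        for i, name in enumerate(("basic", "medium", "hard"), start=1):
            if reach_distance >= self.distances[direction][name] - 1e-12:
                level = i
        return level


def place_targets(
    frts_by_direction: Mapping[str, float], start: Sequence[float] = (0.0, 0.0)
) -> TargetSet:
    """Place the three-level targets from baseline FRTS values.

    The basic target sits at the baseline farthest reach (distance = FRTS
    along the direction's unit vector from ``start``); medium and hard sit
    10 % and 20 % of FRTS farther.
    """
    start = np.asarray(start, dtype=float)
    distances: dict[str, dict[str, float]] = {}
    positions: dict[str, dict[str, np.ndarray]] = {}
    for direction, value in frts_by_direction.items():
        if direction not in DIRECTION_ANGLES_DEG:
            raise ConfigurationError(f"unknown direction {direction!r}")
        if not value > 0:
            raise ConfigurationError(
                f"FRTS for direction {direction} must be positive, got {value}"
            )
        u = direction_unit_vector(direction)
        distances[direction] = {
            name: value * factor for name, factor in TARGET_LEVEL_FACTORS.items()
        }
        positions[direction] = {
            name: start + u * d for name, d in distances[direction].items()
        }
    return TargetSet(distances=distances, positions=positions, start=start)


def reach_task_score(bout_levels: Iterable[int]) -> int:
    """Cumulative reach task score over the 96 training bouts.

    Each bout contributes its reached target level: 1 (basic), 2 (medium),
    3 (hard), or 0 for a miss.  Requires exactly 96 bout levels; the result
    lies in [0, 288].
    """
    levels = np.asarray(list(bout_levels))
    if levels.size != N_TRAINING_BOUTS:
        raise ConfigurationError(
            f"expected {N_TRAINING_BOUTS} bout levels, got {levels.size}"
        )
    if not np.issubdtype(levels.dtype, np.integer):
        raise ConfigurationError("bout levels must be integers")
    if levels.min() < 0 or levels.max() > 3:
        raise ConfigurationError("bout levels must lie in {0, 1, 2, 3}")
    return int(levels.sum())
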