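"""Nine-hole-peg touch-trace segmentation and kinematic features.

Each hand performs 4 repetitions of place-then-remove drags of a virtual
peg.  Per movement we measure path length (screen points), duration
(seconds) and speed (points/second); per (hand, phase) cell the five
statistical summaries over the available repetitions give the canonical
60-feature set: 2 hands x 2 phases x 3 quantities x 5 summaries.

Coordinates stay in screen points — no physical calibration is applied, so
features are device-relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .session_io import Hand, PegMovement, Phase, SensorSession

logger = logging.getLogger(__name__)

HANDS = (Hand.DOMINANT, Hand.SUBORDINATE)
PHASES = (Phase.PLACE, Phase.REMOVE)
QUANTITIES = ("distance", "duration", "speed")
SUMMARIES = ("mean", "median", "min", "max", "sd")
N_REPETITIONS = 4

#: the 60 canonical feature names, e.g. "dominant_remove_distance_mean"
HAND_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{hand.value}_{phase.value}_{qty}_{summ}"
    for hand in HANDS
    for phase in PHASES
    for qty in QUANTITIES
    for summ in SUMMARIES
)
assert len(HAND_FEATURE_NAMES) == 60


@dataclass
class MovementKinematics:
    hand: Hand
    phase: Phase
    repetition: int
    distance: float   # polyline path length, points
    duration: float   # seconds
    speed: float      # points / second


def kinematics(movement: PegMovement) -> MovementKinematics:
    """Path length, duration and speed of one drag.

    distance = sum of Euclidean distances between consecutive samples;
    duration = t_last - t_first; speed = distance / duration.
    """
    t = np.asarray(movement.t, dtype=float)
    x = np.asarray(movement.x, dtype=float)
    y = np.asarray(movement.y, dtype=float)
    if len(t) < 2:
        raise ValueError("degenerate movement: fewer than 2 samples")
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("degenerate movement: zero duration")
    distance = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    return MovementKinematics(
        hand=movement.hand,
        phase=movement.phase,
        repetition=movement.repetition,
        distance=distance,
        duration=duration,
        speed=distance / duration,
    )


def segment_movements(
    t: Sequence[float],
    x: Sequence[float],
    y: Sequence[float],
    event: Sequence[str],
    hand: Hand,
) -> list[PegMovement]:
    """Split one hand's raw touch stream into tagged peg movements.

    Drags are contiguous down -> move* -> up runs; in task order drag
    2k is the place and drag 2k+1 the remove of repetition k+1.  Drags
    with fewer than 2 samples are discarded with a warning; more than 4
    repetitions per phase is an error.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    starts = [i for i, e in enumerate(event) if e == "down"]
    if len(starts) > 2 * N_REPETITIONS:
        raise ValueError(
            f"{len(starts)} drags imply more than {N_REPETITIONS} repetitions per phase"
        )
    movements: list[PegMovement] = []
    for k, start in enumerate(starts):
        end = start
        while end < len(event) and event[end] != "up":
            end += 1
        stop = min(end + 1, len(event))
        phase = PHASES[k % 2]
        repetition = k // 2 + 1
        if stop - start < 2:
            logger.warning(
                "discarding %s/%s repetition %d drag with <2 samples",
                hand.value,
                phase.value,
                repetition,
            )
            continue
        movements.append(
            PegMovement(
                hand=hand,
                phase=phase,
                repetition=repetition,
                t=t[start:stop],
                x=x[start:stop],
                y=y[start:stop],
                event=list(event[start:stop]),
            )
        )
    return movements


def _summaries(values: list[float]) -> dict[str, Optional[float]]:
    if not values:
        return {s: None for s in SUMMARIES}
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(np.mean(arr)),
        "median": float(np.median(arr)),
        "min": float(np.min(arr)),
        "max": float(np.max(arr)),
        # sample SD over repetitions; undefined with a single repetition
        "sd": float(np.std(arr, ddof=1)) if len(arr) >= 2 else None,
    }


def extract_hand_features(session: SensorSession) -> dict[str, Optional[float]]:
    """The 60-feature kinematic summary for one session.

    Missing repetitions propagate: cells with no movements are all-missing,
    cells with one movement have a missing SD.
    """
    kins: list[MovementKinematics] = []
    for mv in session.peg_movements:
        try:
            kins.append(kinematics(mv))
        except ValueError as exc:
            logger.warning("skipping movement (%s)", exc)

    features: dict[str, Optional[float]] = {}
    for hand in HANDS:
        for phase in PHASES:
            cell = [k for k in kins if k.hand == hand and k.phase == phase]
            for qty in QUANTITIES:
                values = [getattr(k, qty) for k in cell]
                for summ, value in _summaries(values).items():
                    features[f"{hand.value}_{phase.value}_{qty}_{summ}"] = value
    return features
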