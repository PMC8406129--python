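"""Session file I/O and the in-memory data model.

A *session* is everything one participant recorded in one app completion:
up to two short walks (user acceleration + device attitude + pedometer),
the touchscreen nine-hole-peg traces, the CIPN20/PRO-CTCAE survey, and
demographics.  Sessions are stored one JSON document per participant under
the versioned schema ``neuropipe-session/1``; a cohort is a directory of
session files plus a ``manifest.csv`` (``participant_id``, ``file``, and an
optional group-label column used as a screening override).

Conventions fixed by this schema
--------------------------------
* Time is seconds since task start, floating point, strictly increasing
  within a recording.  The nominal sampling rate is stored as data; the
  per-sample ``t`` is authoritative.
* Attitude quaternions are ``(w, x, y, z)``, unit norm, and rotate
  device-frame vectors into the world frame (world z up).
* Missing data is an *absent key*, never a sentinel number: the pipeline
  must distinguish "declined pedometer permission" from "walked zero
  metres".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Optional

import numpy as np

SCHEMA_VERSION = "neuropipe-session/1"

#: unit-quaternion norm tolerance
QUAT_NORM_TOL = 1e-6

N_CIPN20_ITEMS = 20


class SessionValidationError(ValueError):
    """A session violates the documented schema; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class Placement(str, Enum):
    POCKET_OR_BAG = "pocket_or_bag"
    IN_HAND = "in_hand"
    UNKNOWN = "unknown"


class Replication(str, Enum):
    FORWARD = "forward"
    BACK = "back"


class Hand(str, Enum):
    DOMINANT = "dominant"
    SUBORDINATE = "subordinate"


class Phase(str, Enum):
    PLACE = "place"
    REMOVE = "remove"


TOUCH_EVENTS = ("down", "move", "up")


@dataclass
class PedometerRecord:
    """Distance walked and step count as reported by the device pedometer."""

    distance_m: float
    step_count: int


@dataclass
class WalkRecording:
    """One straight-line walk: acceleration, attitude, and pedometer data.

    ``t`` is shape (n,), ``a_user`` (n, 3) gravity-removed acceleration in
    the device frame (m/s^2), ``q_attitude`` (n, 4) unit quaternions
    (w, x, y, z) rotating device-frame vectors into the world frame.
    """

    t: np.ndarray
    a_user: np.ndarray
    q_attitude: np.ndarray
    sampling_rate_hz: float
    placement: Placement = Placement.UNKNOWN
    replication: Replication = Replication.FORWARD
    pedometer: Optional[PedometerRecord] = None

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


@dataclass
class PegMovement:
    """One drag of the virtual peg: a touch trace tagged by hand/phase/rep."""

    hand: Hand
    phase: Phase
    repetition: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    event: list[str] = field(default_factory=list)


@dataclass
class SurveyResponse:
    """CIPN20 items plus PRO-CTCAE and the falls diary.

    ``cipn20_items`` has exactly 20 slots (items 1-20 of the instrument:
    1-9 sensory, 10-17 motor, 18-20 autonomic), each an ordinal 1-4 or
    ``None`` if unanswered.
    """

    cipn20_items: list[Optional[int]] = field(
        default_factory=lambda: [None] * N_CIPN20_ITEMS
    )
    proctcae_severity: Optional[int] = None
    proctcae_interference: Optional[int] = None
    fell_since_last_chemo: Optional[bool] = None


@dataclass
class SensorSession:
    """All task recordings and survey answers for one participant."""

    participant_id: str
    walks: list[WalkRecording] = field(default_factory=list)
    peg_movements: list[PegMovement] = field(default_factory=list)
    survey: Optional[SurveyResponse] = None
    pedometer_permission: bool = False
    demographics: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _require_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise SessionValidationError(name, "contains non-finite values")


def _require_strictly_increasing(t: np.ndarray, name: str) -> None:
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise SessionValidationError(name, "timestamps not strictly increasing")


def validate_walk(walk: WalkRecording, name: str = "walk") -> None:
    t = np.asarray(walk.t, dtype=float)
    a = np.asarray(walk.a_user, dtype=float)
    q = np.asarray(walk.q_attitude, dtype=float)
    if a.shape != (len(t), 3):
        raise SessionValidationError(f"{name}.a_user", f"shape {a.shape} != ({len(t)}, 3)")
    if q.shape != (len(t), 4):
        raise SessionValidationError(
            f"{name}.q_attitude", f"shape {q.shape} != ({len(t)}, 4)"
        )
    _require_finite(t, f"{name}.t")
    _require_finite(a, f"{name}.a_user")
    _require_finite(q, f"{name}.q_attitude")
    if len(t) and t[0] < 0:
        raise SessionValidationError(f"{name}.t", "negative timestamp")
    _require_strictly_increasing(t, f"{name}.t")
    if len(q):
        norms = np.linalg.norm(q, axis=1)
        bad = np.abs(norms - 1.0) > QUAT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise SessionValidationError(
                f"{name}.q_attitude",
                f"quaternion {i} has norm {norms[i]:.6g}, expected 1 within {QUAT_NORM_TOL}",
            )
    if walk.pedometer is not None:
        if walk.pedometer.distance_m < 0:
            raise SessionValidationError(f"{name}.pedometer.distance_m", "negative")
        if walk.pedometer.step_count < 0:
            raise SessionValidationError(f"{name}.pedometer.step_count", "negative")


def validate_movement(mv: PegMovement, name: str = "peg_movement") -> None:
    t = np.asarray(mv.t, dtype=float)
    x = np.asarray(mv.x, dtype=float)
    y = np.asarray(mv.y, dtype=float)
    if mv.repetition not in (1, 2, 3, 4):
        raise SessionValidationError(f"{name}.repetition", f"{mv.repetition} not in 1..4")
    if len(t) < 2:
        raise SessionValidationError(f"{name}.trace", "fewer than 2 samples")
    if len(x) != len(t) or len(y) != len(t):
        raise SessionValidationError(f"{name}.trace", "t/x/y lengths differ")
    _require_finite(t, f"{name}.t")
    _require_finite(x, f"{name}.x")
    _require_finite(y, f"{name}.y")
    _require_strictly_increasing(t, f"{name}.t")
    if mv.event:
        if len(mv.event) != len(t):
            raise SessionValidationError(f"{name}.event", "length differs from trace")
        for e in mv.event:
            if e not in TOUCH_EVENTS:
                raise SessionValidationError(f"{name}.event", f"unknown event {e!r}")


def validate_survey(survey: SurveyResponse, name: str = "survey") -> None:
    items = survey.cipn20_items
    if len(items) != N_CIPN20_ITEMS:
        raise SessionValidationError(
            f"{name}.cipn20_items", f"expected {N_CIPN20_ITEMS} slots, got {len(items)}"
        )
    for i, v in enumerate(items):
        if v is not None and v not in (1, 2, 3, 4):
            raise SessionValidationError(
                f"{name}.cipn20_items[{i}]", f"value {v!r} not in {{1,2,3,4}}"
            )


def validate_session(session: SensorSession) -> None:
    """Check every documented invariant; raise SessionValidationError on the
    first violation, naming the offending field."""
    if not session.participant_id:
        raise SessionValidationError("participant_id", "empty")
    if len(session.walks) > 2:
        raise SessionValidationError("walks", f"{len(session.walks)} walks, at most 2")
    for i, w in enumerate(session.walks):
        validate_walk(w, name=f"walks[{i}]")
    for i, m in enumerate(session.peg_movements):
        validate_movement(m, name=f"peg_movements[{i}]")
    if session.survey is not None:
        validate_survey(session.survey)


# ---------------------------------------------------------------------------
# JSON (de)serialisation
# ---------------------------------------------------------------------------


def _walk_to_json(walk: WalkRecording) -> dict:
    d: dict[str, Any] = {
        "sampling_rate_hz": float(walk.sampling_rate_hz),
        "placement": walk.placement.value,
        "replication": walk.replication.value,
        "samples": {
            "t": np.asarray(walk.t, dtype=float).tolist(),
            "a_user": np.asarray(walk.a_user, dtype=float).tolist(),
            "q_attitude": np.asarray(walk.q_attitude, dtype=float).tolist(),
        },
    }
    if walk.pedometer is not None:
        d["pedometer"] = {
            "distance_m": float(walk.pedometer.distance_m),
            "step_count": int(walk.pedometer.step_count),
        }
    return d


def _walk_from_json(d: dict) -> WalkRecording:
    samples = d.get("samples", {})
    ped = d.get("pedometer")
    return WalkRecording(
        t=np.asarray(samples.get("t", []), dtype=float),
        a_user=np.asarray(samples.get("a_user", []), dtype=float).reshape(-1, 3),
        q_attitude=np.asarray(samples.get("q_attitude", []), dtype=float).reshape(-1, 4),
        sampling_rate_hz=float(d["sampling_rate_hz"]),
        placement=Placement(d.get("placement", "unknown")),
        replication=Replication(d.get("replication", "forward")),
        pedometer=None
        if ped is None
        else PedometerRecord(float(ped["distance_m"]), int(ped["step_count"])),
    )


def _movement_to_json(mv: PegMovement) -> dict:
    return {
        "hand": mv.hand.value,
        "phase": mv.phase.value,
        "repetition": int(mv.repetition),
        "trace": {
            "t": np.asarray(mv.t, dtype=float).tolist(),
            "x": np.asarray(mv.x, dtype=float).tolist(),
            "y": np.asarray(mv.y, dtype=float).tolist(),
            "event": list(mv.event),
        },
    }


def _movement_from_json(d: dict) -> PegMovement:
    tr = d["trace"]
    return PegMovement(
        hand=Hand(d["hand"]),
        phase=Phase(d["phase"]),
        repetition=int(d["repetition"]),
        t=np.asarray(tr["t"], dtype=float),
        x=np.asarray(tr["x"], dtype=float),
        y=np.asarray(tr["y"], dtype=float),
        event=list(tr.get("event", [])),
    )


def _survey_to_json(s: SurveyResponse) -> dict:
    d: dict[str, Any] = {
        "cipn20_items": [None if v is None else int(v) for v in s.cipn20_items]
    }
    if s.proctcae_severity is not None:
        d["proctcae_severity"] = int(s.proctcae_severity)
    if s.proctcae_interference is not None:
        d["proctcae_interference"] = int(s.proctcae_interference)
    if s.fell_since_last_chemo is not None:
        d["fell_since_last_chemo"] = bool(s.fell_since_last_chemo)
    return d


def _survey_from_json(d: dict) -> SurveyResponse:
    return SurveyResponse(
        cipn20_items=[None if v is None else int(v) for v in d["cipn20_items"]],
        proctcae_severity=d.get("proctcae_severity"),
        proctcae_interference=d.get("proctcae_interference"),
        fell_since_last_chemo=d.get("fell_since_last_chemo"),
    )


def session_to_json(session: SensorSession) -> dict:
    d: dict[str, Any] = {
        "schema": SCHEMA_VERSION,
        "participant_id": session.participant_id,
        "pedometer_permission": bool(session.pedometer_permission),
        "walks": [_walk_to_json(w) for w in session.walks],
        "peg_movements": [_movement_to_json(m) for m in session.peg_movements],
    }
    if session.survey is not None:
        d["survey"] = _survey_to_json(session.survey)
    if session.demographics:
        d["demographics"] = dict(session.demographics)
    return d


def session_from_json(d: dict) -> SensorSession:
    if d.get("schema") != SCHEMA_VERSION:
        raise SessionValidationError(
            "schema", f"expected {SCHEMA_VERSION!r}, got {d.get('schema')!r}"
        )
    if "participant_id" not in d:
        raise SessionValidationError("participant_id", "missing")
    survey = d.get("survey")
    return SensorSession(
        participant_id=str(d["participant_id"]),
        walks=[_walk_from_json(w) for w in d.get("walks", [])],
        peg_movements=[_movement_from_json(m) for m in d.get("peg_movements", [])],
        survey=None if survey is None else _survey_from_json(survey),
        pedometer_permission=bool(d.get("pedometer_permission", False)),
        demographics=dict(d.get("demographics", {})),
    )


def read_session(path: str | Path) -> SensorSession:
    """Read and validate one session file.

    Raises ``SessionValidationError`` (naming the field) for any schema or
    invariant violation, including non-monotone timestamps and non-unit
    quaternions.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SessionValidationError("<document>", f"not valid JSON: {exc}") from exc
    session = session_from_json(doc)
    validate_session(session)
    return session


def write_session(session: SensorSession, path: str | Path) -> None:
    """Validate and write one session file.

    Refuses to serialise invalid sessions (e.g. NaN acceleration).  Output
    is deterministic (sorted keys) and round-trips through
    :func:`read_session` to an equal in-memory session.
    """
    validate_session(session)
    doc = session_to_json(session)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


# ---------------------------------------------------------------------------
# equality helper (numpy fields defeat dataclass __eq__)
# ---------------------------------------------------------------------------


def walks_equal(a: WalkRecording, b: WalkRecording) -> bool:
    return (
        np.array_equal(a.t, b.t)
        and np.array_equal(a.a_user, b.a_user)
        and np.array_equal(a.q_attitude, b.q_attitude)
        and a.sampling_rate_hz == b.sampling_rate_hz
        and a.placement == b.placement
        and a.replication == b.replication
        and (
            (a.pedometer is None and b.pedometer is None)
            or (
                a.pedometer is not None
                and b.pedometer is not None
                and a.pedometer.distance_m == b.pedometer.distance_m
                and a.pedometer.step_count == b.pedometer.step_count
            )
        )
    )


def movements_equal(a: PegMovement, b: PegMovement) -> bool:
    return (
        a.hand == b.hand
        and a.phase == b.phase
        and a.repetition == b.repetition
        and np.array_equal(a.t, b.t)
        and np.array_equal(a.x, b.x)
        and np.array_equal(a.y, b.y)
        and a.event == b.event
    )


def sessions_equal(a: SensorSession, b: SensorSession) -> bool:
    """Exact equality of the in-memory representation (used by round-trip
    tests; float values compare bitwise, which JSON round-trips preserve)."""
    return (
        a.participant_id == b.participant_id
        and a.pedometer_permission == b.pedometer_permission
        and a.demographics == b.demographics
        and len(a.walks) == len(b.walks)
        and all(walks_equal(x, y) for x, y in zip(a.walks, b.walks))
        and len(a.peg_movements) == len(b.peg_movements)
        and all(movements_equal(x, y) for x, y in zip(a.peg_movements, b.peg_movements))
        and a.survey == b.survey
    )
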