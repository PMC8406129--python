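import numpy as np
import pytest

from neuropipe.session_io import (
    Hand,
    PedometerRecord,
    PegMovement,
    Phase,
    Placement,
    Replication,
    SensorSession,
    SurveyResponse,
    WalkRecording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_walk(
    duration_s=5.0,
    fs=50.0,
    placement=Placement.POCKET_OR_BAG,
    pedometer=None,
    a_world=None,
    quat=(1.0, 0.0, 0.0, 0.0),
    seed=0,
):
    """A simple valid walk with a constant attitude quaternion."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    if a_world is None:
        a_world = np.column_stack(
            [
                1.5 * np.sin(2 * np.pi * 1.8 * t) + 0.5 * np.sin(2 * np.pi * t / t[-1]),
                0.3 * np.sin(2 * np.pi * 0.9 * t) + rng.normal(0, 0.05, n),
                2.0 * np.sin(2 * np.pi * 1.8 * t + 0.3),
            ]
        )
    q = np.tile(np.asarray(quat, dtype=float), (n, 1))
    return WalkRecording(
        t=t,
        a_user=np.asarray(a_world, dtype=float),
        q_attitude=q,
        sampling_rate_hz=fs,
        placement=placement,
        replication=Replication.FORWARD,
        pedometer=pedometer,
    )


def make_movement(
    hand=Hand.DOMINANT, phase=Phase.REMOVE, repetition=1, points=None, duration=1.0
):
    if points is None:
        points = [(0.0, 0.0), (3.0, 4.0)]
    points = np.asarray(points, dtype=float)
    n = len(points)
    return PegMovement(
        hand=hand,
        phase=phase,
        repetition=repetition,
        t=np.linspace(0.0, duration, n),
        x=points[:, 0],
        y=points[:, 1],
        event=["down"] + ["move"] * (n - 2) + ["up"] if n > 1 else ["down"],
    )


def make_survey(items=None, **kwargs):
    if items is None:
        items = [1] * 20
    return SurveyResponse(cipn20_items=list(items), **kwargs)


@pytest.fixture
def simple_session():
    return SensorSession(
        participant_id="P001",
        walks=[make_walk(pedometer=PedometerRecord(10.8, 20))],
        peg_movements=[make_movement()],
        survey=make_survey([2, 1, 3, 1] + [1] * 16),
        pedometer_permission=True,
        demographics={"age": 55},
    )
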