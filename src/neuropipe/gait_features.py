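"""Gait preprocessing, quality control, and per-axis feature extraction.

The walking task records gravity-removed user acceleration in the device
frame together with the device attitude.  Processing follows the study
protocol:

1. rotate user acceleration into the world frame using the per-sample
   attitude quaternion (vertical = world z);
2. among the two horizontal world axes, call *heading* the axis whose
   integrated-acceleration velocity has the larger SD, and *sway* the
   other;
3. exclude walks shorter than 3.50 s (early termination), walks performed
   with the phone in the hand, and walks during which the phone moved
   inside the pocket or bag (gravity direction in the device frame rotates
   by more than a threshold, default 30 degrees);
4. step length = pedometer distance / step count, only where the
   participant granted pedometer permission;
5. per axis, time-domain summaries plus frequency-domain summaries of the
   Welch power spectrum normalised to a probability distribution over
   frequency bins (Shannon entropy, median frequency, frequency at maximal
   power, spectral skewness/kurtosis).

Walking forward and walking back are two replications; features are
averaged over the non-excluded replications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .session_io import PedometerRecord, Placement, SensorSession, WalkRecording

logger = logging.getLogger(__name__)

AXES = ("vertical", "heading", "sway")
TIME_FEATURES = ("mean", "sd", "skewness", "kurtosis", "energy")
FREQ_FEATURES = (
    "shannon_entropy",
    "median_freq_hz",
    "max_power_freq_hz",
    "spectral_skewness",
    "spectral_kurtosis",
)

#: canonical gait feature names: step length + 3 axes x 10 summaries = 31
GAIT_FEATURE_NAMES: tuple[str, ...] = ("step_length_m",) + tuple(
    f"{axis}_{feat}" for axis in AXES for feat in TIME_FEATURES + FREQ_FEATURES
)


class QCReason(str, Enum):
    NONE = "none"
    EARLY_TERMINATION = "early_termination"
    IN_HAND = "in_hand"
    PHONE_MOVED = "phone_moved"


@dataclass
class QCResult:
    excluded: bool
    reason: QCReason
    duration_s: float


@dataclass
class GaitConfig:
    """Tunables for QC and spectral estimation (all config-exposed)."""

    min_duration_s: float = 3.50        # strict <: 3.50 s itself is retained
    gravity_rotation_deg: float = 30.0  # phone-moved threshold
    gravity_window_s: float = 0.5
    psd_segment_len: int = 256          # Welch nperseg cap
    psd_window: str = "hann"
    psd_overlap: float = 0.5
    psd_band_hz: tuple[float, float] = (0.0, 25.0)
    max_freq_mode: str = "dominant"     # or "edge95": 95% spectral edge
    min_spectral_samples: int = 64


@dataclass
class WorldFrameWalk:
    t: np.ndarray
    a_vertical: np.ndarray
    a_heading: np.ndarray
    a_sway: np.ndarray
    heading_axis_index: int
    qc: QCResult


# ---------------------------------------------------------------------------
# rotation and axis assignment
# ---------------------------------------------------------------------------


def _rotations(q_wxyz: np.ndarray) -> Rotation:
    # schema stores (w,x,y,z); scipy expects (x,y,z,w)
    q = np.asarray(q_wxyz, dtype=float)
    return Rotation.from_quat(q[:, [1, 2, 3, 0]])


def rotate_to_world(walk: WalkRecording) -> np.ndarray:
    """Rotate per-sample user acceleration into the world frame.

    Returns an (n, 3) array with columns (world x, world y, world z);
    vertical acceleration is the z column.
    """
    if len(walk.q_attitude) == 0:
        raise ValueError("orientation unavailable")
    return _rotations(walk.q_attitude).apply(np.asarray(walk.a_user, dtype=float))


def assign_axes(world_accel: np.ndarray, t: np.ndarray) -> tuple[int, int]:
    """Identify the heading axis among the two horizontal world axes.

    Velocity per horizontal axis is the cumulative trapezoidal integral of
    acceleration (no drift correction); heading is the axis with the larger
    velocity SD, sway the other.  An exact tie breaks deterministically to
    the first axis with a logged warning.
    """
    a = np.asarray(world_accel, dtype=float)
    t = np.asarray(t, dtype=float)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 samples for axis assignment")
    sds = [
        float(np.std(cumulative_trapezoid(a[:, i], t, initial=0.0))) for i in (0, 1)
    ]
    if sds[0] == sds[1]:
        logger.warning("velocity SDs exactly equal; tie-break to first axis")
        return 0, 1
    heading = int(np.argmax(sds))
    return heading, 1 - heading


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def gravity_rotation_deg(walk: WalkRecording, window_s: float = 0.5) -> float:
    """Angle (degrees) between the mean device-frame gravity direction in
    the first and last ``window_s`` of the walk."""
    t = np.asarray(walk.t, dtype=float)
    rot = _rotations(walk.q_attitude)
    # world "up" expressed in the device frame, per sample
    g_dev = rot.inv().apply(np.array([0.0, 0.0, 1.0]))
    first = g_dev[t <= t[0] + window_s]
    last = g_dev[t >= t[-1] - window_s]
    u = first.mean(axis=0)
    v = last.mean(axis=0)
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def qc_walk(walk: WalkRecording, config: GaitConfig | None = None) -> QCResult:
    """Apply the exclusion rules to one walk.

    Precedence when several apply: early termination (duration strictly
    shorter than 3.50 s), then in-hand placement, then phone movement.
    """
    config = config or GaitConfig()
    duration = walk.duration_s
    if duration < config.min_duration_s:
        return QCResult(True, QCReason.EARLY_TERMINATION, duration)
    if walk.placement == Placement.IN_HAND:
        return QCResult(True, QCReason.IN_HAND, duration)
    if len(walk.q_attitude) >= 2:
        angle = gravity_rotation_deg(walk, config.gravity_window_s)
        if angle > config.gravity_rotation_deg:
            return QCResult(True, QCReason.PHONE_MOVED, duration)
    return QCResult(False, QCReason.NONE, duration)


# ---------------------------------------------------------------------------
# step length
# ---------------------------------------------------------------------------


def step_length(
    pedometer: Optional[PedometerRecord], permission: bool = True
) -> Optional[float]:
    """Pedometer step length: distance / step count; ``None`` when the
    participant declined pedometer permission or the record is degenerate."""
    if not permission or pedometer is None:
        return None
    if pedometer.step_count == 0:
        logger.info("step_length: zero step count, value missing")
        return None
    return pedometer.distance_m / pedometer.step_count


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------


def spectral_summaries(freqs: np.ndarray, power: np.ndarray) -> dict[str, float]:
    """Frequency-domain summaries of a one-sided spectrum on (0, Nyquist].

    ``power`` is normalised to a discrete probability distribution p over
    the frequency bins; returns Shannon entropy (nats), median frequency
    (smallest bin with cumulative p >= 0.5, no interpolation), the
    frequency at maximal power, and the third/fourth standardised moments
    of frequency under p.
    """
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(power, dtype=float)
    if p.size == 0 or np.any(p < 0):
        raise ValueError("degenerate spectrum")
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum")
    p = p / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    cum = np.cumsum(p)
    median_freq = float(f[np.searchsorted(cum, 0.5)])
    max_power_freq = float(f[int(np.argmax(p))])
    mu = float((f * p).sum())
    var = float(((f - mu) ** 2 * p).sum())
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((f - mu) ** 3 * p).sum() / sd**3)
        kurt = float(((f - mu) ** 4 * p).sum() / var**2)
    else:  # all mass in one bin
        skew, kurt = 0.0, 0.0
    return {
        "shannon_entropy": entropy,
        "median_freq_hz": median_freq,
        "max_power_freq_hz": max_power_freq,
        "spectral_skewness": skew,
        "spectral_kurtosis": kurt,
    }


def _spectral_edge(f: np.ndarray, p: np.ndarray, frac: float = 0.95) -> float:
    cum = np.cumsum(p / p.sum())
    return float(f[np.searchsorted(cum, frac)])


def spectral_features(
    series: np.ndarray, sampling_rate_hz: float, config: GaitConfig | None = None
) -> dict[str, float]:
    """Welch PSD (linear detrend, Hann window, 50% overlap, segment length
    min(256, n)) restricted to the configured band, then
    :func:`spectral_summaries` on the normalised spectrum."""
    config = config or GaitConfig()
    x = np.asarray(series, dtype=float)
    if len(x) < config.min_spectral_samples:
        raise ValueError(
            f"series too short for spectral features "
            f"({len(x)} < {config.min_spectral_samples})"
        )
    if np.allclose(x, x[0]):
        raise ValueError("degenerate spectrum")
    nperseg = min(config.psd_segment_len, len(x))
    f, pxx = sps.welch(
        x,
        fs=sampling_rate_hz,
        window=config.psd_window,
        nperseg=nperseg,
        noverlap=int(nperseg * config.psd_overlap),
        detrend="linear",
    )
    lo, hi = config.psd_band_hz
    keep = (f > lo) & (f <= hi)
    f, pxx = f[keep], pxx[keep]
    out = spectral_summaries(f, pxx)
    if config.max_freq_mode == "edge95":
        out["max_power_freq_hz"] = _spectral_edge(f, pxx, 0.95)
    return out


def time_features(series: np.ndarray) -> dict[str, float]:
    """Time-domain summaries: mean, sample SD, skewness, kurtosis (Pearson,
    i.e. non-excess), mean signal energy."""
    x = np.asarray(series, dtype=float)
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "skewness": float(spstats.skew(x)),
        "kurtosis": float(spstats.kurtosis(x, fisher=False)),
        "energy": float(np.mean(x**2)),
    }


# ---------------------------------------------------------------------------
# per-walk / per-session extraction
# ---------------------------------------------------------------------------


def process_walk(walk: WalkRecording, config: GaitConfig | None = None) -> WorldFrameWalk:
    """QC one walk and, if retained, resolve the world-frame axis series."""
    config = config or GaitConfig()
    qc = qc_walk(walk, config)
    if qc.excluded:
        empty = np.empty(0)
        return WorldFrameWalk(empty, empty, empty, empty, -1, qc)
    world = rotate_to_world(walk)
    heading, sway = assign_axes(world, walk.t)
    return WorldFrameWalk(
        t=np.asarray(walk.t, dtype=float),
        a_vertical=world[:, 2],
        a_heading=world[:, heading],
        a_sway=world[:, sway],
        heading_axis_index=heading,
        qc=qc,
    )


def walk_features(
    walk: WalkRecording, config: GaitConfig | None = None
) -> Optional[dict[str, float]]:
    """Axis features for one walk, or ``None`` if the walk is excluded."""
    config = config or GaitConfig()
    wf = process_walk(walk, config)
    if wf.qc.excluded:
        return None
    out: dict[str, float] = {}
    for axis, series in (
        ("vertical", wf.a_vertical),
        ("heading", wf.a_heading),
        ("sway", wf.a_sway),
    ):
        for name, value in time_features(series).items():
            out[f"{axis}_{name}"] = value
        try:
            spec = spectral_features(series, walk.sampling_rate_hz, config)
        except ValueError:
            spec = {name: np.nan for name in FREQ_FEATURES}
        for name, value in spec.items():
            out[f"{axis}_{name}"] = value
    return out


def extract_gait_features(
    session: SensorSession, config: GaitConfig | None = None
) -> tuple[dict[str, Optional[float]], list[QCResult]]:
    """Session-level gait features plus the per-walk QC results.

    Features are averaged over non-excluded walks (forward and back are two
    replications; with one excluded, only the completed walk is used); step
    length is the mean of the per-walk pedometer step lengths where
    permission was granted.  All-excluded sessions yield all-missing
    features.
    """
    config = config or GaitConfig()
    qc_results: list[QCResult] = []
    per_walk: list[dict[str, float]] = []
    step_lengths: list[float] = []
    for walk in session.walks:
        qc = qc_walk(walk, config)
        qc_results.append(qc)
        feats = walk_features(walk, config)
        if feats is not None:
            per_walk.append(feats)
        sl = step_length(walk.pedometer, session.pedometer_permission)
        if sl is not None:
            step_lengths.append(sl)

    features: dict[str, Optional[float]] = {name: None for name in GAIT_FEATURE_NAMES}
    if step_lengths:
        features["step_length_m"] = float(np.mean(step_lengths))
    if per_walk:
        for name in GAIT_FEATURE_NAMES:
            if name == "step_length_m":
                continue
            vals = [w[name] for w in per_walk if np.isfinite(w[name])]
            if vals:
                features[name] = float(np.mean(vals))
    return features, qc_results
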