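"""Synthetic cohort generator.

The study data this pipeline targets (26 chemotherapy patients: 17 CIPN
cases, 9 controls) is not publicly deposited, so every stage is exercised
on generated cohorts that reproduce the *statistical structure* the
analysis assumes rather than any one patient's data.

Architecture: one latent severity scalar per participant (controls low,
cases high) drives every channel coherently —

* shorter pedometer step length (group anchors 0.78 m controls / 0.54 m
  cases, between-subject SD 0.08 m);
* a sway-axis acceleration process whose spectral concentration decreases
  with severity (mixture of a narrowband tone and band-limited noise, the
  broadband weight increasing with severity) while its RMS amplitude is
  held fixed, so only *spectral* sway features carry signal;
* dominant-hand peg-removal distance scaled down by
  ``1 - (1 - ratio) * severity``;
* ordinal survey items noisy-monotone in severity, with the case /
  control classification rule satisfied by construction.

Nonadherence (declined pedometer permission, phone in hand, phone moving
in the pocket, early termination, missing survey) is applied at
configurable rates and recorded in the manifest for truth-checking.

The single latent factor induces the cross-channel correlation that the
discriminant analysis exploits; features the generator does not perturb
(vertical/heading spectra, sway time-domain summaries, placement-phase
kinematics) act as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .session_io import (
    Hand,
    PedometerRecord,
    PegMovement,
    Phase,
    Placement,
    Replication,
    SensorSession,
    SurveyResponse,
    WalkRecording,
    write_session,
)

#: features the default generator perturbs through the latent severity
#: (used by recovery tests: the VIP ranking should surface these)
PLANTED_EFFECT_FEATURES: tuple[str, ...] = (
    "sway_shannon_entropy",
    "sway_median_freq_hz",
    "sway_max_power_freq_hz",
    "sway_spectral_skewness",
    "sway_spectral_kurtosis",
    "dominant_remove_distance_mean",
    "dominant_remove_distance_median",
    "dominant_remove_distance_min",
    "dominant_remove_distance_max",
    "dominant_remove_distance_sd",
    "dominant_remove_speed_mean",
    "dominant_remove_speed_median",
    "dominant_remove_speed_min",
    "dominant_remove_speed_max",
    "dominant_remove_speed_sd",
)


@dataclass
class CohortConfig:
    """Cohort composition, planted effect sizes, noise, and nonadherence."""

    n_cases: int = 17
    n_controls: int = 9
    seed: int = 0
    sampling_rate_hz: float = 50.0

    # walk geometry / gait signal
    walk_duration_s: float = 6.0
    steps_per_walk: int = 7
    step_freq_hz: float = 1.8
    sway_tone_hz: float = 0.9
    sway_amp_ms2: float = 0.4
    accel_noise_sd: float = 0.05

    # planted effects
    step_length_control_m: float = 0.78
    step_length_case_m: float = 0.54
    step_length_sd_m: float = 0.08
    sway_broadband_frac_control: float = 0.15
    sway_broadband_frac_case: float = 0.85
    peg_remove_distance_ratio_case: float = 0.70

    # peg task
    peg_place_distance_pts: float = 280.0
    peg_remove_distance_pts: float = 320.0
    peg_distance_rel_sd: float = 0.08
    peg_duration_s: float = 0.7
    peg_duration_sd_s: float = 0.08

    # nonadherence rates
    rate_no_pedometer: float = 0.5
    rate_in_hand: float = 0.08
    rate_phone_moved: float = 0.08
    rate_early_termination: float = 0.08
    rate_missing_survey: float = 0.08

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be >= 0")
        for name in (
            "rate_no_pedometer",
            "rate_in_hand",
            "rate_phone_moved",
            "rate_early_termination",
            "rate_missing_survey",
        ):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {r}")

    def null(self) -> "CohortConfig":
        """A copy with every planted effect switched off (negative control)."""
        return replace(
            self,
            step_length_case_m=self.step_length_control_m,
            sway_broadband_frac_case=self.sway_broadband_frac_control,
            peg_remove_distance_ratio_case=1.0,
        )


def _lerp(lo: float, hi: float, s: float) -> float:
    return lo + (hi - lo) * s


def _random_quaternion_wxyz(rng: np.random.Generator) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))  # scipy order (x,y,z,w)


def _bandlimited_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(size=n)
    sos = sps.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, white)


def generate_gait_trace(
    severity: float,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    replication: Replication = Replication.FORWARD,
    step_length_m: Optional[float] = None,
    pedometer_permission: bool = True,
    planted_qc: str = "none",
) -> WalkRecording:
    """One walk with the severity-dependent sway spectrum planted.

    ``planted_qc`` is one of ``none | in_hand | phone_moved |
    early_termination`` and makes the walk fail the corresponding QC rule
    by construction.
    """
    fs = config.sampling_rate_hz
    if planted_qc == "early_termination":
        duration = rng.uniform(2.0, 3.4)
    else:
        duration = max(4.0, config.walk_duration_s + rng.normal(0, 0.5))
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    f_step = config.step_freq_hz
    phase = rng.uniform(0, 2 * np.pi, size=4)
    # heading: step-frequency oscillation + start/stop surge (dominates the
    # integrated-velocity SD, anchoring axis assignment)
    a_heading = (
        1.5 * np.sin(2 * np.pi * f_step * t + phase[0])
        + 0.5 * np.sin(4 * np.pi * f_step * t + phase[1])
        + 0.8 * np.sin(2 * np.pi * t / t[-1])
        + rng.normal(0, config.accel_noise_sd, size=n)
    )
    a_vertical = (
        2.0 * np.sin(2 * np.pi * f_step * t + phase[2])
        + 0.6 * np.sin(4 * np.pi * f_step * t + phase[3])
        + rng.normal(0, config.accel_noise_sd, size=n)
    )
    # sway: tone/broadband mixture, RMS held fixed so only the spectrum moves
    b = _lerp(config.sway_broadband_frac_control, config.sway_broadband_frac_case, severity)
    tone = np.sin(2 * np.pi * config.sway_tone_hz * t + rng.uniform(0, 2 * np.pi))
    noise = _bandlimited_noise(n, fs, cutoff_hz=10.0, rng=rng)
    tone /= np.sqrt(np.mean(tone**2))
    noise /= np.sqrt(np.mean(noise**2))
    sway = (1 - b) * tone + b * noise
    sway = sway / np.sqrt(np.mean(sway**2)) * config.sway_amp_ms2

    # world frame: z vertical; heading on world x or y at random
    a_world = np.empty((n, 3))
    h_axis = int(rng.integers(0, 2))
    a_world[:, h_axis] = a_heading
    a_world[:, 1 - h_axis] = sway
    a_world[:, 2] = a_vertical

    # constant pocket attitude; a phone-moved walk flips 90 deg mid-walk
    rot0 = _random_quaternion_wxyz(rng)
    rots = [rot0] * n
    if planted_qc == "phone_moved":
        # flip 90 deg about an axis orthogonal to the device-frame gravity
        # direction, so the gravity vector itself moves by a full 90 deg
        g0 = rot0.inv().apply([0.0, 0.0, 1.0])
        axis = np.cross(g0, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(g0, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        rot1 = rot0 * Rotation.from_rotvec(np.pi / 2 * axis)
        half = n // 2
        rots = [rot0] * half + [rot1] * (n - half)
    a_user = np.empty((n, 3))
    q_wxyz = np.empty((n, 4))
    for i, rot in enumerate(rots):
        a_user[i] = rot.inv().apply(a_world[i])
        qx, qy, qz, qw = rot.as_quat()
        q_wxyz[i] = (qw, qx, qy, qz)

    pedometer = None
    if pedometer_permission and step_length_m is not None:
        pedometer = PedometerRecord(
            distance_m=step_length_m * config.steps_per_walk,
            step_count=config.steps_per_walk,
        )
    return WalkRecording(
        t=t,
        a_user=a_user,
        q_attitude=q_wxyz,
        sampling_rate_hz=fs,
        placement=Placement.IN_HAND if planted_qc == "in_hand" else Placement.POCKET_OR_BAG,
        replication=replication,
        pedometer=pedometer,
    )


def generate_peg_trace(
    severity: float,
    hand: Hand,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[PegMovement]:
    """4 place + 4 remove drags for one hand; dominant-hand removals are
    shortened by the planted severity effect."""
    movements: list[PegMovement] = []
    t0 = 0.0
    for rep in (1, 2, 3, 4):
        for phase in (Phase.PLACE, Phase.REMOVE):
            target = (
                config.peg_place_distance_pts
                if phase == Phase.PLACE
                else config.peg_remove_distance_pts
            )
            if hand == Hand.DOMINANT and phase == Phase.REMOVE:
                target *= 1.0 - (1.0 - config.peg_remove_distance_ratio_case) * severity
            chord = max(30.0, target * (1.0 + rng.normal(0, config.peg_distance_rel_sd)))
            duration = max(0.3, config.peg_duration_s + rng.normal(0, config.peg_duration_sd_s))
            npts = 12
            theta = rng.uniform(0, 2 * np.pi)
            x0, y0 = rng.uniform(100, 300, size=2)
            frac = np.linspace(0.0, 1.0, npts)
            x = x0 + chord * frac * np.cos(theta)
            y = y0 + chord * frac * np.sin(theta)
            # small perpendicular tremor (keeps path length ~ chord)
            perp = rng.normal(0, 1.0, size=npts)
            perp[0] = perp[-1] = 0.0
            x += -np.sin(theta) * perp
            y += np.cos(theta) * perp
            t = t0 + duration * frac
            movements.append(
                PegMovement(
                    hand=hand,
                    phase=phase,
                    repetition=rep,
                    t=t,
                    x=x,
                    y=y,
                    event=["down"] + ["move"] * (npts - 2) + ["up"],
                )
            )
            t0 = t[-1] + rng.uniform(0.3, 0.8)
    return movements


def generate_survey(
    severity: float, is_case: bool, rng: np.random.Generator
) -> SurveyResponse:
    """Ordinal survey responses noisy-monotone in severity; the case /
    control classification rule holds by construction (cases always have a
    first-four item >= 3, controls never do)."""
    items: list[int] = []
    for _ in range(20):
        u = 2.6 * severity + rng.normal(0, 0.8)
        items.append(1 + int(u > 0.7) + int(u > 1.5) + int(u > 2.2))
    if is_case:
        if max(items[:4]) < 3:
            items[int(rng.integers(0, 4))] = 3
    else:
        for i in range(4):
            items[i] = min(items[i], 2)
    sev = int(np.clip(round(3.5 * severity + rng.normal(0, 0.5)), 0, 4))
    interf = int(np.clip(round(3.0 * severity + rng.normal(0, 0.6)), 0, 4))
    fell = bool(rng.random() < 0.05 + 0.30 * severity)
    return SurveyResponse(
        cipn20_items=items,
        proctcae_severity=sev,
        proctcae_interference=interf,
        fell_since_last_chemo=fell,
    )


def generate_session(
    participant_id: str,
    severity: float,
    is_case: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[SensorSession, dict]:
    """One participant's full session plus its ground-truth manifest row."""
    pedometer_permission = bool(rng.random() >= config.rate_no_pedometer)
    u = rng.random()
    if u < config.rate_in_hand:
        planted_qc = "in_hand"
    elif u < config.rate_in_hand + config.rate_phone_moved:
        planted_qc = "phone_moved"
    elif u < config.rate_in_hand + config.rate_phone_moved + config.rate_early_termination:
        planted_qc = "early_termination"
    else:
        planted_qc = "none"
    survey_missing = bool(rng.random() < config.rate_missing_survey)

    L = _lerp(config.step_length_control_m, config.step_length_case_m, severity)
    L = max(0.2, L + rng.normal(0, config.step_length_sd_m))

    walks = [
        generate_gait_trace(
            severity,
            config,
            rng,
            replication=rep,
            step_length_m=L,
            pedometer_permission=pedometer_permission,
            planted_qc=planted_qc,
        )
        for rep in (Replication.FORWARD, Replication.BACK)
    ]
    pegs = generate_peg_trace(severity, Hand.DOMINANT, config, rng)
    pegs += generate_peg_trace(severity, Hand.SUBORDINATE, config, rng)
    survey = None if survey_missing else generate_survey(severity, is_case, rng)

    session = SensorSession(
        participant_id=participant_id,
        walks=walks,
        peg_movements=pegs,
        survey=survey,
        pedometer_permission=pedometer_permission,
        demographics={"group_truth": "case" if is_case else "control"},
    )
    # ground-truth step length recorded exactly as the extractor computes it
    ped = walks[0].pedometer
    truth_row = {
        "participant_id": participant_id,
        "group": "case" if is_case else "control",
        "severity": severity,
        "step_length_true": (
            ped.distance_m / ped.step_count if ped is not None else np.nan
        ),
        "pedometer_permission": pedometer_permission,
        "accel_qc_planted": planted_qc,
        "survey_missing": survey_missing,
    }
    return session, truth_row


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> tuple[list[SensorSession], pd.DataFrame]:
    """Generate the full cohort; optionally write session files + manifest.

    Deterministic: the same config (including seed) yields byte-identical
    files.  Controls draw severity ~ U(0, 0.15), cases ~ U(0.85, 1), so the
    single latent factor separates the groups on every planted channel.
    """
    rng = np.random.default_rng(config.seed)
    sessions: list[SensorSession] = []
    rows: list[dict] = []
    labels = ["case"] * config.n_cases + ["control"] * config.n_controls
    for i, group in enumerate(labels):
        severity = (
            float(rng.uniform(0.85, 1.0))
            if group == "case"
            else float(rng.uniform(0.0, 0.15))
        )
        session, row = generate_session(
            f"P{i + 1:03d}", severity, group == "case", config, rng
        )
        sessions.append(session)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.insert(1, "file", manifest["participant_id"] + ".json")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for session, row in zip(sessions, rows):
            write_session(session, out / f"{session.participant_id}.json")
        manifest.to_csv(out / "manifest.csv", index=False)
    return sessions, manifest
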