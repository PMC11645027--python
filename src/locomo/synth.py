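"""Synthetic FTSTS cohort generator.

Emulates the data a trunk-worn IMU records while a participant stands up
from and sits back onto a chair five times in a row, together with cohort
metadata (locomotive-syndrome stage, GLFS-25 score, demographics).

Signal model
------------
Each sit-stand-sit cycle is built from a smooth pitch-angle profile: a
logistic flexion-extension ramp for the rise and its mirror for sitting
down. Pitch angular velocity is the analytic derivative, so every postural
transition produces exactly one dominant negative trough whose time is
known in closed form and recorded as a ground-truth event. AP and SI
accelerations are biphasic/monophasic pulses centred on the same instants;
ML is postural sway plus noise. The per-group kinematic defaults (longer
cycles and weaker peaks at higher stage) are configuration values chosen
to produce separable classes — they are not measurements of any cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DomainError
from .recording import ImuRecording

GROUPS = ("Young", "NonLS", "Stage1", "Stage2")

#: GLFS-25 staging cut-offs for older adults: score < 7 is non-LS,
#: 7..15 is stage 1, >= 16 is stage 2. Young participants are not staged.
STAGE1_MIN = 7
STAGE2_MIN = 16
GLFS_MAX = 100  # 25 items, each graded 0..4

EARTH_GRAVITY = 9.80665  # m/s^2


def assign_stage(glfs_score: int) -> str:
    """Map a GLFS-25 total score to a locomotive-syndrome stage.

    Parameters
    ----------
    glfs_score : int
        Total questionnaire score in [0, 100].

    Returns
    -------
    str
        ``"NonLS"`` (< 7), ``"Stage1"`` (7..15) or ``"Stage2"`` (>= 16).
    """
    if not 0 <= glfs_score <= GLFS_MAX:
        raise DomainError(f"GLFS-25 score must be in [0, {GLFS_MAX}], got {glfs_score}")
    if glfs_score < STAGE1_MIN:
        return "NonLS"
    if glfs_score < STAGE2_MIN:
        return "Stage1"
    return "Stage2"


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics and staging for one participant."""

    participant_id: str
    group: str
    sex: str
    age_years: float
    glfs_score: int | None  # None for Young participants (not staged)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"unknown group {self.group!r}")
        if self.group == "Young":
            if not 18 <= self.age_years <= 45:
                raise ConfigError(f"Young age must be 18..45 yr, got {self.age_years}")
        else:
            if self.age_years < 60:
                raise ConfigError(f"older-group age must be >= 60 yr, got {self.age_years}")
            if self.glfs_score is None:
                raise ConfigError("older participants require a GLFS-25 score")
            if assign_stage(self.glfs_score) != self.group:
                raise ConfigError(
                    f"GLFS score {self.glfs_score} is inconsistent with group {self.group}"
                )


@dataclass(frozen=True)
class KinematicParams:
    """Kinematic shape of the simulated sit-stand-sit cycles.

    cycle_duration_s is the mean full-cycle length; per-cycle durations are
    log-normal with coefficient of variation ``duration_cv``.
    ``peak_pitch_velocity`` is the depth (deg/s) of the flexion trough in
    the gyroscope pitch channel. Peak accelerations are pulse amplitudes in
    m/s^2; ``tremor_noise_sd`` is additive white accelerometer noise.
    """

    cycle_duration_s: float = 2.0
    duration_cv: float = 0.08
    peak_pitch_velocity: float = 80.0
    peak_ap_accel: float = 2.0
    peak_si_accel: float = 1.6
    tremor_noise_sd: float = 0.05
    inter_cycle_pause_s: float = 0.4

    def __post_init__(self) -> None:
        for name in ("cycle_duration_s", "peak_pitch_velocity", "peak_ap_accel", "peak_si_accel"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("duration_cv", "tremor_noise_sd", "inter_cycle_pause_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


#: Per-group defaults: higher stage -> slower cycles, weaker peaks.
#: Separable-class configuration values, not population measurements.
DEFAULT_GROUP_KINEMATICS: dict[str, KinematicParams] = {
    "Young": KinematicParams(1.5, 0.08, 100.0, 2.5, 2.0, 0.05, 0.30),
    "NonLS": KinematicParams(1.8, 0.08, 85.0, 2.0, 1.6, 0.05, 0.40),
    "Stage1": KinematicParams(2.4, 0.10, 70.0, 1.5, 1.2, 0.06, 0.50),
    "Stage2": KinematicParams(3.0, 0.12, 55.0, 1.1, 0.9, 0.07, 0.60),
}

#: GLFS-25 score ranges sampled per group (uniform; only cut-offs matter).
DEFAULT_GLFS_RANGES: dict[str, tuple[int, int] | None] = {
    "Young": None,
    "NonLS": (0, 6),
    "Stage1": (7, 15),
    "Stage2": (16, 40),
}


def _logistic(t: np.ndarray, centre: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - centre) / tau))


def _trough_pulse(t: np.ndarray, centre: float, tau: float) -> np.ndarray:
    """Unit-depth negative pulse: derivative shape of a logistic ramp."""
    s = _logistic(t, centre, tau)
    return -4.0 * s * (1.0 - s)


def _biphasic_pulse(t: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    """Unit-amplitude odd pulse (accelerate then brake around the transition)."""
    u = (t - centre) / sigma
    return -u * np.exp(0.5 * (1.0 - u * u))  # extrema +-1 at u = -+1


def _bump(t: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    u = (t - centre) / sigma
    return np.exp(-0.5 * u * u)


def simulate_ftsts(
    profile: ParticipantProfile,
    params: KinematicParams | None = None,
    n_cycles: int = 5,
    sample_rate_hz: float = 100.0,
    seed: int = 0,
    add_gravity: bool = False,
) -> ImuRecording:
    """Simulate one instrumented five-time sit-to-stand test.

    Produces ``n_cycles`` smooth sit-stand-sit cycles whose pitch angular
    velocity has exactly one dominant trough per postural transition
    (2 * n_cycles in total), with matching AP/SI acceleration bursts.
    Per-cycle durations are log-normal with the configured mean and CV.
    Ground-truth seat-off/seat-on times are attached to the recording.
    Identical seeds give bit-identical recordings.

    Parameters
    ----------
    add_gravity : bool
        When true, a constant gravity projection is added to the SI
        channel, to exercise the zero-centering step downstream.
    """
    if n_cycles < 1:
        raise DomainError(f"n_cycles must be >= 1, got {n_cycles}")
    if sample_rate_hz <= 0:
        raise DomainError(f"sample_rate_hz must be positive, got {sample_rate_hz}")
    if params is None:
        params = DEFAULT_GROUP_KINEMATICS.get(profile.group, KinematicParams())
    rng = np.random.default_rng(seed)

    # Per-cycle durations: log-normal parameterised to the requested mean/CV.
    if params.duration_cv > 0:
        sigma2 = np.log1p(params.duration_cv**2)
        mu = np.log(params.cycle_duration_s) - 0.5 * sigma2
        durations = rng.lognormal(mu, np.sqrt(sigma2), size=n_cycles)
    else:
        durations = np.full(n_cycles, params.cycle_duration_s)

    lead = 1.0  # quiet sitting before the first rise and after the last descent
    total = lead + durations.sum() + params.inter_cycle_pause_s * (n_cycles - 1) + lead
    n = int(round(total * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    pitch = np.zeros(n)
    ap = np.zeros(n)
    si = np.zeros(n)
    events: list[tuple[str, float]] = []

    start = lead
    for d in durations:
        # Seat-off flexion at 25% of the cycle, seat-on at 75%.
        for frac, kind, si_sign in ((0.25, "seat_off", 1.0), (0.75, "seat_on", -1.0)):
            centre = start + frac * d
            tau = d / 12.0  # transition time-scale relative to cycle length
            pitch += params.peak_pitch_velocity * _trough_pulse(t, centre, tau)
            ap += params.peak_ap_accel * _biphasic_pulse(t, centre, 1.5 * tau)
            si += si_sign * params.peak_si_accel * _bump(t, centre, 1.5 * tau)
            events.append((kind, float(centre)))
        start += d + params.inter_cycle_pause_s

    # ML: slow postural sway, no transition structure.
    sway_f = 0.3 + 0.1 * rng.random()
    ml = 0.08 * params.peak_ap_accel * np.sin(2 * np.pi * sway_f * t + rng.uniform(0, 2 * np.pi))

    noise = params.tremor_noise_sd
    accel = np.column_stack([
        ml + rng.normal(0.0, noise, n) if noise > 0 else ml,
        ap + rng.normal(0.0, noise, n) if noise > 0 else ap,
        si + rng.normal(0.0, noise, n) if noise > 0 else si,
    ])
    if add_gravity:
        accel[:, 2] += EARTH_GRAVITY
    gyro_noise = 15.0 * noise  # deg/s of gyro noise per m/s^2 of accel noise
    gyro = np.column_stack([
        rng.normal(0.0, gyro_noise, n) if noise > 0 else np.zeros(n),
        pitch + (rng.normal(0.0, gyro_noise, n) if noise > 0 else 0.0),
        rng.normal(0.0, gyro_noise, n) if noise > 0 else np.zeros(n),
    ])
    return ImuRecording(
        sample_rate_hz=sample_rate_hz,
        accel=accel,
        gyro=gyro,
        ground_truth_events=events,
        participant_id=profile.participant_id,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and sampling distributions.

    Default group sizes (NonLS 47, Stage1 29, Stage2 49, Young 49; 174 in
    total) mirror the staged-cohort composition the classification stack is
    designed around, with the stage-1 group the under-represented class.
    ``between_subject_cv`` scales multiplicative jitter applied to each
    participant's mean cycle duration and peak amplitudes.
    """

    group_counts: dict[str, int] = field(
        default_factory=lambda: {"NonLS": 47, "Stage1": 29, "Stage2": 49, "Young": 49}
    )
    group_kinematics: dict[str, KinematicParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_KINEMATICS)
    )
    glfs_ranges: dict[str, tuple[int, int] | None] = field(
        default_factory=lambda: dict(DEFAULT_GLFS_RANGES)
    )
    n_cycles: int = 5
    sample_rate_hz: float = 100.0
    between_subject_cv: float = 0.08

    def __post_init__(self) -> None:
        for group, count in self.group_counts.items():
            if group not in GROUPS:
                raise ConfigError(f"unknown group {group!r}")
            if count < 1:
                raise ConfigError(f"group {group} count must be >= 1, got {count}")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")


def _draw_profile(group: str, index: int, config: CohortConfig, rng: np.random.Generator) -> ParticipantProfile:
    sex = "M" if rng.random() < 0.5 else "F"
    if group == "Young":
        age = float(rng.uniform(18, 45))
        glfs = None
    else:
        age = float(np.clip(rng.normal(73.0, 7.0), 60.0, 95.0))
        lo, hi = config.glfs_ranges[group]
        glfs = int(rng.integers(lo, hi + 1))
    return ParticipantProfile(f"{group}_{index:03d}", group, sex, age, glfs)


def _jitter_params(params: KinematicParams, cv: float, rng: np.random.Generator) -> KinematicParams:
    if cv <= 0:
        return params
    factors = rng.lognormal(-0.5 * np.log1p(cv**2), np.sqrt(np.log1p(cv**2)), size=4)
    return replace(
        params,
        cycle_duration_s=params.cycle_duration_s * factors[0],
        peak_pitch_velocity=params.peak_pitch_velocity * factors[1],
        peak_ap_accel=params.peak_ap_accel * factors[2],
        peak_si_accel=params.peak_si_accel * factors[3],
    )


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[list[ParticipantProfile], list[ImuRecording]]:
    """Generate one FTSTS recording per participant of a staged cohort.

    Deterministic under a fixed seed; GLFS scores of older participants
    always satisfy ``assign_stage(score) == group``.
    """
    if config is None:
        config = CohortConfig()
    root = np.random.SeedSequence(seed)
    profiles: list[ParticipantProfile] = []
    recordings: list[ImuRecording] = []
    for group in GROUPS:  # fixed iteration order for reproducibility
        count = config.group_counts.get(group, 0)
        if count == 0:
            continue
        for i in range(count):
            meta_seq, sim_seq = root.spawn(1)[0], root.spawn(1)[0]
            rng = np.random.default_rng(meta_seq)
            profile = _draw_profile(group, i, config, rng)
            params = _jitter_params(
                config.group_kinematics[group], config.between_subject_cv, rng
            )
            rec = simulate_ftsts(
                profile,
                params,
                n_cycles=config.n_cycles,
                sample_rate_hz=config.sample_rate_hz,
                seed=sim_seq,
            )
            profiles.append(profile)
            recordings.append(rec)
    return profiles, recordings


def cohort_manifest(profiles: list[ParticipantProfile]):
    """Cohort metadata as a DataFrame (columns participant_id,group,sex,age,glfs)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "group": [p.group for p in profiles],
            "sex": [p.sex for p in profiles],
            "age": [round(p.age_years, 1) for p in profiles],
            "glfs": [p.glfs_score if p.glfs_score is not None else "" for p in profiles],
        }
    )
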