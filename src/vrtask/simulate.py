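"""Synthetic sensor-stream simulation for the vestibular rotation task.

No raw participant recordings are publicly available for this task, so the
package generates seeded synthetic cohorts with the statistical structure
the downstream analysis assumes.  Each participant carries a latent movement
phenotype (pointing accuracy, hesitation rate, movement vigor, tilt wobble)
drawn from group-specific distributions; the group separation scales
linearly with a single ``effect_size`` knob, with ``effect_size = 0`` giving
a fully null cohort.

A simulated trial response covers only the pointing-back window (the phase
the tablet records): the device heading follows a minimum-jerk angular
trajectory from the post-rotation body heading to the reference bearing
plus a Normal pointing error, with an optional Poisson number of hesitation
pauses inserted.  Gyroscope channels are emitted as per-sample angular
increments in degrees (rate x 0.003 s sample period), which keeps the
downstream feature units literal.  Accelerometer channels carry the
tangential and centripetal acceleration of a hand-held arc plus gravity on
the vertical axis; the compass channel is emitted wrapped to [0, 360) so
north crossings produce genuine wraparound discontinuities.  Two artifacts
the preprocessing stage must correct are simulated: a 180-degree device
flip (with configurable probability) and the compass wraparound itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from vrtask.protocol import (
    TrialSpec,
    ReferencePoint,
    default_protocol,
    net_rotation,
    wrap_heading,
    wrap_signed,
)

__all__ = [
    "SensorStream",
    "PhenotypeParams",
    "ParticipantProfile",
    "SensorNoise",
    "CohortConfig",
    "Session",
    "sample_participant",
    "simulate_trial_response",
    "generate_cohort",
    "flip_transform",
    "stream_to_frame",
    "stream_from_frame",
    "save_cohort",
    "load_cohort",
    "GRAVITY_MS2",
]

GRAVITY_MS2 = 9.81
# Effective lever arm (m) of the hand-held device about the body axis; sets
# the scale that converts angular motion into linear acceleration.
ARM_RADIUS_M = 0.35


@dataclass
class SensorStream:
    """One pointing response: timestamped accelerometer/gyro/compass record.

    ``accel`` and ``gyro`` are (n, 3) arrays in device axes
    (x = forward/backward, y = left/right, z = up/down); accelerometer in
    m/s^2, gyroscope as per-sample angular increments in degrees.
    ``heading`` is the compass bearing in [0, 360).  ``truth`` holds
    simulator ground truth (inserted hesitation count, pointing error,
    continuous heading trajectory, flip state) for validation; it is never
    read by the analysis stages.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    heading: np.ndarray
    sample_period_s: float = 0.003
    flip_corrected: bool = False
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = self.t.shape[0]
        if n < 2:
            raise ValueError("stream must have at least 2 samples")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must have shape (n, 3)")
        if self.heading.shape != (n,):
            raise ValueError("heading must have shape (n,)")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.heading < 0) or np.any(self.heading >= 360):
            raise ValueError("heading must lie in [0, 360)")
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be positive")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    # Per-axis views, for readability at call sites.
    @property
    def accel_x(self) -> np.ndarray:
        return self.accel[:, 0]

    @property
    def accel_y(self) -> np.ndarray:
        return self.accel[:, 1]

    @property
    def accel_z(self) -> np.ndarray:
        return self.accel[:, 2]

    @property
    def gyro_x(self) -> np.ndarray:
        return self.gyro[:, 0]

    @property
    def gyro_y(self) -> np.ndarray:
        return self.gyro[:, 1]

    @property
    def gyro_z(self) -> np.ndarray:
        return self.gyro[:, 2]


@dataclass(frozen=True)
class PhenotypeParams:
    """Latent kinematic phenotype of one participant.

    heading_error_sd_deg : SD of the Normal pointing error per trial.
    heading_bias_deg     : systematic pointing bias (signed degrees).
    hesitation_rate_per_trial : Poisson mean of inserted stop-and-go pauses.
    jerk_scale           : multiplier on movement-related acceleration.
    tilt_wobble_sd       : SD (deg/sample) of off-axis gyro wobble.
    movement_duration_s  : total response duration in seconds.
    """

    heading_error_sd_deg: float
    heading_bias_deg: float
    hesitation_rate_per_trial: float
    jerk_scale: float
    tilt_wobble_sd: float
    movement_duration_s: float

    def __post_init__(self) -> None:
        for name in (
            "heading_error_sd_deg",
            "hesitation_rate_per_trial",
            "jerk_scale",
            "tilt_wobble_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.movement_duration_s <= 0:
            raise ValueError("movement_duration_s must be positive")


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    group: str  # "e33" or "e34"
    age: float
    sex: str  # "male" or "female"
    occupation: int
    phenotype: PhenotypeParams


@dataclass(frozen=True)
class SensorNoise:
    """Sensor-level (non-phenotype) noise of the simulated device."""

    accel_noise_sd: float = 0.05  # m/s^2 per axis, white
    heading_noise_sd: float = 0.3  # deg, low-pass filtered compass jitter


# Baseline (e33) phenotype means and the per-unit-effect-size group deltas
# added for the risk (e34) group.  The group effect is carried jointly by
# pointing accuracy, hesitation rate and movement vigor.
DEFAULT_BASE_PHENOTYPE: dict[str, float] = {
    "heading_error_sd_deg": 10.0,
    "heading_bias_deg": 0.0,
    "hesitation_rate_per_trial": 0.5,
    "jerk_scale": 1.0,
    "tilt_wobble_sd": 0.02,
    "movement_duration_s": 2.0,
}
DEFAULT_GROUP_DELTAS: dict[str, float] = {
    "heading_error_sd_deg": 8.0,
    "hesitation_rate_per_trial": 1.0,
    "jerk_scale": 0.5,
}

# Demographic marginals of the study sample (32 e33 / 21 e34, mean age ~63,
# mixed sex).  Group-specific departures from the pooled values are scaled
# by effect_size so that a zero-effect cohort is demographically null too.
_POOLED_AGE_MEAN = 63.36
_AGE_SD = 5.7
_GROUP_AGE_MEAN = {"e33": 63.63, "e34": 62.95}
_POOLED_MALE_FRAC = 23.0 / 53.0
_GROUP_MALE_FRAC = {"e33": 17.0 / 32.0, "e34": 6.0 / 21.0}
_N_OCCUPATIONS = 5


@dataclass
class CohortConfig:
    """Study-condition configuration for one synthetic cohort."""

    n_e33: int = 32
    n_e34: int = 21
    effect_size: float = 1.0
    flip_prob: float = 0.05
    wrap_guaranteed: bool = False
    seed: int = 0
    sample_period_s: float = 0.003
    base_phenotype: dict = field(default_factory=lambda: dict(DEFAULT_BASE_PHENOTYPE))
    group_deltas: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_DELTAS))
    noise: SensorNoise = field(default_factory=SensorNoise)
    # Hesitation pause geometry.
    pause_duration_s: float = 0.35
    max_hesitations: int = 3

    def __post_init__(self) -> None:
        if self.n_e33 < 0 or self.n_e34 < 0:
            raise ValueError("group sizes must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = SensorNoise(**d["noise"])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Session:
    """All nine trial responses of one participant, plus the recorded reference."""

    profile: ParticipantProfile
    reference: ReferencePoint
    streams: list  # one SensorStream per protocol trial, in trial order


def _group_mean(config: CohortConfig, group: str, name: str) -> float:
    base = float(config.base_phenotype[name])
    if group == "e34":
        base += config.effect_size * float(config.group_deltas.get(name, 0.0))
    return base


def sample_participant(
    group: str, config: CohortConfig, rng: np.random.Generator, participant_id: str = "p0"
) -> ParticipantProfile:
    """Draw one participant's demographics and latent phenotype.

    Strictly positive scale parameters are Gamma-distributed with a fixed
    shape (mean exactly equal to the configured group mean, CV 20%), so the
    empirical group-mean separation equals ``effect_size`` times the
    configured delta.  Pointing bias is Normal.  With ``effect_size = 0``
    the two groups share identical distributions for every field.
    """
    if group not in ("e33", "e34"):
        raise ValueError(f"unknown group label {group!r}")

    def gamma_draw(mean: float, shape: float = 25.0) -> float:
        if mean <= 0:
            return 0.0
        return float(rng.gamma(shape, mean / shape))

    phenotype = PhenotypeParams(
        heading_error_sd_deg=gamma_draw(_group_mean(config, group, "heading_error_sd_deg")),
        heading_bias_deg=float(
            rng.normal(_group_mean(config, group, "heading_bias_deg"), 2.0)
        ),
        hesitation_rate_per_trial=gamma_draw(
            _group_mean(config, group, "hesitation_rate_per_trial")
        ),
        jerk_scale=gamma_draw(_group_mean(config, group, "jerk_scale")),
        tilt_wobble_sd=gamma_draw(_group_mean(config, group, "tilt_wobble_sd")),
        # Durations below 2 s would leave fewer than two 1.0 s feature
        # blocks, so the draw is floored there.
        movement_duration_s=max(
            2.0,
            gamma_draw(_group_mean(config, group, "movement_duration_s"), shape=100.0),
        ),
    )
    age_mean = _POOLED_AGE_MEAN + config.effect_size * (
        _GROUP_AGE_MEAN[group] - _POOLED_AGE_MEAN
    )
    age = float(np.clip(rng.normal(age_mean, _AGE_SD), 50.0, 75.0))
    p_male = float(
        np.clip(
            _POOLED_MALE_FRAC
            + config.effect_size * (_GROUP_MALE_FRAC[group] - _POOLED_MALE_FRAC),
            0.0,
            1.0,
        )
    )
    sex = "male" if rng.uniform() < p_male else "female"
    occupation = int(rng.integers(0, _N_OCCUPATIONS))
    return ParticipantProfile(
        participant_id=participant_id,
        group=group,
        age=age,
        sex=sex,
        occupation=occupation,
        phenotype=phenotype,
    )


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau), tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _minimum_jerk_rate(tau: np.ndarray) -> np.ndarray:
    """ds/dtau of the minimum-jerk profile."""
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, window: int = 33) -> np.ndarray:
    """Low-pass compass jitter: moving-average-filtered white noise with
    post-filter SD approximately ``sd``."""
    if sd == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, sd * np.sqrt(window), n)
    kernel = np.ones(window)
    return np.convolve(raw, kernel, mode="same") / np.convolve(
        np.ones(n), kernel, mode="same"
    )


def flip_transform(stream: SensorStream) -> SensorStream:
    """Map a stream through the 180-degree device-frame rotation (about the
    device x-axis): compass shifts by 180 and the y/z axes of both inertial
    sensors invert sign.  The transform is an involution."""
    accel = stream.accel.copy()
    gyro = stream.gyro.copy()
    accel[:, 1:] *= -1.0
    gyro[:, 1:] *= -1.0
    return SensorStream(
        t=stream.t.copy(),
        accel=accel,
        gyro=gyro,
        heading=(stream.heading + 180.0) % 360.0,
        sample_period_s=stream.sample_period_s,
        flip_corrected=stream.flip_corrected,
        truth=dict(stream.truth),
    )


def simulate_trial_response(
    profile: ParticipantProfile,
    trial: TrialSpec,
    reference: ReferencePoint,
    rng: np.random.Generator,
    *,
    sample_period_s: float = 0.003,
    noise: SensorNoise | None = None,
    flip_prob: float = 0.0,
    pause_duration_s: float = 0.35,
    max_hesitations: int = 3,
) -> SensorStream:
    """Simulate the pointing-back response of one trial.

    The heading trace starts at the post-rotation body heading
    (reference bearing minus the trial's net rotation, wrapped) and follows
    a minimum-jerk trajectory along the minimal arc toward the reference
    bearing plus a Normal(bias, sd) pointing error.  A Poisson number of
    hesitation pauses (angular velocity ~ 0) is inserted, capped so that
    enough movement time remains.  Ground truth is recorded in ``truth``.
    """
    noise = noise if noise is not None else SensorNoise()
    ph = profile.phenotype
    dt = sample_period_s
    n = int(round(ph.movement_duration_s / dt)) + 1
    t = np.arange(n) * dt
    # Snap the duration to the sample grid so the trajectory lands exactly
    # on its target at the final sample (noiseless end error is exactly 0).
    total_s = float(t[-1])

    start = wrap_heading(reference.heading_deg - net_rotation(trial))
    err = float(rng.normal(ph.heading_bias_deg, ph.heading_error_sd_deg))
    turn = wrap_signed(reference.heading_deg + err - start)

    # Hesitations: pauses inserted into the movement; cap to keep at least
    # 0.5 s of actual motion.
    k = int(rng.poisson(ph.hesitation_rate_per_trial))
    k = min(k, max_hesitations, max(0, int((total_s - 0.5) / pause_duration_s)))
    move_s = total_s - k * pause_duration_s
    if k > 0:
        slots = (np.arange(k) + rng.uniform(0.25, 0.75, k)) / k
        pause_starts_move = move_s * (0.15 + 0.70 * slots)  # movement-time
        pause_starts = pause_starts_move + np.arange(k) * pause_duration_s
        paused = np.clip(t[:, None] - pause_starts[None, :], 0.0, pause_duration_s)
        m = t - paused.sum(axis=1)
        moving = ~np.any(
            (t[:, None] >= pause_starts[None, :])
            & (t[:, None] < (pause_starts + pause_duration_s)[None, :]),
            axis=1,
        )
    else:
        m = t
        moving = np.ones(n, dtype=bool)

    tau = np.clip(m / move_s, 0.0, 1.0)
    heading_cont = start + turn * _minimum_jerk(tau)
    omega_deg = turn * _minimum_jerk_rate(tau) / move_s * moving  # deg/s
    omega_rad = np.deg2rad(omega_deg)

    # Hand-held arc kinematics: tangential + centripetal acceleration.
    v = ARM_RADIUS_M * omega_rad
    accel_tan = np.gradient(v, dt)
    accel_cent = v * omega_rad * np.sign(turn) if turn != 0 else np.zeros(n)
    accel = np.empty((n, 3))
    accel[:, 0] = ph.jerk_scale * accel_tan
    accel[:, 1] = ph.jerk_scale * accel_cent
    accel[:, 2] = GRAVITY_MS2
    if noise.accel_noise_sd > 0:
        accel += rng.normal(0.0, noise.accel_noise_sd, (n, 3))

    gyro = np.empty((n, 3))
    increments = np.diff(heading_cont, prepend=heading_cont[0])
    gyro[:, 0] = 0.0
    gyro[:, 1] = 0.0
    gyro[:, 2] = increments
    if ph.tilt_wobble_sd > 0:
        gyro += rng.normal(0.0, ph.tilt_wobble_sd, (n, 3))

    heading = wrap_heading_array(
        heading_cont + _smooth_noise(rng, n, noise.heading_noise_sd)
    )

    flipped = bool(rng.uniform() < flip_prob) if flip_prob > 0 else False
    stream = SensorStream(
        t=t,
        accel=accel,
        gyro=gyro,
        heading=heading,
        sample_period_s=dt,
        truth={
            "n_hesitations": k,
            "pointing_error_deg": err,
            "start_heading_deg": start,
            "turn_deg": turn,
            "heading_continuous": heading_cont,
            "flipped": flipped,
            "trial_id": trial.trial_id,
        },
    )
    if flipped:
        stream = flip_transform(stream)
        stream.truth["flipped"] = True
    return stream


def wrap_heading_array(deg: np.ndarray) -> np.ndarray:
    return np.asarray(deg, dtype=float) % 360.0


def generate_cohort(
    config: CohortConfig, protocol: Sequence[TrialSpec] | None = None
) -> tuple[list[Session], list[str]]:
    """Generate one full cohort: one session (9 streams) per participant.

    Deterministic given ``config.seed``; labels align with sessions.
    """
    protocol = list(protocol) if protocol is not None else default_protocol()
    rng = np.random.default_rng(config.seed)
    sessions: list[Session] = []
    labels: list[str] = []
    groups = ["e33"] * config.n_e33 + ["e34"] * config.n_e34
    for i, group in enumerate(groups):
        pid = f"{group}_{i:03d}"
        profile = sample_participant(group, config, rng, participant_id=pid)
        if config.wrap_guaranteed:
            ref_heading = wrap_heading(float(rng.uniform(-5.0, 5.0)))
        else:
            ref_heading = float(rng.uniform(0.0, 360.0))
        reference = ReferencePoint(heading_deg=ref_heading)
        streams = [
            simulate_trial_response(
                profile,
                trial,
                reference,
                rng,
                sample_period_s=config.sample_period_s,
                noise=config.noise,
                flip_prob=config.flip_prob,
                pause_duration_s=config.pause_duration_s,
                max_hesitations=config.max_hesitations,
            )
            for trial in protocol
        ]
        sessions.append(Session(profile=profile, reference=reference, streams=streams))
        labels.append(group)
    return sessions, labels


# ---------------------------------------------------------------------------
# Disk round-trip: one CSV per trial stream plus a cohort manifest JSON.

_CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "heading"]


def stream_to_frame(stream: SensorStream) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": stream.t,
            "ax": stream.accel[:, 0],
            "ay": stream.accel[:, 1],
            "az": stream.accel[:, 2],
            "gx": stream.gyro[:, 0],
            "gy": stream.gyro[:, 1],
            "gz": stream.gyro[:, 2],
            "heading": stream.heading,
        }
    )


def stream_from_frame(df: pd.DataFrame, sample_period_s: float = 0.003) -> SensorStream:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stream table missing columns: {missing}")
    return SensorStream(
        t=df["t"].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        heading=df["heading"].to_numpy(),
        sample_period_s=sample_period_s,
    )


def save_cohort(sessions: list[Session], labels: list[str], out_dir: str | Path) -> Path:
    """Write stream CSVs and a manifest JSON; returns the manifest path."""
    out_dir = Path(out_dir)
    streams_dir = out_dir / "streams"
    streams_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for session, label in zip(sessions, labels):
        prof = session.profile
        entry = {
            "participant_id": prof.participant_id,
            "group": label,
            "age": prof.age,
            "sex": prof.sex,
            "occupation": prof.occupation,
            "reference_heading_deg": session.reference.heading_deg,
            "trials": [],
        }
        for stream in session.streams:
            trial_id = stream.truth.get("trial_id")
            fname = f"{prof.participant_id}_trial{trial_id}.csv"
            stream_to_frame(stream).to_csv(streams_dir / fname, index=False)
            entry["trials"].append(
                {
                    "trial_id": trial_id,
                    "path": f"streams/{fname}",
                    "sample_period_s": stream.sample_period_s,
                    "true_hesitations": stream.truth.get("n_hesitations"),
                    "true_pointing_error_deg": stream.truth.get("pointing_error_deg"),
                    "flipped": stream.truth.get("flipped"),
                }
            )
        manifest.append(entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(manifest_path: str | Path) -> tuple[list[Session], list[str]]:
    """Load a cohort written by :func:`save_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    sessions, labels = [], []
    for entry in manifest:
        streams = []
        for tr in entry["trials"]:
            df = pd.read_csv(root / tr["path"])
            stream = stream_from_frame(df, sample_period_s=tr["sample_period_s"])
            stream.truth = {
                "trial_id": tr["trial_id"],
                "n_hesitations": tr["true_hesitations"],
                "pointing_error_deg": tr["true_pointing_error_deg"],
                "flipped": tr["flipped"],
            }
            streams.append(stream)
        profile = ParticipantProfile(
            participant_id=entry["participant_id"],
            group=entry["group"],
            age=entry["age"],
            sex=entry["sex"],
            occupation=entry["occupation"],
            phenotype=PhenotypeParams(**DEFAULT_BASE_PHENOTYPE),
        )
        sessions.append(
            Session(
                profile=profile,
                reference=ReferencePoint(heading_deg=entry["reference_heading_deg"]),
                streams=streams,
            )
        )
        labels.append(entry["group"])
    return sessions, labels
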