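"""Synthetic walking-IMU cohort generator.

Emulates the acquisition protocol the classifier is built for: each
subject stands still for 10 s, walks for 2 min (turning around every few
seconds), and stands still again, with accelerometer and gyroscope
triplets recorded at 120 Hz at six body positions (right/left arm, hand,
thigh).

Generative model per subject s and position:

* gait oscillation at a subject-specific fundamental f_s ~ U(0.85, 1.05)
  Hz with a second harmonic; thighs swing in anti-phase left vs right and
  each arm swings in anti-phase with its ipsilateral thigh; the hand
  follows the arm template scaled by beta_s ~ U(1.2, 1.5) plus extra
  high-frequency jitter,
* right-dominant asymmetry: every right-side channel is scaled by
  alpha_s ~ U(1.1, 1.3) (all simulated subjects are right-dominant), so
  the side signal survives only in the unscaled magnitude,
* mirror asymmetry: the medial-lateral waveform of the left side is the
  sign-flipped image of the right side's, and the arm/hand ML waveform is
  shape-asymmetric (skewed), so left and right differ in normalized-axis
  shape as mirror-image kinematics do; the thigh ML waveform is kept
  symmetric, which makes thigh-side the hardest side task,
* 1-s raised-cosine medial-lateral bursts every 6-8 s emulating the
  turnarounds of short back-and-forth laps,
* per-axis offsets b ~ N(0, 0.05) and white sensor noise (0.05 g
  accelerometer, 0.1 rad/s gyroscope); standing phases contain offset and
  noise only.

Gyroscope channels use the phase-shifted (cosine) counterparts of the
accelerometer waveforms, scaled by a fixed factor.  Everything is
deterministic given the master seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import (
    AXES,
    POSITIONS,
    SENSOR_KINDS,
    ManifestEntry,
    SensorRecording,
    position_segment,
    position_side,
    write_manifest,
    write_recording,
)

#: accelerometer template amplitudes (g); the hand reuses the arm template
#: scaled by the subject's hand gain beta_s
TEMPLATE_AMPLITUDES: dict[str, dict[str, float]] = {
    "thigh": {"FB": 0.8, "TA": 0.3, "ML": 0.2},
    "arm": {"FB": 0.5, "TA": 0.25, "ML": 0.15},
}

#: relative amplitude of the second gait harmonic per segment
HARMONIC_RATIO: dict[str, float] = {"thigh": 0.4, "arm": 0.3, "hand": 0.3}

#: shape-asymmetry phase of the second harmonic (pi/2 -> skewed waveform,
#: 0 -> symmetric); thigh TA/ML stay symmetric so thigh-side separation
#: must come from magnitude amplitude alone
HARMONIC_PHASE: dict[str, dict[str, float]] = {
    "thigh": {"FB": math.pi / 2, "TA": 0.0, "ML": 0.0},
    "arm": {"FB": math.pi / 2, "TA": math.pi / 2, "ML": math.pi / 2},
    "hand": {"FB": math.pi / 2, "TA": math.pi / 2, "ML": math.pi / 2},
}

#: fundamental phase offset per axis (arbitrary but fixed)
AXIS_PHASE: dict[str, float] = {"FB": 0.0, "TA": math.pi / 2, "ML": math.pi / 4}


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the synthetic cohort."""

    n_subjects: int = 10
    sampling_rate_hz: float = 120.0
    stand_seconds: float = 10.0
    walk_seconds: float = 120.0
    gait_freq_range_hz: tuple[float, float] = (0.85, 1.05)
    dominant_gain_range: tuple[float, float] = (1.1, 1.3)  # alpha
    hand_gain_range: tuple[float, float] = (1.2, 1.5)  # beta
    axis_offset_sd: float = 0.05
    accel_noise_sd: float = 0.05
    gyro_noise_sd: float = 0.1
    hand_jitter_sd: float = 0.08
    gyro_scale: float = 2.0
    turn_interval_s: tuple[float, float] = (6.0, 8.0)
    turn_duration_s: float = 1.0
    turn_gain: float = 0.4
    mirror_lateral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("sampling_rate_hz", "stand_seconds", "walk_seconds"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.dominant_gain_range[0] < 1 or self.hand_gain_range[0] < 1:
            raise ConfigError("asymmetry gains must be >= 1")

    @property
    def n_samples(self) -> int:
        total = 2 * self.stand_seconds + self.walk_seconds
        return int(round(total * self.sampling_rate_hz))

    def noise_sd(self, sensor_kind: str) -> float:
        return self.accel_noise_sd if sensor_kind == "accelerometer" else self.gyro_noise_sd


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject draws shared across all of that subject's recordings."""

    subject_id: str
    gait_freq_hz: float
    dominant_gain: float  # alpha: right-side amplitude factor
    hand_gain: float  # beta: hand-over-arm amplitude factor
    turn_times_s: tuple[float, ...]  # walk-relative burst onsets


def draw_subjects(config: SimulationConfig) -> list[SubjectParams]:
    """Deterministically draw the per-subject parameters from the master seed."""
    rng = np.random.default_rng([config.seed, 7919])
    subjects = []
    for i in range(config.n_subjects):
        f = rng.uniform(*config.gait_freq_range_hz)
        alpha = rng.uniform(*config.dominant_gain_range)
        beta = rng.uniform(*config.hand_gain_range)
        times, t = [], 0.0
        while True:
            t += rng.uniform(*config.turn_interval_s)
            if t + config.turn_duration_s >= config.walk_seconds:
                break
            times.append(t)
        subjects.append(
            SubjectParams(
                subject_id=f"S{i + 1:02d}",
                gait_freq_hz=float(f),
                dominant_gain=float(alpha),
                hand_gain=float(beta),
                turn_times_s=tuple(times),
            )
        )
    return subjects


def _fundamental_phase(position: str) -> float:
    # thighs anti-phase left vs right; arm FB anti-phase to the
    # ipsilateral thigh; hand follows the arm
    side, segment = position_side(position), position_segment(position)
    phase = math.pi if side == "right" else 0.0
    if segment in ("arm", "hand"):
        phase += math.pi
    return phase


def _turn_envelope(
    n_walk: int, subject: SubjectParams, config: SimulationConfig
) -> np.ndarray:
    """Signed sum of 1-s raised-cosine bursts; successive turns alternate sign."""
    t = np.arange(n_walk) / config.sampling_rate_hz
    env = np.zeros(n_walk)
    for j, onset in enumerate(subject.turn_times_s):
        inside = (t >= onset) & (t < onset + config.turn_duration_s)
        phase = (t[inside] - onset) / config.turn_duration_s
        env[inside] += (-1) ** j * 0.5 * (1 - np.cos(2 * math.pi * phase))
    return env


def simulate_recording(
    subject: SubjectParams,
    position: str,
    sensor_kind: str,
    config: SimulationConfig,
    seed: int | None = None,
) -> SensorRecording:
    """Simulate one stand-walk-stand recording for a subject and position.

    ``seed`` overrides the deterministic per-recording stream derived from
    the master seed and the (subject, position, sensor) indices.
    """
    if position not in POSITIONS:
        raise ConfigError(f"unknown position {position!r}")
    if sensor_kind not in SENSOR_KINDS:
        raise ConfigError(f"unknown sensor kind {sensor_kind!r}")

    side, segment = position_side(position), position_segment(position)
    if seed is None:
        sub_key = zlib.crc32(subject.subject_id.encode())
        rng = np.random.default_rng(
            [config.seed, sub_key, POSITIONS.index(position), SENSOR_KINDS.index(sensor_kind)]
        )
    else:
        rng = np.random.default_rng(seed)

    rate = config.sampling_rate_hz
    n_stand = int(round(config.stand_seconds * rate))
    n_walk = int(round(config.walk_seconds * rate))
    n_total = 2 * n_stand + n_walk
    t_walk = np.arange(n_walk) / rate

    sensor_scale = config.gyro_scale if sensor_kind == "gyroscope" else 1.0
    side_gain = subject.dominant_gain if side == "right" else 1.0
    segment_gain = subject.hand_gain if segment == "hand" else 1.0
    template_segment = "arm" if segment == "hand" else segment

    h = HARMONIC_RATIO[segment]
    phase0 = _fundamental_phase(position)
    turns = _turn_envelope(n_walk, subject, config)
    noise_sd = config.noise_sd(sensor_kind)

    channels: dict[str, np.ndarray] = {}
    for axis in AXES:
        amp = (
            TEMPLATE_AMPLITUDES[template_segment][axis]
            * segment_gain
            * side_gain
            * sensor_scale
        )
        theta = 2 * math.pi * subject.gait_freq_hz * t_walk + phase0 + AXIS_PHASE[axis]
        psi = HARMONIC_PHASE[segment][axis]
        if sensor_kind == "accelerometer":
            wave = np.sin(theta) + h * np.sin(2 * theta + psi)
        else:
            wave = np.cos(theta) + h * np.sin(2 * theta + psi)
        walk = amp * wave
        if axis == "ML":
            if config.mirror_lateral and side == "left":
                walk = -walk
            walk = walk + config.turn_gain * amp * turns
        if segment == "hand":
            walk = walk + rng.normal(
                0.0, config.hand_jitter_sd * side_gain * sensor_scale, n_walk
            )
        offset = rng.normal(0.0, config.axis_offset_sd)
        signal = np.empty(n_total)
        signal[:n_stand] = 0.0
        signal[n_stand : n_stand + n_walk] = walk
        signal[n_stand + n_walk :] = 0.0
        signal += offset + rng.normal(0.0, noise_sd, n_total)
        channels[axis] = signal

    return SensorRecording(
        subject_id=subject.subject_id,
        sensor_kind=sensor_kind,
        position=position,
        sampling_rate_hz=rate,
        channels=channels,
        phases={
            "stand_pre": (0, n_stand),
            "walk": (n_stand, n_stand + n_walk),
            "stand_post": (n_stand + n_walk, n_total),
        },
    )


@dataclass
class Cohort:
    """A simulated cohort: per-subject parameters and all their recordings."""

    config: SimulationConfig
    subjects: list[SubjectParams]
    recordings: list[SensorRecording]


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(),
    sensor_kinds: tuple[str, ...] = SENSOR_KINDS,
) -> Cohort:
    """Simulate n_subjects x 6 positions x sensors recordings, deterministically."""
    subjects = draw_subjects(config)
    recordings = [
        simulate_recording(subject, position, kind, config)
        for subject in subjects
        for position in POSITIONS
        for kind in sensor_kinds
    ]
    return Cohort(config=config, subjects=subjects, recordings=recordings)


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write all recordings as CSVs plus a YAML manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort.recordings:
        kind_tag = "accel" if rec.sensor_kind == "accelerometer" else "gyro"
        name = f"{rec.subject_id}_{rec.position}_{kind_tag}.csv"
        write_recording(rec, directory / name)
        entries.append(
            ManifestEntry(
                path=name,
                subject_id=rec.subject_id,
                position=rec.position,
                sensor_kind=rec.sensor_kind,
                sampling_rate_hz=rec.sampling_rate_hz,
            )
        )
    manifest = directory / "manifest.yaml"
    write_manifest(entries, manifest)
    return manifest
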