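"""Data model and CSV/YAML I/O for on-body inertial recordings.

A recording is one (subject, body position, sensor kind) time series whose
raw x/y/z axes have already been relabeled into anatomical motion
directions:

* ``FB`` — forward/backward (sagittal plane),
* ``TA`` — toward/away from the body midline (frontal plane),
* ``ML`` — medial/lateral (transverse plane).

Each recording carries three contiguous protocol phases: standing still
before the walk (``stand_pre``), the walk itself (``walk``), and standing
still after it (``stand_post``).  The on-disk format is a plain CSV with
columns ``t_s, FB, TA, ML, phase`` plus a YAML cohort manifest mapping files
to their metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, RecordingParseError, SchemaError, ValidationError

SENSOR_KINDS = ("accelerometer", "gyroscope")
#: accelerometer readings are in g, gyroscope readings in rad/s
SENSOR_UNITS = {"accelerometer": "g", "gyroscope": "rad/s"}

POSITIONS = (
    "right_arm",
    "left_arm",
    "right_hand",
    "left_hand",
    "right_thigh",
    "left_thigh",
)

AXES = ("FB", "TA", "ML")
PHASES = ("stand_pre", "walk", "stand_post")

METADATA_COLUMNS = ("subject_id", "position", "sensor_kind", "window_index")

DEFAULT_SAMPLING_RATE_HZ = 120.0


def position_side(position: str) -> str:
    return position.split("_", 1)[0]


def position_segment(position: str) -> str:
    return position.split("_", 1)[1]


@dataclass
class SensorRecording:
    """One subject x position x sensor time series in FB/TA/ML coordinates.

    ``phases`` maps each phase label to a half-open ``[start, stop)`` index
    interval; the three intervals must be ordered, disjoint and jointly
    cover the whole index range.
    """

    subject_id: str
    sensor_kind: str
    position: str | None
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    phases: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.channels = {a: np.asarray(v, dtype=float) for a, v in self.channels.items()}
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.channels["FB"])

    def phase_slice(self, label: str) -> slice:
        start, stop = self.phases[label]
        return slice(start, stop)

    def validate(self) -> None:
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValidationError(f"unknown sensor kind {self.sensor_kind!r}")
        if self.position is not None and self.position not in POSITIONS:
            raise ValidationError(f"unknown position {self.position!r}")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if set(self.channels) != set(AXES):
            raise ValidationError(f"channels must be exactly {AXES}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError("channels must have identical length")
        n = lengths.pop()
        if n < 1:
            raise ValidationError("channels must contain at least one sample")
        if tuple(self.phases) != PHASES:
            raise ValidationError(f"phases must be exactly {PHASES} in order")
        cursor = 0
        for label in PHASES:
            start, stop = self.phases[label]
            if start != cursor or stop < start:
                raise ValidationError(
                    f"phase {label!r} interval [{start}, {stop}) is not contiguous"
                )
            cursor = stop
        if cursor != n:
            raise ValidationError("phases must jointly cover the full index range")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensorRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.sensor_kind == other.sensor_kind
            and self.position == other.position
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.phases == other.phases
            and all(np.array_equal(self.channels[a], other.channels[a]) for a in AXES)
        )


@dataclass(frozen=True)
class AxisMap:
    """Signed bijection from raw sensor axis labels onto FB/TA/ML.

    ``mapping`` sends each motion direction to a ``(source_axis, sign)``
    pair, e.g. ``{"FB": ("z", -1), "TA": ("x", 1), "ML": ("y", 1)}``.
    The raw-to-anatomical mapping depends on how the sensor is worn at each
    position, so it is user configuration (normally carried in the cohort
    manifest), not a built-in constant.
    """

    mapping: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if len(self.mapping) != 3:
            raise ConfigError("axis map must define exactly three target axes")
        sources = [src for src, _ in self.mapping.values()]
        if len(set(sources)) != len(sources):
            raise ConfigError("axis map sources must be distinct (bijection)")
        for tgt, (src, sign) in self.mapping.items():
            if sign not in (-1, 1):
                raise ConfigError(f"axis map sign for {tgt!r} must be +1 or -1")

    @classmethod
    def identity(cls) -> "AxisMap":
        return cls({a: (a, 1) for a in AXES})

    def inverse(self) -> "AxisMap":
        inv = {src: (tgt, sign) for tgt, (src, sign) in self.mapping.items()}
        return AxisMap(inv)


def apply_axis_map(
    raw: Mapping[str, np.ndarray], axis_map: AxisMap
) -> dict[str, np.ndarray]:
    """Relabel raw axis channels into FB/TA/ML motion-direction channels."""
    out: dict[str, np.ndarray] = {}
    for target, (source, sign) in axis_map.mapping.items():
        if source not in raw:
            raise ConfigError(f"axis map references missing raw axis {source!r}")
        out[target] = sign * np.asarray(raw[source], dtype=float)
    return out


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["t_s", "FB", "TA", "ML", "phase"]


def write_recording(rec: SensorRecording, path: str | Path) -> None:
    """Write a recording as a ``t_s, FB, TA, ML, phase`` CSV file."""
    rec.validate()
    n = rec.n_samples
    phase_col = np.empty(n, dtype=object)
    for label in PHASES:
        phase_col[rec.phase_slice(label)] = label
    frame = pd.DataFrame(
        {
            "t_s": np.arange(n) / rec.sampling_rate_hz,
            "FB": rec.channels["FB"],
            "TA": rec.channels["TA"],
            "ML": rec.channels["ML"],
            "phase": phase_col,
        }
    )
    # repr-based float formatting round-trips float64 exactly
    frame.to_csv(path, index=False)


def read_recording(
    path: str | Path,
    *,
    subject_id: str,
    position: str | None,
    sensor_kind: str,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> SensorRecording:
    """Read a ``t_s, FB, TA, ML, phase`` CSV into a validated recording."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in AXES:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy()))
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise RecordingParseError(
                f"{path}: non-finite value in column {col!r} at line {bad[0] + 2}"
            )
        frame[col] = values

    labels = frame["phase"].to_numpy()
    unknown = set(labels) - set(PHASES)
    if unknown:
        raise SchemaError(f"{path}: unknown phase labels {sorted(unknown)}")
    phases: dict[str, tuple[int, int]] = {}
    cursor = 0
    for label in PHASES:
        idx = np.flatnonzero(labels == label)
        if idx.size == 0:
            raise SchemaError(f"{path}: phase {label!r} missing")
        if idx[0] != cursor or idx[-1] - idx[0] + 1 != idx.size:
            raise ValidationError(f"{path}: phase {label!r} is not contiguous/ordered")
        phases[label] = (int(idx[0]), int(idx[-1]) + 1)
        cursor = int(idx[-1]) + 1
    if cursor != len(frame):
        raise ValidationError(f"{path}: phases do not cover all rows")

    return SensorRecording(
        subject_id=subject_id,
        sensor_kind=sensor_kind,
        position=position,
        sampling_rate_hz=sampling_rate_hz,
        channels={a: frame[a].to_numpy() for a in AXES},
        phases=phases,
    )


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------


@dataclass
class ManifestEntry:
    path: str
    subject_id: str
    position: str
    sensor_kind: str
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> None:
    payload = {
        "recordings": [
            {
                "path": e.path,
                "subject_id": e.subject_id,
                "position": e.position,
                "sensor_kind": e.sensor_kind,
                "sampling_rate_hz": e.sampling_rate_hz,
            }
            for e in entries
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "recordings" not in payload:
        raise SchemaError(f"{path}: manifest must contain a 'recordings' list")
    return [ManifestEntry(**item) for item in payload["recordings"]]


def load_cohort(manifest_path: str | Path) -> list[SensorRecording]:
    """Load every recording listed in a cohort manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    recordings = []
    for entry in read_manifest(manifest_path):
        rec_path = root / entry.path
        recordings.append(
            read_recording(
                rec_path,
                subject_id=entry.subject_id,
                position=entry.position,
                sensor_kind=entry.sensor_kind,
                sampling_rate_hz=entry.sampling_rate_hz,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature column names of a feature table (everything non-metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def validate_feature_table(table: pd.DataFrame, n_features: int | None = None) -> None:
    for col in METADATA_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"feature table missing metadata column {col!r}")
    feats = feature_columns(table)
    if len(set(feats)) != len(feats):
        raise ValidationError("feature table has duplicate columns")
    if n_features is not None and len(feats) != n_features:
        raise ValidationError(f"expected {n_features} feature columns, got {len(feats)}")
    values = table[feats].to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValidationError("feature table contains non-finite cells")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in table.columns] + feature_columns(table)
    table[cols].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_feature_table(table)
    return table
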