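"""End-to-end convenience chains: simulate -> preprocess -> featurize -> evaluate.

Accelerometer and gyroscope data are always handled as independent
experiments — their feature tables are never fused.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .features import FeatureRegistry, WindowSpec, featurize_cohort
from .io import SensorRecording
from .preprocess import preprocess_recording
from .synthetic import SimulationConfig, simulate_cohort


def feature_table_from_recordings(
    recordings: Iterable[SensorRecording],
    sensor_kind: str | None = None,
    window_spec: WindowSpec | None = None,
    registry: FeatureRegistry = FeatureRegistry(),
    smoothing_width: int = 10,
) -> pd.DataFrame:
    """Preprocess and featurize recordings (optionally one sensor kind only)."""
    selected = [
        r for r in recordings if sensor_kind is None or r.sensor_kind == sensor_kind
    ]
    preprocessed = [preprocess_recording(r, smoothing_width) for r in selected]
    return featurize_cohort(preprocessed, window_spec, registry)


def simulated_feature_table(
    config: SimulationConfig = SimulationConfig(),
    sensor_kind: str = "accelerometer",
    window_spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Feature table of a fresh synthetic cohort for one sensor kind."""
    cohort = simulate_cohort(config, sensor_kinds=(sensor_kind,))
    return feature_table_from_recordings(cohort.recordings, sensor_kind, window_spec)


def report_to_json(report: dict) -> str:
    """Canonical (sorted, fixed-format) JSON serialization of a report."""
    return json.dumps(report, indent=2, sort_keys=True)
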