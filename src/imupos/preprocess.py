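"""Signal conditioning for walking IMU recordings.

The chain applied to each recording, per axis, is:

1. trailing moving average (default 10 points) to suppress sensor noise,
2. offset removal — subtract the mean of the pre-walk standing phase, so a
   sensor's residual bias at rest does not leak into walking features,
3. magnitude: per-sample Euclidean norm of the three offset-removed axes,
4. min-max normalization of FB/TA/ML to [-1, 1] using the walking-phase
   extrema of the recording.

The magnitude channel is deliberately left unscaled: dominant-side limbs
move with larger amplitude, and normalizing the magnitude would erase
exactly the left/right asymmetry the classifier needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, ParameterError
from .io import AXES, SensorRecording

CHANNELS = ("FB", "TA", "ML", "MAG")


@dataclass
class PreprocessedRecording:
    """A conditioned recording: FB/TA/ML in [-1, 1] plus unscaled MAG."""

    subject_id: str
    sensor_kind: str
    position: str | None
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    phases: dict[str, tuple[int, int]]

    def phase_slice(self, label: str) -> slice:
        start, stop = self.phases[label]
        return slice(start, stop)

    @property
    def n_samples(self) -> int:
        return len(self.channels["MAG"])


def moving_average(x: np.ndarray, width: int = 10) -> np.ndarray:
    """Trailing moving average: output[i] = mean(x[max(0, i-width+1) .. i]).

    The warm-up region (first ``width - 1`` samples) averages whatever
    prefix is available, so the output has the same length as the input.
    All samples are equally weighted.
    """
    if width <= 0:
        raise ParameterError("moving average width must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("moving_average requires at least one sample")
    csum = np.cumsum(x)
    out = np.empty_like(x)
    if x.size <= width:
        out[:] = csum / np.arange(1, x.size + 1)
        return out
    out[:width] = csum[:width] / np.arange(1, width + 1)
    out[width:] = (csum[width:] - csum[:-width]) / width
    return out


def remove_offset(x: np.ndarray, standing: tuple[int, int]) -> np.ndarray:
    """Subtract the mean over the standing interval from every sample."""
    x = np.asarray(x, dtype=float)
    start, stop = standing
    if stop <= start:
        raise ParameterError("standing interval must be non-empty")
    return x - x[start:stop].mean()


def magnitude(fb: np.ndarray, ta: np.ndarray, ml: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(FB^2 + TA^2 + ML^2)."""
    fb, ta, ml = (np.asarray(v, dtype=float) for v in (fb, ta, ml))
    if not (len(fb) == len(ta) == len(ml)):
        raise ParameterError("magnitude requires equal-length channels")
    return np.sqrt(fb**2 + ta**2 + ml**2)


def minmax_axis(x: np.ndarray) -> np.ndarray:
    """Map x affinely onto [-1, 1]: min(x) -> -1, max(x) -> +1."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateSignalError("cannot min-max normalize a constant sequence")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _minmax_with_stats(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise DegenerateSignalError("cannot min-max normalize with a degenerate range")
    return np.clip(2.0 * (x - lo) / (hi - lo) - 1.0, -1.0, 1.0)


def preprocess_recording(
    rec: SensorRecording, smoothing_width: int = 10
) -> PreprocessedRecording:
    """Run the full conditioning chain on one recording.

    Normalization statistics (min/max) are taken over the walking phase
    only — standing samples sit near zero after offset removal and would
    otherwise shrink the informative dynamic range.  The normalized
    channels are clipped to [-1, 1] outside the walk; the magnitude is
    computed from the offset-removed axes *before* normalization and is
    never rescaled.
    """
    rec.validate()
    walk = rec.phase_slice("walk")
    stand_pre = rec.phases["stand_pre"]

    conditioned: dict[str, np.ndarray] = {}
    for axis in AXES:
        smoothed = moving_average(rec.channels[axis], smoothing_width)
        conditioned[axis] = remove_offset(smoothed, stand_pre)

    mag = magnitude(conditioned["FB"], conditioned["TA"], conditioned["ML"])

    channels: dict[str, np.ndarray] = {}
    for axis in AXES:
        x = conditioned[axis]
        channels[axis] = _minmax_with_stats(x, x[walk].min(), x[walk].max())
    channels["MAG"] = mag

    return PreprocessedRecording(
        subject_id=rec.subject_id,
        sensor_kind=rec.sensor_kind,
        position=rec.position,
        sampling_rate_hz=rec.sampling_rate_hz,
        channels=channels,
        phases=dict(rec.phases),
    )
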