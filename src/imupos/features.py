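"""Windowing and the 28-per-channel feature set (112 per sensor).

Each preprocessed recording is segmented into overlapping windows taken
from the walking phase (default 5 s, 50% overlap).  For every window and
every channel (FB, TA, ML, MAG) the registry computes 28 features:

* 14 moment/order statistics: mean, rms, per25/per50/per75, std, var,
  min, max, range, iqr, skew, kurt, energy;
* 5 binned Shannon entropies (10..50 histogram bins), in bits;
* 9 Higuchi curve lengths L(k) for stride k = 2..10.

The Higuchi curve length L(k) is the normalized average length of the
signal subsampled at stride k; for a fractal signal L(k) is proportional
to k^(-D) with fractal dimension D, which ``higuchi_fd`` estimates as the
negated log-log slope.  The per-k lengths themselves — not the fitted
slope — are the features named ``k-2`` .. ``k-10``, which is what makes
the per-channel count 28.

Magnitude features carry bare names (``mean``, ``k-2``); axis features are
suffixed (``mean-FB``, ``k-2-TA``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateSignalError, ParameterError
from .io import METADATA_COLUMNS, feature_columns
from .preprocess import CHANNELS, PreprocessedRecording

DEFAULT_ENTROPY_BINS = (10, 20, 30, 40, 50)
DEFAULT_HIGUCHI_K = tuple(range(2, 11))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 5-s windows with 50% overlap by default."""

    window_seconds: float = 5.0
    overlap_fraction: float = 0.5
    sampling_rate_hz: float = 120.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ParameterError("overlap_fraction must lie in [0, 1)")
        if self.window_samples < 2:
            raise ParameterError("window must span at least 2 samples")
        if self.step_samples < 1:
            raise ParameterError("window step must be at least 1 sample")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds * self.sampling_rate_hz))

    @property
    def step_samples(self) -> int:
        return int(round(self.window_samples * (1.0 - self.overlap_fraction)))


def slide_windows(n_samples: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """All [start, end) windows that fit fully inside ``n_samples``."""
    w, step = spec.window_samples, spec.step_samples
    if n_samples < w:
        return []
    count = (n_samples - w) // step + 1
    return [(i * step, i * step + w) for i in range(count)]


# ---------------------------------------------------------------------------
# Individual feature families
# ---------------------------------------------------------------------------


def entropy(x: np.ndarray, m: int) -> float:
    """Binned Shannon entropy in bits over an m-bin histogram of the window.

    Bins are equal-width over the window's own [min, max]; empty bins
    contribute nothing (0 * log 0 = 0).  A constant window occupies a
    single bin and has zero entropy.  Bounded by log2(m).
    """
    if m < 1:
        raise ParameterError("bin count must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("entropy requires a non-empty window")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=m, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


@dataclass(frozen=True)
class HiguchiParams:
    """Stride values k for the Higuchi curve-length features (2..10)."""

    k_values: tuple[int, ...] = DEFAULT_HIGUCHI_K

    def __post_init__(self) -> None:
        if len(self.k_values) == 0 or any(k < 2 for k in self.k_values):
            raise ParameterError("all Higuchi k values must be >= 2")


def higuchi_lengths(
    x: np.ndarray, params: HiguchiParams = HiguchiParams()
) -> dict[int, float]:
    """Normalized Higuchi curve lengths L(k) for each configured stride.

    For offsets m = 1..k the subsampled curve X(m), X(m+k), X(m+2k), ...
    has length

        L_m(k) = [sum_i |X(m+ik) - X(m+(i-1)k)|] * (N-1) / (n_i * k) / k,
        n_i = floor((N - m) / k),

    and L(k) is the mean of L_m(k) over m.  For a straight line of N
    samples this collapses to exactly (N-1)/k.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    out: dict[int, float] = {}
    for k in sorted(params.k_values):
        if k >= n:
            raise ParameterError(f"Higuchi stride k={k} must be < window length {n}")
        lengths = np.empty(k)
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                raise ParameterError(
                    f"window length {n} too short for Higuchi stride k={k}"
                )
            series = x[m - 1 :: k]
            dist = np.abs(np.diff(series[: n_i + 1])).sum()
            lengths[m - 1] = dist * (n - 1) / (n_i * k) / k
        out[k] = float(lengths.mean())
    return out


def fd_from_lengths(lengths: Mapping[int, float]) -> float:
    """Fractal dimension D = -slope of the ln L(k) vs ln k least-squares fit."""
    if len(lengths) < 2:
        raise ParameterError("fractal dimension needs at least two k values")
    ks = np.array(sorted(lengths))
    ls = np.array([lengths[k] for k in ks])
    if np.any(ls <= 0):
        raise DegenerateSignalError("zero curve length: fractal dimension undefined")
    slope = np.polyfit(np.log(ks), np.log(ls), 1)[0]
    return float(-slope)


def higuchi_fd(x: np.ndarray, params: HiguchiParams = HiguchiParams()) -> float:
    """Fractal dimension of a window from its Higuchi curve lengths.

    Expected in [1, 2] for curves: 1 for a straight line, approaching 2
    for white noise.  Used for validating the curve-length features; the
    classifier consumes the L(k) values directly.
    """
    return fd_from_lengths(higuchi_lengths(x, params))


_STAT_NAMES = (
    "mean",
    "rms",
    "per25",
    "per50",
    "per75",
    "std",
    "var",
    "min",
    "max",
    "range",
    "iqr",
    "skew",
    "kurt",
    "energy",
)


def basic_stats(x: np.ndarray) -> dict[str, float]:
    """The 14 moment/order statistics of one window.

    Quantiles use linear interpolation; std/var are population moments
    (ddof = 0); skew is Fisher-Pearson g1 and kurt is excess kurtosis,
    both defined as 0 for a zero-variance window; energy is the raw sum
    of squares.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("basic_stats requires a non-empty window")
    p25, p50, p75 = np.percentile(x, [25, 50, 75])
    var = float(np.var(x))
    if var > 0:
        skew = float(scipy.stats.skew(x, bias=True))
        kurt = float(scipy.stats.kurtosis(x, fisher=True, bias=True))
    else:
        skew = kurt = 0.0
    return {
        "mean": float(np.mean(x)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "per25": float(p25),
        "per50": float(p50),
        "per75": float(p75),
        "std": float(np.sqrt(var)),
        "var": var,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "range": float(np.max(x) - np.min(x)),
        "iqr": float(p75 - p25),
        "skew": skew,
        "kurt": kurt,
        "energy": float(np.sum(x**2)),
    }


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered definition of the 28 per-channel features."""

    entropy_bins: tuple[int, ...] = DEFAULT_ENTROPY_BINS
    higuchi: HiguchiParams = field(default_factory=HiguchiParams)

    @property
    def names(self) -> tuple[str, ...]:
        return (
            _STAT_NAMES
            + tuple(f"entro{m}" for m in self.entropy_bins)
            + tuple(f"k-{k}" for k in sorted(self.higuchi.k_values))
        )

    def compute(self, x: np.ndarray) -> dict[str, float]:
        """All 28 features of one window, keyed by registry name."""
        values = basic_stats(x)
        for m in self.entropy_bins:
            values[f"entro{m}"] = entropy(x, m)
        for k, lk in higuchi_lengths(x, self.higuchi).items():
            values[f"k-{k}"] = lk
        return values


def feature_name(stat: str, channel: str) -> str:
    """Column name: bare for the magnitude channel, ``-axis`` suffixed else."""
    return stat if channel == "MAG" else f"{stat}-{channel}"


def registry_column_names(registry: FeatureRegistry) -> list[str]:
    """The 112 feature column names in canonical (channel-major) order."""
    return [feature_name(s, c) for c in CHANNELS for s in registry.names]


def featurize_window(
    channels: Mapping[str, np.ndarray],
    registry: FeatureRegistry = FeatureRegistry(),
) -> dict[str, float]:
    """28 features per channel over aligned FB/TA/ML/MAG windows (112 total)."""
    missing = [c for c in CHANNELS if c not in channels]
    if missing:
        raise ParameterError(f"featurize_window missing channels {missing}")
    out: dict[str, float] = {}
    for channel in CHANNELS:
        for stat, value in registry.compute(channels[channel]).items():
            out[feature_name(stat, channel)] = value
    return out


def featurize_recording(
    rec: PreprocessedRecording,
    spec: WindowSpec | None = None,
    registry: FeatureRegistry = FeatureRegistry(),
) -> pd.DataFrame:
    """One feature row per walking-phase window, with metadata attached.

    Windows are laid out inside the walking phase only and never straddle
    its boundaries; a walk shorter than one window yields an empty table.
    """
    if spec is None:
        spec = WindowSpec(sampling_rate_hz=rec.sampling_rate_hz)
    walk = rec.phase_slice("walk")
    walk_channels = {c: rec.channels[c][walk] for c in CHANNELS}
    n_walk = len(walk_channels["MAG"])
    rows = []
    for idx, (start, end) in enumerate(slide_windows(n_walk, spec)):
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "position": rec.position,
            "sensor_kind": rec.sensor_kind,
            "window_index": idx,
        }
        row.update(
            featurize_window({c: walk_channels[c][start:end] for c in CHANNELS}, registry)
        )
        rows.append(row)
    columns = list(METADATA_COLUMNS) + registry_column_names(registry)
    return pd.DataFrame(rows, columns=columns)


def featurize_cohort(
    recordings: Iterable[PreprocessedRecording],
    spec: WindowSpec | None = None,
    registry: FeatureRegistry = FeatureRegistry(),
) -> pd.DataFrame:
    """Concatenated feature table over many preprocessed recordings."""
    tables = [featurize_recording(rec, spec, registry) for rec in recordings]
    return pd.concat(tables, ignore_index=True)


def scale_features(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Min-max scale feature columns to [0, 1] using training statistics.

    The transform is fitted on ``train`` and applied to both tables;
    out-of-range values in ``apply_to`` are clipped to [0, 1].  A constant
    training column maps to 0 everywhere.  Metadata columns pass through
    untouched.
    """
    if len(train) == 0:
        raise ParameterError("scale_features requires a non-empty training table")
    feats = feature_columns(train)
    lo = train[feats].min(axis=0)
    hi = train[feats].max(axis=0)
    span = (hi - lo).replace(0.0, np.nan)

    def _apply(table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        scaled = ((table[feats] - lo) / span).clip(0.0, 1.0).fillna(0.0)
        out[feats] = scaled
        return out

    return _apply(train), (None if apply_to is None else _apply(apply_to))
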