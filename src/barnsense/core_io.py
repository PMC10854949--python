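"""Data model, CSV I/O and preprocessing shared by every pipeline stage.

The universal container is :class:`EnvMatrix`: a timestamp x sensor grid of
air temperature (deg C) and relative humidity (%RH) readings from a fixed set
of named monitoring locations (``L-1`` ... ``L-30`` in the default barn
layout).  Downstream stages never touch the raw CSV; they consume
:class:`EnvMatrix` and the per-sensor feature vectors built by
:func:`make_samples`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvMatrix",
    "SensorSample",
    "PipelineConfig",
    "FormatError",
    "CompletenessError",
    "DataQualityError",
    "ConfigError",
    "TEMPERATURE_RANGE",
    "HUMIDITY_RANGE",
    "read_env_csv",
    "write_env_csv",
    "preprocess",
    "make_samples",
]

#: Physical measurement range of the temperature probes (deg C).
TEMPERATURE_RANGE = (-40.0, 80.0)
#: Physical measurement range of the humidity probes (%RH).
HUMIDITY_RANGE = (0.0, 100.0)

CSV_COLUMNS = ("timestamp", "sensor_id", "temperature_c", "relative_humidity_pct")


class FormatError(ValueError):
    """Input file does not follow the expected CSV dialect."""


class CompletenessError(ValueError):
    """The time x sensor grid has a duplicate or missing cell."""


class DataQualityError(ValueError):
    """A sensor's data is too corrupted to repair."""


class ConfigError(ValueError):
    """A pipeline configuration value violates its invariant."""


@dataclass
class EnvMatrix:
    """Timestamp x sensor matrices of temperature and humidity.

    Attributes
    ----------
    timestamps : pandas.DatetimeIndex
        Strictly increasing, constant step.
    sensor_ids : list of str
        Unique location labels, column order of the matrices.
    temperature : ndarray, shape (n_times, n_sensors)
        Air temperature in deg C.
    humidity : ndarray, shape (n_times, n_sensors)
        Relative humidity in %RH.
    """

    timestamps: pd.DatetimeIndex
    sensor_ids: list[str]
    temperature: np.ndarray
    humidity: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.sensor_ids = [str(s) for s in self.sensor_ids]
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.humidity = np.asarray(self.humidity, dtype=float)
        self.validate()

    def validate(self) -> None:
        shape = (len(self.timestamps), len(self.sensor_ids))
        if self.temperature.shape != shape or self.humidity.shape != shape:
            raise CompletenessError(
                f"matrix shapes {self.temperature.shape}/{self.humidity.shape} "
                f"do not match |timestamps| x |sensors| = {shape}"
            )
        if len(set(self.sensor_ids)) != len(self.sensor_ids):
            raise FormatError("sensor_ids must be unique")
        if len(self.timestamps) > 1:
            steps = np.diff(self.timestamps.asi8)
            if not (steps > 0).all():
                raise FormatError("timestamps must be strictly increasing")
            if len(set(steps)) > 1:
                raise FormatError("timestamps must have a constant step")

    @property
    def n_times(self) -> int:
        return len(self.timestamps)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    def window(self, start, end) -> "EnvMatrix":
        """Restrict to timestamps in ``[start, end]`` (inclusive)."""
        start = pd.Timestamp(start)
        end = pd.Timestamp(end)
        mask = (self.timestamps >= start) & (self.timestamps <= end)
        if not mask.any():
            raise ValueError(f"window [{start}, {end}] contains no timestamps")
        return EnvMatrix(
            timestamps=self.timestamps[mask],
            sensor_ids=list(self.sensor_ids),
            temperature=self.temperature[mask],
            humidity=self.humidity[mask],
        )

    def sensor_index(self, sensor_id: str) -> int:
        return self.sensor_ids.index(sensor_id)


@dataclass
class SensorSample:
    """One sensor's analysis-window feature vector.

    ``features`` is the min-max normalized temperature series followed by the
    normalized humidity series; ``bins`` is the equal-width discretization of
    ``features`` into ``B`` integer levels, which feeds both the attribute
    similarity scores and the entropy mass functions.
    """

    sensor_id: str
    features: np.ndarray
    bins: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.bins = np.asarray(self.bins, dtype=int)
        if self.features.shape != self.bins.shape:
            raise ValueError("features and bins must have equal length")


@dataclass
class PipelineConfig:
    """Tunable parameters for the whole placement pipeline.

    The defaults mirror the study conditions: cluster counts scanned from 2
    to 8, summer = June-August, winter = December-February, 30-minute
    sampling.
    """

    k_min: int = 2
    k_max: int = 8
    season_windows: dict = field(
        default_factory=lambda: {
            "summer": ("2022-06-01", "2022-08-31"),
            "winter": ("2021-12-01", "2022-02-28"),
        }
    )
    bins: int = 10
    ensemble_size: int = 20
    seed: int = 0
    # PSO
    pso_inertia: float = 0.7
    pso_c1: float = 2.0
    pso_c2: float = 2.0
    pso_swarm_size: int = 30
    pso_max_iter: int = 200
    pso_stagnation: int = 20
    # GA
    ga_population: int = 30
    ga_generations: int = 100
    ga_base_mutation: float = 0.1
    # similarity weights: core-core, core-boundary, boundary-boundary matches
    sim_weights: tuple = (0.5, 0.3, 0.2)
    # fuzzy category cut points
    temp_cuts: tuple = (17.5, 22.5)
    humi_cuts: tuple = (65.5, 69.5)
    # placement ranking: "weighted" (equal-weight normalized sum) or
    # "lexicographic" (entropy first, validity index as tie-break)
    ranking_mode: str = "weighted"

    def __post_init__(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ConfigError(f"need 2 <= k_min <= k_max, got [{self.k_min}, {self.k_max}]")
        if self.bins < 2:
            raise ConfigError("bins must be >= 2")
        if self.ensemble_size < 2:
            raise ConfigError("ensemble_size must be >= 2")
        w = self.sim_weights
        if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError("similarity weights must be three values summing to 1")
        if not (w[0] >= w[1] >= w[2] >= 0):
            raise ConfigError("similarity weights must satisfy i1 >= i2 >= i3 >= 0")
        if self.ranking_mode not in ("weighted", "lexicographic"):
            raise ConfigError(f"unknown ranking_mode {self.ranking_mode!r}")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def read_env_csv(path) -> EnvMatrix:
    """Read a long-format sensor CSV into an :class:`EnvMatrix`.

    The file must have columns ``timestamp`` (ISO-8601), ``sensor_id``,
    ``temperature_c`` and ``relative_humidity_pct`` and contain exactly one
    row per (timestamp, sensor) cell of a complete grid.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing}; expected {list(CSV_COLUMNS)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    dup = df.duplicated(subset=["timestamp", "sensor_id"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise CompletenessError(
            f"duplicate row for ({row['timestamp']}, {row['sensor_id']})"
        )

    temp = df.pivot(index="timestamp", columns="sensor_id", values="temperature_c")
    humi = df.pivot(index="timestamp", columns="sensor_id", values="relative_humidity_pct")
    if temp.isna().any().any():
        col = temp.isna().any().idxmax()
        ts = temp.index[temp[col].isna()][0]
        raise CompletenessError(f"sensor {col} has no reading at {ts}")

    # natural sort of L-<n> labels; lexicographic fallback for other schemes
    sensor_ids = sorted(temp.columns, key=_sensor_sort_key)
    temp = temp[sensor_ids]
    humi = humi[sensor_ids]
    return EnvMatrix(
        timestamps=temp.index,
        sensor_ids=list(sensor_ids),
        temperature=temp.to_numpy(),
        humidity=humi.to_numpy(),
    )


def _sensor_sort_key(label: str):
    head, _, tail = str(label).rpartition("-")
    if tail.isdigit():
        return (0, head, int(tail))
    return (1, str(label), 0)


def write_env_csv(env: EnvMatrix, path) -> None:
    """Write an :class:`EnvMatrix` back to the long CSV dialect (6 decimals)."""
    n_t, n_s = env.temperature.shape
    df = pd.DataFrame(
        {
            "timestamp": np.repeat(env.timestamps.values, n_s),
            "sensor_id": np.tile(np.asarray(env.sensor_ids, dtype=object), n_t),
            "temperature_c": env.temperature.ravel(),
            "relative_humidity_pct": env.humidity.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f", date_format="%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(env: EnvMatrix, cfg: PipelineConfig | None = None,
               max_invalid_fraction: float = 0.5) -> EnvMatrix:
    """Replace physically impossible readings by linear interpolation in time.

    Readings outside the probes' measurement range (temperature -40..80 deg C,
    humidity 0..100 %RH) are treated as sensor faults and replaced by linear
    interpolation along the time axis (nearest valid value at the series
    edges).  A sensor with more than ``max_invalid_fraction`` faulty readings
    in either variable cannot be repaired and raises :class:`DataQualityError`.

    Idempotent on clean data.  Normalization is deliberately *not* applied
    here; it happens per analysis window in :func:`make_samples`.
    """
    temp = _repair(env.temperature, TEMPERATURE_RANGE, env.sensor_ids,
                   "temperature", max_invalid_fraction)
    humi = _repair(env.humidity, HUMIDITY_RANGE, env.sensor_ids,
                   "humidity", max_invalid_fraction)
    return EnvMatrix(env.timestamps, list(env.sensor_ids), temp, humi)


def _repair(values, rng, sensor_ids, name, max_invalid_fraction):
    lo, hi = rng
    invalid = ~np.isfinite(values) | (values < lo) | (values > hi)
    frac = invalid.mean(axis=0)
    bad = np.flatnonzero(frac > max_invalid_fraction)
    if bad.size:
        raise DataQualityError(
            f"sensor {sensor_ids[bad[0]]}: {frac[bad[0]]:.0%} of {name} readings "
            f"outside [{lo}, {hi}]"
        )
    if not invalid.any():
        return values.copy()
    df = pd.DataFrame(np.where(invalid, np.nan, values))
    df = df.interpolate(method="linear", axis=0, limit_direction="both")
    return df.to_numpy()


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def normalize_block(values: np.ndarray) -> np.ndarray:
    """Min-max normalize a whole window x sensor block to [0, 1].

    A zero-range block (constant variable) maps to 0 by convention.
    """
    lo = float(np.min(values))
    hi = float(np.max(values))
    if hi == lo:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def discretize(features: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning of [0, 1] features: ``floor(v * B)`` clipped to B-1."""
    return np.clip(np.floor(features * bins).astype(int), 0, bins - 1)


def make_samples(env: EnvMatrix, window=None,
                 cfg: PipelineConfig | None = None) -> list[SensorSample]:
    """Build one :class:`SensorSample` per sensor for an analysis window.

    Temperature and humidity are each min-max normalized over the whole
    window x sensor block (so inter-sensor offsets survive normalization),
    then concatenated per sensor into the feature vector that the clustering
    stages consume.
    """
    cfg = cfg or PipelineConfig()
    if window is not None:
        env = env.window(*window)
    if env.n_times == 0:
        raise ValueError("empty analysis window")
    temp = normalize_block(env.temperature)
    humi = normalize_block(env.humidity)
    samples = []
    for j, sid in enumerate(env.sensor_ids):
        feats = np.concatenate([temp[:, j], humi[:, j]])
        samples.append(SensorSample(sid, feats, discretize(feats, cfg.bins)))
    return samples


def feature_matrix(samples: list[SensorSample]) -> np.ndarray:
    """Stack sample feature vectors into an (n_samples, n_features) array."""
    return np.stack([s.features for s in samples])


def bin_matrix(samples: list[SensorSample]) -> np.ndarray:
    """Stack sample bin vectors into an (n_samples, n_features) int array."""
    return np.stack([s.bins for s in samples])
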