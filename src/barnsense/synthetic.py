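"""Synthetic barn microclimate generator with known ground truth.

Emulates a 30-sensor pig-house array: two layers of 3 x 5 sensor grids
sampled at a fixed interval over a configurable number of days.  Each
sensor's temperature is an annual sinusoid plus a diurnal sinusoid plus a
static spatial signature (planted zone offset, east-west column gradient
toward the fan wall, layer offset) plus Gaussian noise; humidity is a base
level anticorrelated with the temperature anomaly plus its own noise.  The
planted zone map is returned as ground truth so clustering stages can be
scored against a known partition.  :func:`plant_unstable` additionally gives
a chosen fraction of sensors a slowly wandering, zone-ambiguous offset and
inflated noise so they should land in the low-stability outer set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import EnvMatrix

__all__ = ["SceneSpec", "generate", "plant_unstable"]


@dataclass
class SceneSpec:
    """Geometry, climate and noise parameters of a synthetic barn scene.

    Defaults mirror the monitored house: 30 sensors (two layers of 3 rows x
    5 columns), readings every 30 minutes for a year starting 1 September,
    and an inter-sensor temperature spread of about 2.8 deg C.
    """

    rows: int = 3
    cols: int = 5
    layers: int = 2
    start: str = "2021-09-01 00:00"
    step_minutes: int = 30
    days: int = 365
    seed: int = 0
    # temperature model (deg C)
    temp_mean: float = 18.0
    seasonal_amp: float = 8.0
    diurnal_amp: float = 3.0
    zone_spread: float = 2.8     # max zone-offset difference
    col_gradient: float = 0.1    # per column, wet-curtain (east) -> fans (west)
    layer_offset: float = 0.2    # upper layer warmer
    temp_noise: float = 0.25
    # humidity model (%RH)
    humi_base: float = 72.0
    humi_coupling: float = 1.5   # %RH decrease per deg C of temperature anomaly
    humi_noise: float = 1.0
    # planted structure
    n_zones: int = 5
    zone_map: dict = field(default_factory=dict)  # sensor_id -> zone id

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.temp_noise < 0 or self.humi_noise < 0:
            raise ValueError("noise sigma must be >= 0")
        if not self.zone_map:
            self.zone_map = self.default_zone_map()
        missing = set(self.sensor_ids()) - set(self.zone_map)
        if missing:
            raise ValueError(f"zone map does not cover sensors {sorted(missing)}")

    @property
    def n_sensors(self) -> int:
        return self.rows * self.cols * self.layers

    def sensor_ids(self) -> list[str]:
        return [f"L-{i + 1}" for i in range(self.n_sensors)]

    def sensor_position(self, index: int) -> tuple[int, int, int]:
        """(layer, row, col) of the index-th sensor, row-major per layer."""
        per_layer = self.rows * self.cols
        layer, rest = divmod(index, per_layer)
        row, col = divmod(rest, self.cols)
        return layer, row, col

    def default_zone_map(self) -> dict:
        """Columns as zones (cycled if n_zones != cols), same for both layers."""
        mapping = {}
        for i in range(self.n_sensors):
            _, _, col = self.sensor_position(i)
            mapping[f"L-{i + 1}"] = col % self.n_zones
        return mapping

    def zone_offsets(self) -> np.ndarray:
        """Evenly spaced temperature offsets spanning ``zone_spread``."""
        if self.n_zones == 1:
            return np.zeros(1)
        z = np.arange(self.n_zones) / (self.n_zones - 1)
        return self.zone_spread * (z - 0.5)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zone_map"] = {k: int(v) for k, v in self.zone_map.items()}
        return d


def _timestamps(spec: SceneSpec) -> pd.DatetimeIndex:
    n = spec.days * 24 * 60 // spec.step_minutes
    return pd.date_range(spec.start, periods=n, freq=f"{spec.step_minutes}min")


def _deterministic_temperature(spec: SceneSpec, ts: pd.DatetimeIndex) -> np.ndarray:
    """(n_times, n_sensors) noise-free temperature field."""
    day_of_year = ts.dayofyear.to_numpy() + ts.hour.to_numpy() / 24.0
    hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    seasonal = spec.seasonal_amp * np.cos(2 * np.pi * (day_of_year - 196) / 365.25)
    diurnal = spec.diurnal_amp * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    base = spec.temp_mean + seasonal + diurnal  # shared by every sensor

    offsets = spec.zone_offsets()
    spatial = np.empty(spec.n_sensors)
    for i, sid in enumerate(spec.sensor_ids()):
        layer, _, col = spec.sensor_position(i)
        spatial[i] = (offsets[spec.zone_map[sid]]
                      + spec.col_gradient * col
                      + spec.layer_offset * (1 - layer))  # layer 0 = upper
    return base[:, None] + spatial[None, :]


def generate(spec: SceneSpec) -> tuple[EnvMatrix, dict]:
    """Generate an :class:`EnvMatrix` and its ground truth.

    Returns ``(env, truth)`` where ``truth`` holds the zone map, the planted
    unstable set (empty here; see :func:`plant_unstable`) and an echo of the
    scene parameters.
    """
    rng = np.random.default_rng(spec.seed)
    ts = _timestamps(spec)
    temp_det = _deterministic_temperature(spec, ts)
    temp = temp_det + rng.normal(0.0, spec.temp_noise, temp_det.shape)
    anomaly = temp_det - spec.temp_mean
    humi = (spec.humi_base - spec.humi_coupling * anomaly
            + rng.normal(0.0, spec.humi_noise, temp_det.shape))
    humi = np.clip(humi, 0.0, 100.0)
    env = EnvMatrix(timestamps=ts, sensor_ids=spec.sensor_ids(),
                    temperature=temp, humidity=humi)
    truth = {
        "zones": {sid: int(spec.zone_map[sid]) for sid in spec.sensor_ids()},
        "unstable": [],
        "spec": spec.to_dict(),
    }
    return env, truth


def plant_unstable(spec: SceneSpec, fraction: float) -> tuple[EnvMatrix, dict]:
    """Generate a scene where a fraction of sensors is deliberately unstable.

    ``ceil(fraction * n)`` sensors (chosen by the spec's seed) lose their
    static zone offset; instead their offset wanders across the full zone
    range as a slow sinusoid with a random phase and multi-day period, and
    their reading noise is quadrupled.  Such sensors sit between zones and
    drift, so clustering runs place them inconsistently — they should end up
    in the outer (low-stability) set.  The truth dict lists them under
    ``"unstable"``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(spec.seed)
    ts = _timestamps(spec)
    temp_det = _deterministic_temperature(spec, ts)

    n_unstable = math.ceil(fraction * spec.n_sensors)
    unstable_idx = np.sort(rng.choice(spec.n_sensors, size=n_unstable,
                                      replace=False))
    ids = spec.sensor_ids()

    hours = (ts - ts[0]) / pd.Timedelta(hours=1)
    hours = np.asarray(hours, dtype=float)
    amplitude = spec.zone_spread  # sweeps the whole planted offset range
    for i in unstable_idx:
        period_h = rng.uniform(48.0, 120.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        offsets = spec.zone_offsets()
        # drop the static zone offset, substitute the wandering one
        temp_det[:, i] -= offsets[spec.zone_map[ids[i]]]
        temp_det[:, i] += amplitude * np.sin(2 * np.pi * hours / period_h + phase)

    noise_scale = np.ones(spec.n_sensors)
    noise_scale[unstable_idx] = 4.0
    temp = temp_det + rng.normal(0.0, spec.temp_noise, temp_det.shape) * noise_scale
    anomaly = temp_det - spec.temp_mean
    humi = (spec.humi_base - spec.humi_coupling * anomaly
            + rng.normal(0.0, spec.humi_noise, temp_det.shape) * noise_scale)
    humi = np.clip(humi, 0.0, 100.0)
    env = EnvMatrix(timestamps=ts, sensor_ids=ids,
                    temperature=temp, humidity=humi)
    truth = {
        "zones": {sid: int(spec.zone_map[sid]) for sid in ids},
        "unstable": [ids[i] for i in unstable_idx],
        "spec": spec.to_dict(),
    }
    return env, truth
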