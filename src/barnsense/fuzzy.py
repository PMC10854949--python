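"""Fuzzy fusion of the selected sensors' readings into categorical labels.

Temperature is classified as Low / Moderate / High around the fattening-pig
comfort band (cuts at 17.5 and 22.5 deg C) and humidity as Dry / Suitable /
Humid (cuts at 65.5 and 69.5 %RH).  Each category carries a Gaussian
membership function: the middle category is centered on the band midpoint
with its width fixed so that membership is exactly 0.5 at each cut, and the
outer categories are one-sided (saturating at 1 beyond their centers) so
extreme readings are not penalized.  Each sensor votes for its
highest-membership category and the fused label is the majority vote, with
ties broken by the larger summed membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import EnvMatrix

__all__ = [
    "FuzzyBands",
    "FuzzyReading",
    "membership",
    "fuse",
    "classify_crisp",
    "fuse_series",
    "agreement_rate",
]

TEMP_CATEGORIES = ("Low", "Moderate", "High")
HUMI_CATEGORIES = ("Dry", "Suitable", "Humid")


@dataclass(frozen=True)
class FuzzyBands:
    """Two cut points and three ordered categories for one variable.

    ``sigma`` is fixed by the half-width of the middle band so that the
    Gaussian membership equals 0.5 exactly at each cut.
    """

    cuts: tuple[float, float]
    categories: tuple[str, str, str]

    def __post_init__(self) -> None:
        if not self.cuts[0] < self.cuts[1]:
            raise ValueError("cut points must be strictly increasing")

    @property
    def mid_center(self) -> float:
        return 0.5 * (self.cuts[0] + self.cuts[1])

    @property
    def half_width(self) -> float:
        return 0.5 * (self.cuts[1] - self.cuts[0])

    @property
    def sigma(self) -> float:
        # exp(-h^2 / (2 sigma^2)) = 0.5  =>  sigma = h / sqrt(2 ln 2)
        return self.half_width / math.sqrt(2.0 * math.log(2.0))

    @classmethod
    def temperature(cls, cuts=(17.5, 22.5)) -> "FuzzyBands":
        return cls(cuts=tuple(cuts), categories=TEMP_CATEGORIES)

    @classmethod
    def humidity(cls, cuts=(65.5, 69.5)) -> "FuzzyBands":
        return cls(cuts=tuple(cuts), categories=HUMI_CATEGORIES)


@dataclass
class FuzzyReading:
    """Fused label for one timestamp with the vote evidence behind it."""

    label: str
    margin: float  # top category's vote share
    votes: dict[str, int] = field(default_factory=dict)
    memberships: list[dict[str, float]] = field(default_factory=list)


def membership(value: float, bands: FuzzyBands) -> dict[str, float]:
    """Gaussian membership of a reading in each of the three categories.

    The lower category saturates at 1 below ``cut_low - half_width``, the
    upper above ``cut_high + half_width``; adjacent memberships cross at
    exactly 0.5 on the cuts.
    """
    lo_cut, hi_cut = bands.cuts
    h = bands.half_width
    two_s2 = 2.0 * bands.sigma ** 2
    lo_center = lo_cut - h
    hi_center = hi_cut + h

    def gauss(center):
        return math.exp(-((value - center) ** 2) / two_s2)

    low = 1.0 if value <= lo_center else gauss(lo_center)
    mid = gauss(bands.mid_center)
    high = 1.0 if value >= hi_center else gauss(hi_center)
    c_lo, c_mid, c_hi = bands.categories
    return {c_lo: low, c_mid: mid, c_hi: high}


def classify_crisp(value: float, bands: FuzzyBands) -> str:
    """Threshold classification; boundary values belong to the middle band."""
    lo_cut, hi_cut = bands.cuts
    if value < lo_cut:
        return bands.categories[0]
    if value <= hi_cut:
        return bands.categories[1]
    return bands.categories[2]


def fuse(readings, bands: FuzzyBands) -> FuzzyReading:
    """Majority vote over per-sensor argmax categories.

    Each sensor votes for its highest-membership category (membership ties
    within one sensor resolve toward the middle of the scale, matching the
    crisp rule that boundary values belong to the middle band).  Label ties
    across sensors break by the larger total membership mass; a residual tie
    falls back to category order.
    """
    readings = list(np.atleast_1d(np.asarray(readings, dtype=float)))
    if not readings:
        raise ValueError("need at least one sensor reading to fuse")
    votes: dict[str, int] = {c: 0 for c in bands.categories}
    mass: dict[str, float] = {c: 0.0 for c in bands.categories}
    per_sensor = []
    order = {c: i for i, c in enumerate(bands.categories)}
    for value in readings:
        m = membership(float(value), bands)
        per_sensor.append(m)
        # argmax with middle-preference on exact ties
        best = max(bands.categories,
                   key=lambda c: (m[c], -abs(order[c] - 1)))
        votes[best] += 1
        for c in bands.categories:
            mass[c] += m[c]
    label = max(bands.categories, key=lambda c: (votes[c], mass[c], -order[c]))
    margin = votes[label] / len(readings)
    return FuzzyReading(label=label, margin=margin, votes=votes,
                        memberships=per_sensor)


def fuse_series(env: EnvMatrix, sensors: list[str],
                temp_bands: FuzzyBands | None = None,
                humi_bands: FuzzyBands | None = None) -> list[dict]:
    """Per-timestamp fused temperature and humidity labels for a placement."""
    temp_bands = temp_bands or FuzzyBands.temperature()
    humi_bands = humi_bands or FuzzyBands.humidity()
    idx = [env.sensor_index(s) for s in sensors]
    out = []
    for t, ts in enumerate(env.timestamps):
        ft = fuse(env.temperature[t, idx], temp_bands)
        fh = fuse(env.humidity[t, idx], humi_bands)
        out.append({
            "ts": ts.isoformat(),
            "label_temp": ft.label,
            "label_humi": fh.label,
            "margin_temp": ft.margin,
            "margin_humi": fh.margin,
        })
    return out


def agreement_rate(env: EnvMatrix, sensors: list[str],
                   temp_bands: FuzzyBands | None = None,
                   humi_bands: FuzzyBands | None = None,
                   variable: str = "temperature",
                   exclude_margin: float = 0.0) -> float:
    """Percent of timestamps where the fused placement label matches the
    crisp category of the all-sensor average.

    ``exclude_margin`` drops timestamps whose all-sensor average lies within
    that distance of a cut point, where the crisp reference itself is
    ill-conditioned.
    """
    if env.n_times == 0:
        raise ValueError("empty window")
    missing = set(sensors) - set(env.sensor_ids)
    if missing:
        raise ValueError(f"placement sensors not in data: {sorted(missing)}")
    if variable == "temperature":
        bands = temp_bands or FuzzyBands.temperature()
        block = env.temperature
    elif variable == "humidity":
        bands = humi_bands or FuzzyBands.humidity()
        block = env.humidity
    else:
        raise ValueError(f"unknown variable {variable!r}")
    idx = [env.sensor_index(s) for s in sensors]
    overall = block.mean(axis=1)
    hits = 0
    considered = 0
    for t in range(env.n_times):
        if exclude_margin > 0.0 and min(abs(overall[t] - c) for c in bands.cuts) < exclude_margin:
            continue
        considered += 1
        fused = fuse(block[t, idx], bands)
        if fused.label == classify_crisp(overall[t], bands):
            hits += 1
    if considered == 0:
        raise ValueError("no timestamps left after excluding near-cut values")
    return 100.0 * hits / considered
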