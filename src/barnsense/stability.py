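"""Sample-stability analysis: co-occurrence ensemble and kernel/outer split.

Before any three-way clustering, the sensors are partitioned into a
high-stability *kernel* set and a low-stability *outer* set.  An ensemble of
plain k-means runs (varying k, varying seed) yields a co-occurrence matrix
``P`` whose entry ``P_ij`` is the fraction of runs assigning sensors i and j
to the same cluster.  A sample is stable when its co-occurrence pattern is
consistently near 0 or near 1; the stability score averages a tent-shaped
mapping of ``P_ij`` around a maximum-between-class-variance threshold.
Kernel samples later seed cluster cores; outer samples can only join cluster
boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core_io import ConfigError, PipelineConfig, SensorSample, feature_matrix

__all__ = [
    "ClusteringEnsemble",
    "StabilityResult",
    "build_ensemble",
    "cooccurrence",
    "max_variance_threshold",
    "sample_stability",
    "split_kernel_outer",
]

#: Number of candidate thresholds scanned in (0, 1).
THRESHOLD_GRID_SIZE = 256


@dataclass
class ClusteringEnsemble:
    """L label vectors over the same samples, one per base clustering run."""

    labelings: list[np.ndarray]
    member_params: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labelings) < 2:
            raise ConfigError("ensemble needs at least 2 clustering runs")
        n = len(self.labelings[0])
        if any(len(lab) != n for lab in self.labelings):
            raise ValueError("all label vectors must cover the same samples")
        self.labelings = [np.asarray(lab, dtype=int) for lab in self.labelings]

    @property
    def size(self) -> int:
        return len(self.labelings)

    @property
    def n_samples(self) -> int:
        return len(self.labelings[0])


@dataclass
class StabilityResult:
    """Co-occurrence matrix, thresholds and the kernel/outer split."""

    P: np.ndarray
    t0: float
    s: np.ndarray
    s0: float
    kernel_ids: list[str]
    outer_ids: list[str]

    def is_kernel(self, sensor_id: str) -> bool:
        return sensor_id in self._kernel_set

    def __post_init__(self) -> None:
        self._kernel_set = set(self.kernel_ids)
        if self._kernel_set & set(self.outer_ids):
            raise ValueError("kernel and outer sets must be disjoint")

    def to_dict(self) -> dict:
        return {
            "P": self.P.tolist(),
            "t0": self.t0,
            "s": self.s.tolist(),
            "s0": self.s0,
            "kernel_ids": list(self.kernel_ids),
            "outer_ids": list(self.outer_ids),
        }


def build_ensemble(samples: list[SensorSample],
                   cfg: PipelineConfig) -> ClusteringEnsemble:
    """Run plain k-means L times with k cycling over [k_min, k_max].

    Run ``l`` uses ``k = k_min + (l mod (k_max - k_min + 1))`` (clipped to the
    sample count) and seed ``cfg.seed + l``, so the ensemble is deterministic
    under a fixed base seed.
    """
    n = len(samples)
    if n < 2:
        raise ConfigError("need at least 2 samples to build an ensemble")
    X = feature_matrix(samples)
    k_values = range(cfg.k_min, cfg.k_max + 1)
    k_cycle = [min(k, n) for k in k_values]
    labelings, params = [], []
    for run in range(cfg.ensemble_size):
        k = k_cycle[run % len(k_cycle)]
        seed = cfg.seed + run
        km = KMeans(n_clusters=k, n_init=1, random_state=seed)
        labelings.append(km.fit_predict(X))
        params.append({"k": k, "seed": seed})
    return ClusteringEnsemble(labelings, params)


def cooccurrence(ens: ClusteringEnsemble) -> np.ndarray:
    """Fraction of ensemble runs co-assigning each sample pair.

    Symmetric with unit diagonal; entries in [0, 1].
    """
    n = ens.n_samples
    P = np.zeros((n, n))
    for lab in ens.labelings:
        P += (lab[:, None] == lab[None, :])
    return P / ens.size


def max_variance_threshold(values: np.ndarray) -> float:
    """Maximum between-class variance (Otsu-style) threshold on [0, 1] scores.

    Scans a uniform grid of 256 candidate thresholds in (0, 1); each
    candidate splits the scores into a below/above pair of classes and is
    scored by the weighted between-class variance
    ``sigma_t = w0*(mu0 - mu)^2 + w1*(mu1 - mu)^2``.  Ties break toward the
    smaller threshold.  If every score is identical the variance is flat
    everywhere; 0.5 is returned with a warning.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values to pick a threshold")
    if np.ptp(values) == 0.0:
        warnings.warn("all scores identical; between-class variance is flat, "
                      "returning threshold 0.5", stacklevel=2)
        return 0.5
    grid = np.arange(1, THRESHOLD_GRID_SIZE + 1) / (THRESHOLD_GRID_SIZE + 1)
    mu = values.mean()
    best_t, best_sigma = grid[0], -1.0
    for t in grid:
        below = values < t
        w0 = below.mean()
        w1 = 1.0 - w0
        if w0 == 0.0 or w1 == 0.0:
            continue
        mu0 = values[below].mean()
        mu1 = values[~below].mean()
        sigma = w0 * (mu0 - mu) ** 2 + w1 * (mu1 - mu) ** 2
        if sigma > best_sigma + 1e-15:
            best_t, best_sigma = t, sigma
    if best_sigma < 0.0:
        # every grid point put all mass on one side (scores outside (0,1) grid)
        warnings.warn("no threshold separates the scores; returning 0.5",
                      stacklevel=2)
        return 0.5
    return float(best_t)


def stability_mapping(P: np.ndarray, t0: float) -> np.ndarray:
    """Tent map sending co-occurrence values near 0 or 1 to high confidence.

    ``f(p) = (t0 - p)/t0`` below the threshold and ``(p - t0)/(1 - t0)``
    above it, so f(t0) = 0 and f(0) = f(1) = 1.
    """
    if not (0.0 < t0 < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {t0}")
    P = np.asarray(P, dtype=float)
    return np.where(P < t0, np.abs(P - t0) / t0, np.abs(P - t0) / (1.0 - t0))


def sample_stability(P: np.ndarray, t0: float) -> np.ndarray:
    """Per-sample stability: mean mapped co-occurrence against all samples."""
    return stability_mapping(P, t0).mean(axis=1)


def split_kernel_outer(samples: list[SensorSample],
                       ens: ClusteringEnsemble) -> StabilityResult:
    """Full stability chain: P -> t0 -> s -> s0 -> kernel/outer sets.

    Kernel = samples with stability strictly above the stability threshold
    ``s0``; the rest form the outer set.  In the degenerate case where every
    stability score is identical (e.g. all ensemble runs agree exactly), all
    samples are placed in the kernel so that monitoring can proceed.
    """
    if len(samples) != ens.n_samples:
        raise ValueError("samples and ensemble cover different universes")
    P = cooccurrence(ens)
    ids = [s.sensor_id for s in samples]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t0 = max_variance_threshold(P.ravel())
    s = sample_stability(P, t0)
    if np.ptp(s) == 0.0:
        # flat stability: everything is equally (un)stable -> keep all kernel
        return StabilityResult(P=P, t0=t0, s=s, s0=0.5,
                               kernel_ids=list(ids), outer_ids=[])
    s0 = max_variance_threshold(s)
    kernel = [ids[i] for i in range(len(ids)) if s[i] > s0]
    outer = [ids[i] for i in range(len(ids)) if s[i] <= s0]
    if not kernel:
        # threshold above every score: fall back to keeping all samples kernel
        kernel, outer = list(ids), []
    return StabilityResult(P=P, t0=t0, s=s, s0=s0,
                           kernel_ids=kernel, outer_ids=outer)
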