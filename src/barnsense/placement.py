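"""Sensor-combination generation, joint-entropy scoring and seasonal selection.

After clustering, each cluster contributes two candidate sensors: the sensor
nearest its centroid and the second nearest (one for singletons).  Taking one
candidate per cluster enumerates the combination pool — for five 2-candidate
clusters that is 2^5 = 32 combinations instead of the C(30,5) = 142,506 of a
brute-force scan.  Each combination is scored per variable by its *total
entropy*: the entropies of the selected sensors plus the joint entropies
linking every unselected sensor to every selected one, so a good combination
is both informative itself and informative about the sensors it replaces.
Across cluster counts, the winner maximizes an equal-weight sum of the
min-max-normalized total entropy and the three-way clustering validity index
(mean intra-cluster minus mean inter-cluster similarity).  The chosen
combination is validated by the RMSE and MAPE of its mean reading (the
*combination trend*) against the all-sensor mean (the *reference trend*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clustering import ThreeWayClustering, distance
from .core_io import (
    EnvMatrix,
    PipelineConfig,
    SensorSample,
    discretize,
    make_samples,
    normalize_block,
)
from .ga import ga_threeway
from .pso import pso_threeway
from .recluster import (
    SimilarityWeights,
    inter_similarity,
    intra_similarity,
    recluster,
)
from .stability import build_ensemble, split_kernel_outer

__all__ = [
    "PlacementCandidate",
    "PlacementReport",
    "candidates_from_clusters",
    "enumerate_combinations",
    "entropy",
    "joint_entropy",
    "total_entropy",
    "twcvi",
    "select_placement",
    "rmse",
    "mape",
    "fuse_seasonal",
]


@dataclass
class PlacementCandidate:
    """A sensor combination with its scores and validation errors."""

    sensor_ids: list[str]
    entropy_temp: float = float("nan")
    entropy_humi: float = float("nan")
    twcvi: float = float("nan")
    rmse_temp: float = float("nan")
    rmse_humi: float = float("nan")
    mape_temp: float = float("nan")
    mape_humi: float = float("nan")

    def __post_init__(self) -> None:
        if len(set(self.sensor_ids)) != len(self.sensor_ids):
            raise ValueError("combination contains a duplicate sensor")

    def to_dict(self) -> dict:
        return {
            "sensors": list(self.sensor_ids),
            "entropy_temp": self.entropy_temp,
            "entropy_humi": self.entropy_humi,
            "twcvi": self.twcvi,
            "rmse_temp": self.rmse_temp,
            "rmse_humi": self.rmse_humi,
            "mape_temp": self.mape_temp,
            "mape_humi": self.mape_humi,
        }


@dataclass
class PlacementReport:
    """Per-k scan records plus the chosen combination for one season."""

    season: str
    algo: str
    per_k: list[dict] = field(default_factory=list)
    chosen_k: int = -1
    chosen: PlacementCandidate | None = None

    def to_dict(self) -> dict:
        return {
            "season": self.season,
            "algo": self.algo,
            "per_k": self.per_k,
            "chosen_k": self.chosen_k,
            "chosen": self.chosen.to_dict() if self.chosen else None,
        }


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def candidates_from_clusters(tw: ThreeWayClustering,
                             samples: list[SensorSample]) -> list[list[str]]:
    """Per cluster, the sensor nearest the centroid and the second nearest.

    Singleton clusters contribute a single candidate.  Returns one candidate
    list per cluster, ordered by cluster index.
    """
    by_id = {s.sensor_id: s for s in samples}
    out: list[list[str]] = []
    for cluster in tw.clusters:
        members = cluster.member_ids
        if not members:
            raise ValueError("cannot draw candidates from an empty cluster")
        ranked = sorted(members,
                        key=lambda sid: (distance(by_id[sid].features,
                                                  cluster.center), sid))
        out.append(ranked[: min(2, len(ranked))])
    return out


def enumerate_combinations(candidates: list[list[str]]) -> list[list[str]]:
    """All combinations taking one candidate sensor per cluster."""
    import itertools

    return [list(combo) for combo in itertools.product(*candidates)]


# ---------------------------------------------------------------------------
# Entropy machinery
# ---------------------------------------------------------------------------

def entropy(values) -> float:
    """Shannon entropy (bits) of the empirical distribution of a discrete
    vector; the 0*log(0) convention contributes nothing."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def joint_entropy(x, y) -> float:
    """Shannon entropy (bits) of the empirical joint distribution of two
    equally long discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    pairs = np.stack([x, y], axis=-1).reshape(-1, 2)
    _, counts = np.unique(pairs, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(y, x) -> float:
    """H(Y|X) = H(X,Y) - H(X) in bits (standard empirical form)."""
    return joint_entropy(x, y) - entropy(x)


def total_entropy(selected: list[str], all_sensors: list[str],
                  series_by_id: dict[str, np.ndarray],
                  pair_table: dict[frozenset, float] | None = None) -> float:
    """Total entropy of a sensor combination for one variable (bits).

    Sum of the selected sensors' own entropies plus, for every unselected
    sensor, its joint entropy with every selected sensor — the information
    the rest of the array delivers through the chosen one.
    ``pair_table`` optionally caches pairwise joint entropies keyed by
    ``frozenset({u, s})``.
    """
    if not selected:
        raise ValueError("empty sensor selection")
    unknown = set(selected) - set(all_sensors)
    if unknown:
        raise ValueError(f"selected sensors not in pool: {sorted(unknown)}")
    sel = list(selected)
    unsel = [s for s in all_sensors if s not in set(sel)]
    total = sum(entropy(series_by_id[s]) for s in sel)
    for u in unsel:
        for s in sel:
            if pair_table is not None:
                key = frozenset((u, s))
                if key not in pair_table:
                    pair_table[key] = joint_entropy(series_by_id[u], series_by_id[s])
                total += pair_table[key]
            else:
                total += joint_entropy(series_by_id[u], series_by_id[s])
    return float(total)


def discretized_series(env: EnvMatrix, bins: int) -> dict[str, dict[str, np.ndarray]]:
    """Per-variable, per-sensor bin sequences for entropy computation.

    Each variable is min-max normalized over the whole window x sensor block
    and equal-width binned, matching the discretization used for the
    similarity scores.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, block in (("temperature", env.temperature), ("humidity", env.humidity)):
        norm = discretize(normalize_block(block), bins)
        out[name] = {sid: norm[:, j] for j, sid in enumerate(env.sensor_ids)}
    return out


# ---------------------------------------------------------------------------
# Validity index
# ---------------------------------------------------------------------------

def twcvi(tw: ThreeWayClustering, samples: list[SensorSample],
          w: SimilarityWeights) -> float:
    """Three-way clustering validity index: mean intra-cluster similarity
    minus mean pairwise inter-cluster similarity.  Undefined for k = 1."""
    if tw.k < 2:
        raise ValueError("validity index needs at least 2 clusters")
    by_id = {s.sensor_id: s for s in samples}
    intra = float(np.mean([intra_similarity(c, by_id, w) for c in tw.clusters]))
    pairs = [(m, n) for m in range(tw.k) for n in range(m + 1, tw.k)]
    inter = float(np.mean([inter_similarity(tw.clusters[m], tw.clusters[n], by_id, w)
                           for m, n in pairs]))
    return intra - inter


# ---------------------------------------------------------------------------
# Validation metrics
# ---------------------------------------------------------------------------

def rmse(c, r) -> float:
    """Root-mean-square error between combination and reference trends."""
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    if c.shape != r.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {r.shape}")
    if c.size == 0:
        raise ValueError("empty trends")
    return float(np.sqrt(np.mean((c - r) ** 2)))


def mape(c, r) -> float:
    """Mean absolute percentage error (%) of c against reference r."""
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    if c.shape != r.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {r.shape}")
    zero = np.flatnonzero(r == 0.0)
    if zero.size:
        raise ValueError(f"reference trend is zero at index {zero[0]}")
    return float(100.0 * np.mean(np.abs((c - r) / r)))


def _trend(env: EnvMatrix, sensors: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(temperature, humidity) mean trends over the given sensors (all by default)."""
    if sensors is None:
        idx = slice(None)
    else:
        idx = [env.sensor_index(s) for s in sensors]
    return env.temperature[:, idx].mean(axis=1), env.humidity[:, idx].mean(axis=1)


def evaluate_combination(env: EnvMatrix, sensors: list[str]) -> dict[str, float]:
    """RMSE and MAPE of a combination's trend against the all-sensor trend."""
    ref_t, ref_h = _trend(env)
    com_t, com_h = _trend(env, sensors)
    return {
        "rmse_temp": rmse(com_t, ref_t),
        "rmse_humi": rmse(com_h, ref_h),
        "mape_temp": mape(com_t, ref_t),
        "mape_humi": mape(com_h, ref_h),
    }


# ---------------------------------------------------------------------------
# Seasonal selection
# ---------------------------------------------------------------------------

def select_placement(env: EnvMatrix, window, algo: str, cfg: PipelineConfig,
                     season: str = "", rng: np.random.Generator | None = None,
                     stride: int = 1) -> PlacementReport:
    """Full per-season pipeline: stability split, k scan, entropy ranking.

    For each k in ``[k_min, k_max]``: cluster with the chosen optimizer
    (``pso`` or ``ga``), apply the re-clustering pass, enumerate the
    candidate combinations and keep the one maximizing the summed
    (per-variable min-max normalized) total entropy.  Across k the winner
    maximizes the equal-weight sum of normalized total entropy and TWCVI
    (``cfg.ranking_mode == "lexicographic"`` ranks by entropy first
    instead); ties go to the smallest k.  ``stride`` subsamples the window's
    timestamps for feature building and entropy scoring; validation errors
    are always computed on the full window.
    """
    if algo not in ("pso", "ga"):
        raise ValueError(f"unknown algorithm {algo!r}; expected 'pso' or 'ga'")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    env_w = env.window(*window)
    env_feat = env_w if stride <= 1 else EnvMatrix(
        env_w.timestamps[::stride], list(env_w.sensor_ids),
        env_w.temperature[::stride], env_w.humidity[::stride])

    samples = make_samples(env_feat, cfg=cfg)
    ens = build_ensemble(samples, cfg)
    stability = split_kernel_outer(samples, ens)
    weights = SimilarityWeights.from_config(cfg)
    series = discretized_series(env_feat, cfg.bins)
    pair_tables = {"temperature": {}, "humidity": {}}

    per_k: list[dict] = []
    records: list[tuple[int, float, float, PlacementCandidate]] = []
    for k in range(cfg.k_min, min(cfg.k_max, len(samples)) + 1):
        if algo == "pso":
            tw = pso_threeway(samples, stability, k, cfg, rng=rng)
        else:
            tw = ga_threeway(samples, stability, cfg, k=k, rng=rng)
        report = recluster(tw, samples, stability, weights, cfg, rng=rng)
        final = report.result
        validity = twcvi(final, samples, weights) if final.k >= 2 else float("nan")

        combos = enumerate_combinations(candidates_from_clusters(final, samples))
        scored = []
        for combo in combos:
            e_t = total_entropy(combo, env_feat.sensor_ids,
                                series["temperature"], pair_tables["temperature"])
            e_h = total_entropy(combo, env_feat.sensor_ids,
                                series["humidity"], pair_tables["humidity"])
            scored.append((combo, e_t, e_h))
        best_combo, e_t, e_h = _best_by_normalized_entropy(scored)
        cand = PlacementCandidate(sensor_ids=sorted(best_combo, key=_sensor_key),
                                  entropy_temp=e_t, entropy_humi=e_h,
                                  twcvi=validity)
        records.append((k, e_t + e_h, validity, cand))
        per_k.append({
            "k": k,
            "k_final": final.k,
            "n_combinations": len(combos),
            "entropy_temp": e_t,
            "entropy_humi": e_h,
            "twcvi": validity,
            "best_combo": cand.sensor_ids,
        })

    chosen_k, chosen = _rank_across_k(records, cfg.ranking_mode)
    metrics = evaluate_combination(env_w, chosen.sensor_ids)
    chosen.rmse_temp = metrics["rmse_temp"]
    chosen.rmse_humi = metrics["rmse_humi"]
    chosen.mape_temp = metrics["mape_temp"]
    chosen.mape_humi = metrics["mape_humi"]
    return PlacementReport(season=season, algo=algo, per_k=per_k,
                           chosen_k=chosen_k, chosen=chosen)


def _best_by_normalized_entropy(scored):
    """Best combination by summed per-variable min-max normalized entropy.

    Deterministic tie-break on the sorted sensor labels.
    """
    e_t = np.array([s[1] for s in scored])
    e_h = np.array([s[2] for s in scored])
    n_t = _minmax(e_t)
    n_h = _minmax(e_h)
    totals = n_t + n_h
    order = sorted(range(len(scored)),
                   key=lambda i: (-totals[i], sorted(scored[i][0])))
    return scored[order[0]]


def _minmax(v: np.ndarray) -> np.ndarray:
    span = np.ptp(v)
    if span == 0.0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def _rank_across_k(records, mode: str):
    ks = [r[0] for r in records]
    ent = np.array([r[1] for r in records])
    tv = np.array([0.0 if math.isnan(r[2]) else r[2] for r in records])
    if mode == "lexicographic":
        order = sorted(range(len(records)), key=lambda i: (-ent[i], -tv[i], ks[i]))
    else:
        score = _minmax(ent) + _minmax(tv)
        order = sorted(range(len(records)), key=lambda i: (-score[i], ks[i]))
    best = order[0]
    return ks[best], records[best][3]


def _sensor_key(label: str):
    head, _, tail = str(label).rpartition("-")
    if tail.isdigit():
        return (0, head, int(tail))
    return (1, str(label), 0)


def fuse_seasonal(a: PlacementReport, b: PlacementReport) -> list[str]:
    """Union of two seasons' chosen sensor sets, ordered by sensor label."""
    if a.chosen is None or b.chosen is None:
        raise ValueError("both reports must carry a chosen combination")
    return sorted(set(a.chosen.sensor_ids) | set(b.chosen.sensor_ids),
                  key=_sensor_key)
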