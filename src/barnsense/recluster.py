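"""Within-cluster similarity, re-clustering of weak clusters, and result merging.

Cohesion is measured on discretized attributes rather than raw distances: two
samples score ``i1``/``i2``/``i3`` per matching attribute bin depending on
whether the pair is core-core, core-boundary or boundary-boundary (weights
sum to 1, ordered ``i1 >= i2 >= i3``), and 0 on mismatching bins.  A
cluster's *re-clustering potential* is the ratio of the mean within-cluster
similarity over all clusters to its own; a ratio above 1 marks the cluster
as under-cohesive and splits it into ``ceil(ratio)`` subclusters with a PSO
pass over its members.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import ThreeWayCluster, ThreeWayClustering, assign_three_way
from .core_io import PipelineConfig, SensorSample
from .pso import optimize_centers_pso
from .stability import StabilityResult

__all__ = [
    "SimilarityWeights",
    "ReclusterReport",
    "pair_similarity",
    "intra_similarity",
    "inter_similarity",
    "mean_intra_similarity",
    "recluster",
    "combine_results",
]


@dataclass(frozen=True)
class SimilarityWeights:
    """Scores per matching attribute for core-core / core-boundary /
    boundary-boundary pairs; must sum to 1 with i1 >= i2 >= i3 >= 0."""

    i1: float = 0.5
    i2: float = 0.3
    i3: float = 0.2

    def __post_init__(self) -> None:
        if abs(self.i1 + self.i2 + self.i3 - 1.0) > 1e-9:
            raise ValueError("similarity weights must sum to 1")
        if not (self.i1 >= self.i2 >= self.i3 >= 0.0):
            raise ValueError("weights must satisfy i1 >= i2 >= i3 >= 0")

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "SimilarityWeights":
        return cls(*cfg.sim_weights)

    def score(self, a_core: bool, b_core: bool) -> float:
        if a_core and b_core:
            return self.i1
        if a_core or b_core:
            return self.i2
        return self.i3


@dataclass
class ReclusterReport:
    """Outcome of one re-clustering pass."""

    intra_per_cluster: list[float]
    mean_intra: float
    ratios: list[float]
    split_clusters: dict[int, int]  # original cluster index -> subcluster count
    result: ThreeWayClustering
    mean_intra_after: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "intra_per_cluster": self.intra_per_cluster,
            "mean_intra": self.mean_intra,
            "ratios": [r if math.isfinite(r) else None for r in self.ratios],
            "split_clusters": {str(k): v for k, v in self.split_clusters.items()},
            "mean_intra_after": self.mean_intra_after,
            "result": self.result.to_dict(),
        }


def pair_similarity(a: SensorSample, b: SensorSample,
                    a_core: bool, b_core: bool,
                    w: SimilarityWeights) -> float:
    """Attribute-wise similarity of two samples given their region roles.

    Mean over attributes of the role weight where the bins match, 0 where
    they differ.
    """
    if a.bins.shape != b.bins.shape:
        raise ValueError("samples have different attribute counts")
    score = w.score(a_core, b_core)
    return float(score * (a.bins == b.bins).mean())


def intra_similarity(cluster: ThreeWayCluster, samples_by_id: dict[str, SensorSample],
                     w: SimilarityWeights) -> float:
    """Mean pairwise similarity within a cluster (1 for singletons)."""
    ids = cluster.member_ids
    n = len(ids)
    if n < 2:
        # a singleton cannot be split further; treat as maximally cohesive
        return 1.0
    core = set(cluster.core_ids)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += pair_similarity(samples_by_id[ids[i]], samples_by_id[ids[j]],
                                     ids[i] in core, ids[j] in core, w)
    return 2.0 * total / (n * (n - 1))


def inter_similarity(a: ThreeWayCluster, b: ThreeWayCluster,
                     samples_by_id: dict[str, SensorSample],
                     w: SimilarityWeights) -> float:
    """Mean pairwise similarity across two clusters."""
    core_a, core_b = set(a.core_ids), set(b.core_ids)
    total = 0.0
    for i in a.member_ids:
        for j in b.member_ids:
            total += pair_similarity(samples_by_id[i], samples_by_id[j],
                                     i in core_a, j in core_b, w)
    return total / (a.size * b.size)


def mean_intra_similarity(tw: ThreeWayClustering,
                          samples_by_id: dict[str, SensorSample],
                          w: SimilarityWeights) -> float:
    return float(np.mean([intra_similarity(c, samples_by_id, w)
                          for c in tw.clusters]))


def recluster(tw: ThreeWayClustering, samples: list[SensorSample],
              stability: StabilityResult,
              w: SimilarityWeights, cfg: PipelineConfig,
              rng: np.random.Generator | None = None) -> ReclusterReport:
    """Split under-cohesive clusters; single pass.

    For each cluster m, ``ratio_m = mean IntraS / IntraS(C_m)``.  Clusters
    with ``ratio_m > 1`` are re-clustered into ``ceil(ratio_m)`` subclusters
    (capped at the cluster size) by a PSO pass over their members; a cluster
    with IntraS = 0 has unbounded potential and splits into
    ``min(size, k_max)`` subclusters.  Cohesive clusters pass through.

    Splits are applied worst-cohesion-first and each is committed only if it
    does not decrease the running mean within-cluster similarity (splitting
    gives a weak cluster's fragments more weight in the equally-weighted
    mean, so even a locally improving split can drag the mean down); the
    pass therefore never reduces average cohesion.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    samples_by_id = {s.sensor_id: s for s in samples}
    intra = [intra_similarity(c, samples_by_id, w) for c in tw.clusters]
    mean_intra = float(np.mean(intra))

    ratios: list[float] = []
    split_plan: dict[int, int] = {}
    for m, value in enumerate(intra):
        if value == 0.0:
            warnings.warn(f"cluster {m} has zero within-cluster similarity; "
                          "splitting into the maximum subcluster count",
                          stacklevel=2)
            ratios.append(float("inf"))
            split_plan[m] = min(tw.clusters[m].size, cfg.k_max)
            continue
        ratio = mean_intra / value
        ratios.append(ratio)
        if ratio > 1.0:
            sub_k = min(math.ceil(ratio), tw.clusters[m].size)
            if sub_k >= 2:
                split_plan[m] = sub_k

    # evaluate proposals worst-cohesion-first; commit only mean-preserving ones
    pieces: dict[int, list[ThreeWayCluster]] = {m: [c] for m, c in enumerate(tw.clusters)}
    intra_of: dict[int, list[float]] = {m: [v] for m, v in enumerate(intra)}
    accepted: dict[int, int] = {}
    for m in sorted(split_plan, key=lambda m: -ratios[m]):
        members = [samples_by_id[i] for i in tw.clusters[m].member_ids]
        sub = _split_cluster(members, stability, split_plan[m], cfg, rng)
        sub_clusters = [c for c in sub.clusters if c.size > 0]
        if len(sub_clusters) < 2:
            continue
        sub_intra = [intra_similarity(c, samples_by_id, w) for c in sub_clusters]
        current = [v for vals in intra_of.values() for v in vals]
        candidate = ([v for mm, vals in intra_of.items() if mm != m for v in vals]
                     + sub_intra)
        if np.mean(candidate) >= np.mean(current) - 1e-12:
            pieces[m] = sub_clusters
            intra_of[m] = sub_intra
            accepted[m] = len(sub_clusters)
    split_plan = accepted

    new_clusters = [c for m in range(tw.k) for c in pieces[m]]
    result = ThreeWayClustering(clusters=new_clusters)
    result.validate()
    report = ReclusterReport(
        intra_per_cluster=intra,
        mean_intra=mean_intra,
        ratios=ratios,
        split_clusters=split_plan,
        result=result,
        mean_intra_after=mean_intra_similarity(result, samples_by_id, w),
    )
    return report


def _split_cluster(members: list[SensorSample], stability: StabilityResult,
                   sub_k: int, cfg: PipelineConfig,
                   rng: np.random.Generator) -> ThreeWayClustering:
    """PSO three-way pass restricted to one cluster's members."""
    from .core_io import feature_matrix  # local import to avoid cycle noise

    X = feature_matrix(members)
    kernel_idx = [i for i, s in enumerate(members) if stability.is_kernel(s.sensor_id)]
    kernel_X = X[kernel_idx] if kernel_idx else X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centers, value, _ = optimize_centers_pso(X, kernel_X, sub_k, cfg, rng)
    return assign_three_way(members, centers, stability, fitness=value)


def combine_results(a: ThreeWayClustering, b: ThreeWayClustering,
                    stability: StabilityResult | None = None) -> ThreeWayClustering:
    """Consensus of two clusterings by co-membership intersection.

    Samples sharing both their cluster in ``a`` and their cluster in ``b``
    form one output cluster; every non-empty intersection becomes a cluster
    (singletons allowed), so the output refines both inputs.  Core/boundary
    status is preserved per sample (from ``stability`` if given, else from
    the roles recorded in ``a``).  Output centroids are the means of the
    member feature positions of the input-``a`` centers weighted equally,
    i.e. the midpoint of the two parent centers.
    """
    ids_a, ids_b = set(a.all_ids()), set(b.all_ids())
    if ids_a != ids_b:
        raise ValueError("clusterings cover different sample universes")
    labels_a, labels_b = a.labels(), b.labels()
    core_a = {sid for c in a.clusters for sid in c.core_ids}

    groups: dict[tuple[int, int], list[str]] = {}
    for sid in sorted(ids_a, key=lambda s: (labels_a[s], labels_b[s], s)):
        groups.setdefault((labels_a[sid], labels_b[sid]), []).append(sid)

    clusters = []
    for (ma, mb), members in sorted(groups.items()):
        center = (a.clusters[ma].center + b.clusters[mb].center) / 2.0
        cluster = ThreeWayCluster(center=center)
        for sid in members:
            is_core = stability.is_kernel(sid) if stability is not None else sid in core_a
            (cluster.core_ids if is_core else cluster.boundary_ids).append(sid)
        clusters.append(cluster)
    out = ThreeWayClustering(clusters=clusters)
    out.validate()
    return out
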