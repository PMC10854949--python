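"""Shared three-way k-means machinery: distance, SSE fitness, assignment.

A *three-way* clustering gives every cluster two member sets: a **core**
(certain members, drawn from the high-stability kernel samples) and a
**boundary** or fringe (possible members, drawn from the low-stability outer
samples).  Both optimizer front-ends (particle swarm and genetic) share the
machinery here: Euclidean distance, the sum-of-squared-errors objective, and
the nearest-center core/boundary assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import SensorSample, feature_matrix
from .stability import StabilityResult

__all__ = [
    "ThreeWayCluster",
    "ThreeWayClustering",
    "distance",
    "nearest_centers",
    "sse_fitness",
    "assign_three_way",
    "lloyd_step",
    "repair_empty_clusters",
]


@dataclass
class ThreeWayCluster:
    """One cluster: its centroid, core member ids and boundary member ids."""

    center: np.ndarray
    core_ids: list[str] = field(default_factory=list)
    boundary_ids: list[str] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return list(self.core_ids) + list(self.boundary_ids)

    @property
    def size(self) -> int:
        return len(self.core_ids) + len(self.boundary_ids)


@dataclass
class ThreeWayClustering:
    """A full three-way clustering with its SSE fitness value."""

    clusters: list[ThreeWayCluster]
    fitness: float = float("nan")

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def centers(self) -> np.ndarray:
        return np.stack([c.center for c in self.clusters])

    def all_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.clusters:
            out.extend(c.member_ids)
        return out

    def labels(self) -> dict[str, int]:
        """Map each sample id to its cluster index (core or boundary alike)."""
        return {sid: m for m, c in enumerate(self.clusters) for sid in c.member_ids}

    def validate(self) -> None:
        ids = self.all_ids()
        if len(ids) != len(set(ids)):
            raise ValueError("a sample appears in more than one cluster region")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fitness": self.fitness,
            "clusters": [
                {
                    "center": c.center.tolist(),
                    "core_ids": list(c.core_ids),
                    "boundary_ids": list(c.boundary_ids),
                }
                for c in self.clusters
            ],
        }


def distance(x: np.ndarray, c: np.ndarray) -> float:
    """Euclidean distance between a sample vector and a center."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {c.shape}")
    return float(np.linalg.norm(x - c))


def nearest_centers(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Index of the nearest center per row of X; ties -> lowest index."""
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)  # argmin takes the first minimum, our tie rule


def sse_fitness(X: np.ndarray, centers: np.ndarray,
                assignment: np.ndarray | None = None) -> float:
    """Sum of squared distances from each sample to its assigned center.

    With no explicit assignment, samples are assigned to their nearest
    center.  Empty clusters simply contribute nothing.
    """
    X = np.asarray(X, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if assignment is None:
        assignment = nearest_centers(X, centers)
    diff = X - centers[assignment]
    return float((diff ** 2).sum())


def lloyd_step(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """One Lloyd iteration: assign to nearest center, recenter on the mean.

    Centers with no assigned samples are left in place.
    """
    assignment = nearest_centers(X, centers)
    new = centers.copy()
    for m in range(len(centers)):
        members = X[assignment == m]
        if len(members):
            new[m] = members.mean(axis=0)
    return new


def repair_empty_clusters(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Reseed any center with no assigned samples.

    The empty center moves to the sample farthest from its current center,
    which peels the worst-represented sample into its own cluster.  Repeated
    until every center owns at least one sample or no pass makes progress
    (duplicate samples can leave a center permanently empty; such clusters
    stay empty and contribute nothing to the SSE).
    """
    centers = np.asarray(centers, dtype=float).copy()
    k = len(centers)
    if k > len(X):
        raise ValueError("cannot repair: more centers than samples")
    n_empty_before = k + 1
    for _ in range(k):
        assignment = nearest_centers(X, centers)
        empty = [m for m in range(k) if not (assignment == m).any()]
        if not empty or len(empty) >= n_empty_before:
            break
        n_empty_before = len(empty)
        dist_to_own = np.linalg.norm(X - centers[assignment], axis=1)
        for m in empty:
            far = int(dist_to_own.argmax())
            centers[m] = X[far]
            dist_to_own[far] = -1.0  # don't reuse the same sample this pass
    return centers


def assign_three_way(samples: list[SensorSample], centers: np.ndarray,
                     stability: StabilityResult,
                     fitness: float | None = None) -> ThreeWayClustering:
    """Nearest-center three-way assignment.

    Kernel samples go to the **core** of their nearest center; outer samples
    go to the **boundary** of theirs.  Distance ties resolve to the lowest
    cluster index.
    """
    centers = np.asarray(centers, dtype=float)
    X = feature_matrix(samples)
    assignment = nearest_centers(X, centers)
    clusters = [ThreeWayCluster(center=centers[m].copy()) for m in range(len(centers))]
    for s, m in zip(samples, assignment):
        if stability.is_kernel(s.sensor_id):
            clusters[m].core_ids.append(s.sensor_id)
        else:
            clusters[m].boundary_ids.append(s.sensor_id)
    if fitness is None:
        fitness = sse_fitness(X, centers, assignment)
    tw = ThreeWayClustering(clusters=clusters, fitness=fitness)
    tw.validate()
    return tw
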