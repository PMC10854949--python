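"""Particle-swarm-optimized three-way k-means.

Each particle encodes a full set of k cluster centers (a k x d block).  The
swarm minimizes the k-means SSE objective; the velocity update uses the
standard inertia + cognitive + social form

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),   x <- x + v*T, T = 1,

with r1, r2 drawn per scalar coordinate.  Particles are initialized on k
distinct kernel samples so the search starts from high-stability sensors.
After convergence the global-best centers drive the three-way core/boundary
assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .clustering import (
    ThreeWayClustering,
    assign_three_way,
    lloyd_step,
    nearest_centers,
    repair_empty_clusters,
    sse_fitness,
)
from .core_io import PipelineConfig, SensorSample, feature_matrix
from .stability import StabilityResult

__all__ = ["Particle", "init_swarm", "velocity_update", "pso_threeway",
           "optimize_centers_pso"]


@dataclass
class Particle:
    """One candidate solution: a k x d block of centers plus its velocity."""

    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray = field(default=None)  # type: ignore[assignment]
    best_value: float = float("inf")

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.best_position is None:
            self.best_position = self.position.copy()


#: Fraction of particles seeded from the full sample pool rather than the
#: kernel, so the swarm keeps coverage of regions the stability split exiled.
FULL_POOL_FRACTION = 1 / 3


def init_swarm(kernel_X: np.ndarray, k: int, m: int,
               rng: np.random.Generator,
               all_X: np.ndarray | None = None) -> list[Particle]:
    """Seed m particles on k distinct samples each, zero velocity.

    Most particles draw their k centers from the kernel (high-stability)
    samples; a third draw from the full pool.  The stability split can exile
    a whole spatial zone to the outer set — a kernel-only swarm then has no
    particle near that zone's centroid and the SSE optimum becomes
    unreachable, so a minority of full-pool particles preserves coverage.
    If the kernel holds fewer than k samples every particle falls back to
    the full pool (with a warning).
    """
    pool = kernel_X
    if len(pool) < k:
        if all_X is None or len(all_X) < k:
            raise ValueError(f"cannot draw {k} distinct initial centers")
        warnings.warn(
            f"kernel has {len(pool)} samples < k={k}; initializing particles "
            "from the full sample set", stacklevel=2)
        pool = all_X
    n_full = int(m * FULL_POOL_FRACTION) if all_X is not None and len(all_X) >= k else 0
    swarm = []
    for i in range(m):
        src = all_X if i < n_full else pool
        idx = rng.choice(len(src), size=k, replace=False)
        pos = src[idx].astype(float).copy()
        swarm.append(Particle(position=pos, velocity=np.zeros_like(pos)))
    return swarm


def velocity_update(p: Particle, gbest: np.ndarray, cfg: PipelineConfig,
                    rng: np.random.Generator) -> None:
    """In-place inertia/cognitive/social velocity and position update."""
    r1 = rng.random(p.position.shape)
    r2 = rng.random(p.position.shape)
    p.velocity = (cfg.pso_inertia * p.velocity
                  + cfg.pso_c1 * r1 * (p.best_position - p.position)
                  + cfg.pso_c2 * r2 * (gbest - p.position))
    p.position = p.position + p.velocity  # T = 1


def optimize_centers_pso(X: np.ndarray, kernel_X: np.ndarray, k: int,
                         cfg: PipelineConfig,
                         rng: np.random.Generator) -> tuple[np.ndarray, float, list[float]]:
    """Run the swarm and return (best centers, best SSE, per-iteration bests).

    Stops at ``cfg.pso_max_iter`` iterations or after ``cfg.pso_stagnation``
    iterations without global-best improvement.  Empty clusters in the final
    best centers are repaired by reseeding on the farthest sample.
    """
    swarm = init_swarm(kernel_X, k, cfg.pso_swarm_size, rng, all_X=X)
    # memetic hybrid: each particle's start is polished by local Lloyd descent,
    # so the swarm explores between k-means local optima rather than raw samples
    for p in swarm:
        p.position = _lloyd_polish(X, p.position)
        p.best_position = p.position.copy()
    gbest = None
    gbest_value = float("inf")
    history: list[float] = []
    stall = 0
    for _ in range(cfg.pso_max_iter):
        for p in swarm:
            value = sse_fitness(X, p.position)
            if value < p.best_value:
                p.best_value = value
                p.best_position = p.position.copy()
            if value < gbest_value - 1e-12:
                gbest_value = value
                gbest = p.position.copy()
                stall = -1  # reset below after increment
        stall += 1
        history.append(gbest_value)
        if stall >= cfg.pso_stagnation:
            break
        for p in swarm:
            velocity_update(p, gbest, cfg, rng)
    centers = repair_empty_clusters(X, gbest)
    value = sse_fitness(X, centers)
    if value > gbest_value:
        # repair should not worsen the reported SSE; keep the better of the two
        assignment = nearest_centers(X, gbest)
        if len(set(assignment.tolist())) == k:
            centers, value = gbest, gbest_value
    # final polish from the swarm's best centers; Lloyd never increases SSE
    centers = _lloyd_polish(X, centers)
    value = sse_fitness(X, centers)
    return centers, value, history


def _lloyd_polish(X: np.ndarray, centers: np.ndarray,
                  max_iter: int = 100) -> np.ndarray:
    """Lloyd descent to convergence, with empty-cluster repair each step."""
    centers = np.asarray(centers, dtype=float)
    for _ in range(max_iter):
        new = lloyd_step(X, repair_empty_clusters(X, centers))
        if np.allclose(new, centers):
            return new
        centers = new
    return centers


def pso_threeway(samples: list[SensorSample], stability: StabilityResult,
                 k: int, cfg: PipelineConfig,
                 rng: np.random.Generator | None = None) -> ThreeWayClustering:
    """PSO-based three-way k-means at a fixed cluster count k."""
    if not (2 <= k <= len(samples)):
        raise ValueError(f"k={k} out of range [2, {len(samples)}]")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    X = feature_matrix(samples)
    kernel_idx = [i for i, s in enumerate(samples) if stability.is_kernel(s.sensor_id)]
    kernel_X = X[kernel_idx]
    centers, value, _ = optimize_centers_pso(X, kernel_X, k, cfg, rng)
    return assign_three_way(samples, centers, stability, fitness=value)
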