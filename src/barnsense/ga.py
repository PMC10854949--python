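"""Genetic-algorithm three-way k-means.

The GA is used twice, with two encodings:

1. **Cluster-count selection** — chromosomes are 8-bit binary strings whose
   decoded integer, clamped into ``[k_min, k_max]``, is a candidate cluster
   count k.  Each k is scored by a short k-means fit on the kernel samples.
2. **Center refinement** — at the chosen k, chromosomes are k distinct
   kernel-sample indices; the encoded centers are scored by the SSE of the
   induced nearest-center partition.

Both passes share roulette-wheel selection and fitness-adaptive crossover
and mutation probabilities: individuals above the population-average fitness
cross over / mutate with probability shrinking linearly to 0 at the
population maximum, individuals below it always do.

Because SSE is monotonically non-increasing in k, a fitness of ``1/(1+SSE)``
alone would always drive the count search to ``k_max``; the count search
instead scores each k by the Calinski-Harabasz index of a short k-means
fit — the standard SSE-derived criterion that balances within-cluster
tightness against between-cluster separation and therefore peaks at the
planted structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import calinski_harabasz_score

from .clustering import (
    ThreeWayClustering,
    assign_three_way,
    lloyd_step,
    nearest_centers,
    repair_empty_clusters,
    sse_fitness,
)
from .core_io import ConfigError, PipelineConfig, SensorSample, feature_matrix
from .stability import StabilityResult

__all__ = [
    "Chromosome",
    "selection_prob",
    "adaptive_crossover_prob",
    "adaptive_mutation_prob",
    "ga_select_k",
    "ga_threeway",
]

K_BITS = 8  # chromosome width for the cluster-count search


@dataclass
class Chromosome:
    """An 8-bit binary string with its decoded value and fitness."""

    genes: np.ndarray  # 0/1 vector of length K_BITS
    fitness: float = 0.0

    @property
    def decoded(self) -> int:
        return int(np.polyval(self.genes, 2))  # big-endian binary

    @classmethod
    def from_int(cls, value: int) -> "Chromosome":
        bits = [(value >> i) & 1 for i in reversed(range(K_BITS))]
        return cls(genes=np.array(bits, dtype=int))


def decode_k(genes: np.ndarray, k_min: int, k_max: int) -> int:
    """Decode 8 bits to a cluster count in [k_min, k_max].

    The raw 0-255 value is scaled proportionally onto the allowed range
    (then clamped for safety).  Scaling rather than hard clamping keeps the
    whole 8-bit code space informative: with a hard clamp onto a range as
    narrow as [2, 8], ~97% of random chromosomes would decode to k_max and
    the count search would degenerate.
    """
    value = int(np.polyval(np.asarray(genes, dtype=int), 2))
    k = k_min + round(value / 255 * (k_max - k_min)) if k_max > k_min else k_min
    return int(np.clip(k, k_min, k_max))


def selection_prob(fitnesses: np.ndarray) -> np.ndarray:
    """Roulette-wheel probabilities proportional to fitness.

    All-zero fitness degenerates to the uniform distribution (with warning).
    """
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise ValueError("fitness values must be non-negative")
    total = f.sum()
    if total <= 0.0:
        warnings.warn("all fitness values are zero; selecting uniformly",
                      stacklevel=2)
        return np.full(len(f), 1.0 / len(f))
    return f / total


def adaptive_crossover_prob(f: float, fmax: float, favg: float) -> float:
    """Crossover probability shrinking with fitness rank.

    ``(fmax - f)/(fmax - favg)`` for individuals at or above the average
    (0 at the maximum), 1 below it.  A flat population (fmax == favg)
    crosses over with probability 1.
    """
    if fmax < favg:
        raise ValueError("fmax must be >= favg")
    if f < favg:
        return 1.0
    if fmax == favg:
        return 1.0
    return float(np.clip((fmax - f) / (fmax - favg), 0.0, 1.0))


def adaptive_mutation_prob(f: float, fmax: float, favg: float,
                           base_rate: float = 0.1) -> float:
    """Mutation probability: the same adaptive form scaled by a low base rate.

    Above-average individuals mutate rarely (rate -> 0 at the maximum);
    below-average ones mutate at the full base rate.
    """
    if fmax < favg:
        raise ValueError("fmax must be >= favg")
    if f < favg:
        return base_rate
    if fmax == favg:
        return base_rate
    return float(base_rate * np.clip((fmax - f) / (fmax - favg), 0.0, 1.0))


def _short_kmeans_labels(X: np.ndarray, k: int, rng: np.random.Generator,
                         n_starts: int = 3, n_iter: int = 20) -> np.ndarray:
    """Labels of the best of a few short Lloyd fits (distinct-sample inits)."""
    k = min(k, len(X))
    best_sse, best_centers = np.inf, None
    for _ in range(n_starts):
        idx = rng.choice(len(X), size=k, replace=False)
        centers = X[idx].astype(float).copy()
        for _ in range(n_iter):
            new = lloyd_step(X, repair_empty_clusters(X, centers))
            if np.allclose(new, centers):
                break
            centers = new
        sse = sse_fitness(X, centers)
        if sse < best_sse:
            best_sse, best_centers = sse, centers
    return nearest_centers(X, best_centers)


def _count_fitness(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz score of a labeling (0 when degenerate)."""
    if len(set(labels.tolist())) < 2:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        score = calinski_harabasz_score(X, labels)
    if not np.isfinite(score):
        return 0.0
    return float(max(score, 0.0))


def _evolve(population: list, fitness_of, crossover, mutate,
            generations: int, rng: np.random.Generator,
            base_mutation: float) -> list:
    """Generic GA loop with elitism of one and adaptive operator rates."""
    fitnesses = np.array([fitness_of(ind) for ind in population])
    for _ in range(generations):
        probs = selection_prob(fitnesses)
        elite_idx = int(fitnesses.argmax())
        elite = population[elite_idx]
        n = len(population)
        children = [elite]
        while len(children) < n:
            i, j = rng.choice(n, size=2, p=probs)
            a, b = population[i], population[j]
            fmax = fitnesses.max()
            favg = min(fitnesses.mean(), fmax)  # guard float round-off on flat populations
            f_pair = max(fitnesses[i], fitnesses[j])
            if rng.random() < adaptive_crossover_prob(f_pair, fmax, favg):
                a, b = crossover(a, b, rng)
            for child, f_child in ((a, fitnesses[i]), (b, fitnesses[j])):
                pm = adaptive_mutation_prob(f_child, fmax, favg, base_mutation)
                child = mutate(child, pm, rng)
                if len(children) < n:
                    children.append(child)
        population = children
        fitnesses = np.array([fitness_of(ind) for ind in population])
    return population


def ga_select_k(samples: list[SensorSample], stability: StabilityResult,
                cfg: PipelineConfig,
                rng: np.random.Generator | None = None) -> int:
    """Evolve 8-bit chromosomes to pick the cluster count k.

    Each candidate k is scored by the Calinski-Harabasz index of a short
    multi-start k-means fit on the kernel samples — the standard
    SSE-derived criterion that trades within-cluster tightness against
    between-cluster separation, so it peaks at the planted structure instead
    of growing monotonically with k (see module docstring).  Each k is
    scored once per run and cached, so the search cost does not grow with
    population size.  Ties resolve to the smallest k.
    """
    if cfg.ga_population < 4:
        raise ConfigError("GA population must be >= 4")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    X = feature_matrix(samples)
    kernel_idx = [i for i, s in enumerate(samples) if stability.is_kernel(s.sensor_id)]
    kernel_X = X[kernel_idx] if kernel_idx else X
    k_max = min(cfg.k_max, len(kernel_X))
    k_min = min(cfg.k_min, k_max)

    score_cache: dict[int, float] = {}

    def score_of(k: int) -> float:
        if k not in score_cache:
            labels = _short_kmeans_labels(kernel_X, k, rng)
            score_cache[k] = _count_fitness(kernel_X, labels)
        return score_cache[k]

    def fitness_of(genes: np.ndarray) -> float:
        return score_of(decode_k(genes, k_min, k_max))

    def crossover(a, b, rng):
        point = int(rng.integers(1, K_BITS))
        return (np.concatenate([a[:point], b[point:]]),
                np.concatenate([b[:point], a[point:]]))

    def mutate(genes, pm, rng):
        flips = rng.random(K_BITS) < pm
        out = genes.copy()
        out[flips] ^= 1
        return out

    population = [rng.integers(0, 2, size=K_BITS) for _ in range(cfg.ga_population)]
    population = _evolve(population, fitness_of, crossover, mutate,
                         cfg.ga_generations, rng, cfg.ga_base_mutation)
    # best k among the final population; k_min is always kept as a parsimony
    # baseline candidate, and ties in fitness resolve to the smallest k
    candidates = sorted({decode_k(genes, k_min, k_max) for genes in population}
                        | {k_min})
    fitness_by_k = {k: score_of(k) for k in candidates}
    best_f = max(fitness_by_k.values())
    return min(k for k, f in fitness_by_k.items() if f >= best_f * (1 - 1e-12))


def optimize_centers_ga(X: np.ndarray, kernel_idx: list[int], k: int,
                        cfg: PipelineConfig,
                        rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """GA over k-subsets of samples minimizing the induced SSE.

    Chromosomes are k distinct indices into the full sample array.  The
    initial population draws from the kernel indices (full set when the
    kernel is smaller than k), but mutation replaces indices from the whole
    pool so the search can reach regions the stability split exiled from
    the kernel.
    """
    pool = X
    if len(pool) < k:
        raise ValueError(f"cannot draw {k} distinct centers from {len(pool)} samples")
    init_idx = np.asarray(kernel_idx if len(kernel_idx) >= k else range(len(pool)),
                          dtype=int)

    def fitness_of(idx: np.ndarray) -> float:
        return 1.0 / (1.0 + sse_fitness(X, pool[idx]))

    def crossover(a, b, rng):
        # uniform exchange with duplicate repair: children stay k distinct indices
        def child_of(primary, other):
            take = rng.random(k) < 0.5
            genes = np.where(take, primary, other)
            seen, out = set(), []
            for g in genes:
                if g not in seen:
                    seen.add(int(g))
                    out.append(int(g))
            for g in np.concatenate([primary, other]):
                if len(out) == k:
                    break
                if int(g) not in seen:
                    seen.add(int(g))
                    out.append(int(g))
            return np.array(out, dtype=int)

        return child_of(a, b), child_of(b, a)

    def mutate(idx, pm, rng):
        out = idx.copy()
        for pos in range(k):
            if rng.random() < pm:
                choices = np.setdiff1d(np.arange(len(pool)), out)
                if len(choices):
                    out[pos] = int(rng.choice(choices))
        return out

    population = [init_idx[rng.choice(len(init_idx), size=k, replace=False)]
                  for _ in range(cfg.ga_population)]
    population = _evolve(population, fitness_of, crossover, mutate,
                         cfg.ga_generations, rng, cfg.ga_base_mutation)
    best = max(population, key=fitness_of)
    centers = pool[best].astype(float).copy()
    return centers, sse_fitness(X, centers)


def ga_threeway(samples: list[SensorSample], stability: StabilityResult,
                cfg: PipelineConfig, k: int | None = None,
                rng: np.random.Generator | None = None) -> ThreeWayClustering:
    """GA-based three-way k-means.

    With ``k=None`` the cluster count is first chosen by :func:`ga_select_k`;
    a fixed ``k`` skips that step (used when scanning k externally).  The
    center GA is followed by one Lloyd refinement pass before the three-way
    assignment.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if k is None:
        k = ga_select_k(samples, stability, cfg, rng=rng)
    if not (2 <= k <= len(samples)):
        raise ValueError(f"k={k} out of range [2, {len(samples)}]")
    X = feature_matrix(samples)
    kernel_idx = [i for i, s in enumerate(samples) if stability.is_kernel(s.sensor_id)]
    centers, _ = optimize_centers_ga(X, kernel_idx, k, cfg, rng)
    refined = lloyd_step(X, centers)
    refined = repair_empty_clusters(X, refined)
    if sse_fitness(X, refined) <= sse_fitness(X, centers):
        centers = refined
    return assign_three_way(samples, centers, stability)
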