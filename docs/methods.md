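# Methods

This note documents the models, default parameters, numerical conventions
and open design choices behind `barnsense`, in pipeline order.

## Data model and preprocessing

The universal container is a complete timestamp × sensor grid of air
temperature (°C) and relative humidity (%RH) at a constant step (30 min by
default). Readings outside the probes' physical range (−40…80 °C,
0…100 %RH) are treated as faults and replaced by linear interpolation in
time; a sensor with more than 50% faulty readings in either variable is
rejected rather than repaired. Preprocessing is idempotent on clean data.

Clustering operates on one feature vector per sensor: its temperature
series and humidity series over the analysis window, each min–max
normalized over the whole window × sensor block and then concatenated.
Normalizing per block (not per sensor) preserves the inter-sensor offsets
that carry the spatial signal. Whether temperature and humidity should be
clustered jointly or separately is genuinely open; the package clusters
jointly (one placement serves both variables, which are then *evaluated*
separately), and users who want per-variable placements can run the
pipeline on a single-variable matrix. A zero-range variable maps to 0 by
convention. Equal-width binning with B = 10 levels (configurable)
discretizes the features for the attribute-match similarity and for all
entropy estimates.

## Sample stability

The ensemble defaults to L = 20 plain k-means runs with k cycling
round-robin over the configured [k_min, k_max] = [2, 8] and seeds
`base + run`. The co-occurrence matrix, tent-map stability score and the
two maximum-between-class-variance thresholds (one on the co-occurrence
entries, one on the stability scores) follow the standard consensus-
clustering construction. Numerical conventions:

- Threshold search scans a fixed uniform grid of 256 points in (0, 1);
  ties break toward the smaller threshold for determinism.
- If every score is identical the between-class variance is flat; the
  threshold degenerates to 0.5 (with a warning) and all sensors are kept
  in the kernel, so monitoring can proceed.
- Low-k ensemble members are what exposes erratic sensors (an outlier that
  is always alone is perfectly *stable* at high k, but gets absorbed into
  different clusters run-to-run at low k). The same members make sensors
  in mid-gradient zones look unstable — their merges at k below the true
  zone count flip from run to run — so the kernel is not guaranteed to
  span the spatial structure. The optimizers are designed around this
  (below).

## Three-way clustering and the two optimizers

Both optimizers minimize the k-means SSE with Euclidean distance; the
final centers drive the three-way assignment (kernel sensors → core of the
nearest center, outer sensors → boundary; distance ties → lowest cluster
index). Empty clusters are permitted mid-search (they contribute zero SSE)
and are repaired before output by reseeding on the sample farthest from
its center; with duplicate samples a cluster can stay legitimately empty.

**PSO** (swarm 30, inertia ω = 0.7, c1 = c2 = 2, T = 1, at most 200
iterations or 20 without global-best improvement) encodes a full k × d
center block per particle, with the cognitive/social random factors drawn
per scalar coordinate. It is implemented as a memetic hybrid: every
particle's initial position and the final global best are polished by
Lloyd descent, so the swarm explores *between* k-means local optima. Plain
PSO in the k × d center space (d is twice the window length, thousands of
coordinates) reliably stalls far from the optimum; the hybrid form is the
standard remedy in the PSO-clustering literature. Particles are seeded on
k distinct kernel sensors, except that one third of the swarm seeds from
the full sensor pool — without this, a kernel that misses a whole zone
(see above) makes the optimum unreachable.

**GA** (population 30, generations 100, elitism 1) is used twice. The
cluster-count search evolves 8-bit chromosomes whose 0–255 value is scaled
proportionally onto [k_min, k_max]; scaling rather than hard clamping
keeps the whole code space informative (a clamp onto a range as narrow as
[2, 8] would map ~97% of random chromosomes to k_max). Because SSE is
monotone non-increasing in k, the count fitness is not a function of SSE
alone but the Calinski–Harabasz index of a short multi-start k-means fit
on the kernel set, cached per k; ties resolve to the smallest k, and k_min
is always retained as a parsimony baseline candidate. The center
refinement at fixed k evolves k distinct sample indices under the
`1/(1+SSE)` fitness (reciprocal form so that roulette selection favors
lower SSE), initial population drawn from kernel indices, mutation
replacing indices from the full pool; one Lloyd pass refines the winning
centers. Crossover and mutation probabilities are fitness-adaptive:
individuals at or above the population-average fitness use
`(f_max − f)/(f_max − f_avg)` (mutation additionally scaled by a base rate
of 0.1), individuals below it always cross over and mutate at the base
rate; a flat population degenerates to probability 1 (crossover) and the
base rate (mutation).

## Re-clustering

Within-cluster similarity weights default to i1 = 0.5, i2 = 0.3, i3 = 0.2
(only the ordering and the sum-to-1 constraint are structural; the split
is configurable). Singleton clusters score IntraS = 1 — they cannot be
split further. A cluster with IntraS = 0 has unbounded re-clustering
potential and splits into `min(size, k_max)` subclusters with a warning.
Proposed splits (into `⌈ratio⌉` subclusters, via a PSO pass over the
cluster's members) are applied worst-cohesion-first, and each is committed
only if it does not decrease the running mean within-cluster similarity:
splitting hands a weak cluster's fragments more weight in the
equally-weighted mean, so even a locally improving split can drag the mean
down, and the guard makes the pass cohesion-monotone by construction.
Re-clustering is a single pass (no recursion). Combining two clusterings
(`combine_results`) takes the co-membership intersection — deterministic,
order-independent, and a common refinement of both inputs; in the seasonal
pipeline the two optimizers are instead compared and the winner kept
(lower mean of the per-variable trend RMSEs), and both modes are exposed.

## Placement scoring

Each cluster contributes its centroid-nearest and second-nearest sensors
(one for singletons); taking one per cluster enumerates the candidate
pool. Entropies are empirical plug-in estimates in bits on the B-level bin
sequences, per variable; the conditional entropy is the standard
`H(Y|X) = H(X,Y) − H(X)`, so the chain rule holds to rounding. The total
entropy of a selection sums the selected sensors' entropies plus the joint
entropy of every (unselected, selected) pair — the information the rest of
the array delivers through the chosen sensors. Within one k, the best
combination maximizes the sum of the two per-variable min–max-normalized
totals; across k the winner maximizes the equal-weight sum of the
min–max-normalized total entropy and TWCVI (a lexicographic mode — entropy
first, TWCVI as tie-break — is available by config), ties to the smallest
k. The chosen combination is validated by RMSE and MAPE of its mean trend
against the all-sensor reference trend on the full, unnormalized window.

## Fuzzy fusion

Category cuts are fixed by the comfort bands for fattening pigs:
temperature Low/Moderate/High with cuts 17.5 and 22.5 °C, humidity
Dry/Suitable/Humid with cuts 65.5 and 69.5 %RH. The middle category's
Gaussian is centered on the band midpoint with σ = h/√(2 ln 2) (h the
half-width), so membership is exactly 0.5 at each cut; the outer
categories are one-sided, saturating at 1 beyond `cut ∓ h`, so extreme
readings are not penalized. Fusion is by voting: each sensor votes for its
argmax category (ties within a sensor resolve toward the middle of the
scale, matching the crisp rule that boundary values belong to the middle
band), the fused label is the majority, label ties break by the larger
summed membership mass. The agreement rate compares the fused label
against the crisp category of the all-sensor mean per timestamp; an
optional margin excludes timestamps where that mean sits within a stated
distance of a cut, where the crisp reference itself is ill-conditioned.

## Synthetic scenes

The generator emulates the monitored house: 30 sensors in two 3 × 5
layers, 30-minute readings, one year starting 1 September. Temperature is
`annual sinusoid (amplitude 8 °C, peak mid-July) + diurnal sinusoid
(amplitude 3 °C, peak 15:00) + zone offset + column gradient
(0.1 °C/column, wet-curtain wall → fan wall) + layer offset (0.2 °C) +
N(0, 0.25²)` noise; zone offsets are evenly spaced over a 2.8 °C spread
(five column zones by default), matching the reported average inter-sensor
temperature difference regime of the real house. Humidity is a 72 %RH base
minus 1.5 %RH per °C of deterministic temperature anomaly plus N(0, 1²)
noise, clipped to [0, 100] — anticorrelated with temperature as observed,
without a physical moisture model. `plant_unstable` makes a chosen
fraction of sensors erratic: their static zone offset is replaced by a
slow sinusoid sweeping the full zone range (random phase, 2–5-day period)
and their noise is quadrupled, so they drift between zones.

What the generator does *not* emulate — airflow and ventilation-state
transients, solar-radiation bursts, animal-activity spikes, sensor drift
and dropouts — bounds what passing tests show: they demonstrate that the
pipeline recovers planted spatial structure and rejects planted
instability under realistic amplitude/noise ratios, not that it would pick
the same sensor positions in a physical barn.

## Problem sizes and tolerances

Simulation-backed tests and the acceptance script use 14-day windows for
clustering studies, a stride of 4 (2-hour effective step) for the
full-year seasonal features, 20-seed repetitions for recovery/capture
rates, and 100 seeded instances (n ≤ 12, k = 2) for the exhaustive
optimality comparison, keeping every study well inside a desktop run while
leaving the amplitude/noise ratios of the full problem unchanged. Entropy
identities are asserted to 1e−9; equality-sensitive tie rules
(nearest-center, threshold grid, best-k) are exact by construction.

## Known limitations

- The stability split inherits the consensus-ensemble's blind spot:
  persistent lone outliers are "stable" and can reach the kernel.
- The total-entropy objective grows with the number of selected sensors,
  so the across-k choice leans on the TWCVI term to resist always picking
  k_max; a cost-aware variant (entropy per sensor) is not implemented.
- Re-clustering does not recurse; a split that is still heterogeneous
  after one pass stays as is.
- The fuzzy categories are fixed bands, not learned from the data.
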