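# Methods

## Model and procedure

The package implements stability-based estimation of the number of clusters
by consensus. One run is specified by a clustering engine A, the number of
resampling steps H, the subsampling fraction p, a candidate range
[k_min, k_max], and a plateau threshold τ.

For each candidate k, every resampling step draws ⌊p·n⌋ of the n items
uniformly without replacement, clusters the induced sub-matrix into k
groups with A, and accumulates two integer matrices: co-draw counts
(how often a pair was sampled together) and co-cluster counts (how often it
additionally shared a cluster). Their element-wise ratio is the consensus
matrix M(k) ∈ [0,1]^{n×n}. The classical procedure ("consensus") runs the
k-loop outermost with fresh resamples per k; the fast variant ("fc")
switches the loops so one resample serves every k, and — for hierarchical
engines — one dendrogram per resample is cut at every k. Both procedures
estimate the same quantity; the package's central engineering guarantee,
enforced by test, is that the dendrogram-reuse path is bit-identical to a
naive reference that re-clusters each resample from scratch for every k.

Prediction: with x₁ ≤ … ≤ x_m the sorted m = n(n−1)/2 upper-triangle
consensus entries, the empirical CDF is summarized by the discrete area
A(k) = Σ_{i≥2} (x_i − x_{i−1})·CDF(x_i), and Δ(2) = A(2),
Δ(k) = (A(k+1) − A(k))/A(k) for k > 2. The forward-difference form means Δ
is defined on {2} ∪ [3, k_max−1] and has no value at k_max; the increment
A(3) − A(2) is never used. Both facts follow the definitions exactly, and
the k_max point that visualizations sometimes show is deliberately not
produced. k* is the smallest k ≥ 3 such that Δ(j) ≤ τ for every j from k
to k_max−1. When no such k exists the run reports k_max−1 with
`stabilized=False`; k* = 2 is reachable only through that fallback or
through visual inspection of the emitted curves, since the rule scans
k ≥ 3. The historical practice is visual inspection of the Δ and CDF
curves; the fixed plateau rule exists to make predictions deterministic
and testable, τ is exposed in configuration, and all curves are emitted so
a human can always override the automatic call. `flat_range` reports the
maximal contiguous interval with Δ ≤ τ, surfacing interval-valued
ambiguity (a "5–6"-style call) instead of hiding it.

## Parameters

- H (`n_resamples`), default 250: resampling steps. Consensus-entry
  standard error scales like 1/√(p²H); 100 is sufficient for the benchmark
  analogs below, 250 is the robust general-purpose setting.
- p (`subsample_fraction`), default 0.80: fraction of rows per resample.
  Must leave ⌊p·n⌋ ≥ k_max items; sample size uses floor, the conservative
  rounding.
- k range, default [2, 30] (k_max additionally capped by ⌊p·n⌋).
- τ (`tau`), default 0.03: plateau threshold on the relative area increase.
- Engines: `hier-a`/`hier-c`/`hier-s` (average/complete/single linkage,
  Euclidean distance) and `kmeans-r`/`kmeans-a`/`kmeans-c`/`kmeans-s`
  (Lloyd from a uniform random partition, redrawn until all k labels occur,
  or from the k-cut of the named dendrogram; one initialization per call,
  at most 300 sweeps, convergence when assignments stop changing, emptied
  clusters repopulated with the points farthest from their centroids).

## Randomness and determinism

A master seed feeds keyed child streams (`default_rng([seed, tag, k, h])`):
resample draws are keyed per (k, h) in the k-outer procedure and per h in
FC (which shares the draw across k); K-means partition draws are keyed per
(k, h) identically in the FC fast and naive paths, so equivalence tests
compare literally the same sampled problems. Hierarchical merges are
deterministic for a given input (scipy's nearest-neighbor-chain / MST
linkage); minimal-distance ties are resolved by that implementation's
fixed order, which is immaterial for continuous expression data where
exact ties have probability zero. Two runs with the same configuration and
seed produce byte-identical output files (floats printed with 12
significant digits, exact on re-parse at printed precision).

Degenerate inputs: pairs never drawn together (probability ≈ (1−p²)^H,
negligible at defaults) get consensus 0 — absence of evidence of
co-clustering — with a logged warning; the diagonal is fixed at 1 and
excluded from all curve statistics; a constant consensus matrix makes some
A(k) = 0 and the Δ series is then refused as degenerate rather than
silently divided through. Δ can be negative (only its non-negativity is
ever *observed*, not guaranteed); negative values are recorded in the
prediction notes, never rejected.

## Synthetic benchmark generators

`gaussian_clusters` draws spherical unit-variance Gaussian classes whose
means are pairwise *c-separated* in the standard Gaussian-mixture sense:
`separation` is measured in units of the within-class RMS radius √d, i.e.
inter-mean Euclidean distance ≥ separation·√d. A dimension-aware unit is
essential: a fixed absolute gap that separates clusters cleanly in 2
dimensions is swamped in 200 dimensions, where pairwise point distances
concentrate at √(2d) ± O(1) and a constant inter-mean offset becomes
invisible to any Euclidean-distance method. Means are placed on a scaled
standard-basis simplex when the class count allows (all pairs exactly at
the target distance — which also makes the *wrong* coarser clusterings
maximally ambiguous, a deliberately hard regime for k < k*), on a regular
polygon in the first two coordinates otherwise, or equally spaced in one
dimension. `marker_block_dataset` models up-regulation patterns: standard
Gaussian background noise, with each class over-expressing its own
disjoint block of features by `effect` noise-SDs. `null_dataset` is pure
noise with gold k = 1.

Presets with known gold k: `gaussian3` — sizes (20, 20, 20), 200
dimensions, separation 6; `gaussian5` — sizes (80, 120, 100, 120, 80), 2
dimensions, separation 6; `simulated6` — sizes (8, 12, 10, 15, 5, 10), 600
features, 50 markers per class, effect 2. These are analogs of the classic
three-, five- and six-class artificial benchmarks: they preserve the gold
cluster counts and the qualitative regimes (high-dimensional well-separated
Gaussians; low-dimensional multi-cluster structure with unequal class
sizes; marker-block expression patterns), not any particular dataset's
exact values. What they deliberately do not model: heavy-tailed microarray
noise, dye bias, missing values, correlated genes, or classes of wildly
unequal spread — so passing recovery tests here demonstrates correctness of
the procedure and its statistics, not performance on real microarrays.

## Numerical behavior worth knowing

The area statistic is discontinuous at perfectly stable clusterings: if
every resample clusters identically at some k, the consensus entries are
exactly {0, 1} and A(k) = 1, while a single discordant resample introduces
entries near 0 and 1 and drops A(k) to roughly the fraction of
never-co-clustered pairs. On cleanly separable data this makes A(k*) = 1
and often A(k) < A(k*) for k > k* — so Δ can be negative beyond k*, and
quantities that compare independent runs near k* can differ noticeably
whenever one run happens to be perfectly stable and the other not. The
plateau rule is insensitive to this (negative Δ values satisfy Δ ≤ τ), but
run-to-run curve comparisons on nearly-ideal data should be read with it
in mind. Relatedly, on small datasets (n ≲ 60) the post-plateau Δ tail
sits near 0.02–0.03, close to the default τ; the k-outer procedure's
independent per-k noise can then push single points above τ and delay its
k*, while FC's shared resamples correlate the tail and make its calls more
stable at equal H.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run FC with Hier-A at H = 100,
p = 0.8, k ∈ [2, 10] on ten seeded instances per preset (n = 60, 500, 60),
plus a k-outer/h-outer comparison at the same scale; fast-path/naive-path
bit-equality is checked at n ≤ 30, H ≤ 20 for all three linkages. These
sizes were chosen as the smallest at which the benchmark regimes are
clearly expressed; all statistics scale to larger n and H unchanged.
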