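# fastconsensus

Stability-based estimation of the number of clusters in expression
matrices: consensus clustering and its fast loop-switched variant (FC).

## The problem

Given an n × d expression matrix (rows = items to cluster, e.g. genes or
samples; columns = experimental conditions), how many clusters k* does it
actually contain? Consensus clustering answers by perturbation: if the data
really fall into k groups, then clustering many random subsamples at k
should keep assigning the same item pairs together.

For each candidate k, the procedure draws H subsamples of ⌊p·n⌋ rows,
clusters each, and records for every item pair

```
M(k)(i, j) = Σ_h M⁽ʰ⁾(i, j) / Σ_h I⁽ʰ⁾(i, j)
```

where M⁽ʰ⁾(i, j) = 1 when i and j share a cluster in resample h and
I⁽ʰ⁾(i, j) = 1 when both were drawn into it — the *consensus matrix*, the
fraction of co-draws in which a pair co-clustered. With m = n(n−1)/2 and
x₁ ≤ … ≤ x_m the sorted upper-triangle entries, the empirical CDF
`CDF(c) = #{(i,j): M(i,j) ≤ c}/m` is summarized by the area

```
A(k) = Σ_{i=2..m} (x_i − x_{i−1}) · CDF(x_i)
Δ(k) = A(2)                         for k = 2
       (A(k+1) − A(k)) / A(k)       for k > 2
```

A(k) grows markedly while k is below the true cluster number and flattens
beyond it; the k where the Δ curve stabilizes (here: the smallest k ≥ 3
with Δ(j) ≤ τ for all later j, default τ = 0.03) is the prediction k*.

**FC** is the loop-switched variant: instead of drawing fresh resamples for
every k (k-outer loop), it draws each resample once and harvests clustering
solutions for *all* k from it (h-outer loop). For agglomerative hierarchical
engines a single dendrogram per resample yields every k-cut, so H trees are
built instead of (k_max − k_min + 1)·H — an order-of-magnitude speed-up with
statistically equivalent output. The package verifies bit-exactness of the
dendrogram-reuse path against a naive re-clustering reference.

Engines: agglomerative hierarchical clustering under average, complete or
single linkage (Euclidean distance), and Lloyd K-means initialized from a
random partition or from a hierarchical cut.

## Worked example

```python
import numpy as np
from fastconsensus import ConsensusClustering
from fastconsensus.datasets import make_preset

ds = make_preset("gaussian3", np.random.default_rng([0, 99]))  # 60 items, 3 classes
est = ConsensusClustering(method="fc", algorithm="hier-a", n_resamples=100,
                          subsample_fraction=0.8, k_min=2, k_max=10,
                          tau=0.03, random_state=0)
est.fit(ds.X)
print(est.k_star_, est.stabilized_, est.flat_range_)
print({k: round(v, 3) for k, v in est.areas_.items()})
print({k: round(v, 3) for k, v in est.deltas_.items()})
```

prints

```
3 True (3, 9)
{2: 0.457, 3: 1.0, 4: 0.696, 5: 0.709, 6: 0.722, 7: 0.734, 8: 0.749, 9: 0.764, 10: 0.782}
{2: 0.457, 3: -0.304, 4: 0.019, 5: 0.017, 6: 0.017, 7: 0.02, 8: 0.021, 9: 0.024}
```

Reading: at k = 3 the clustering is perfectly stable across all 100
subsamples (every consensus entry is 0 or 1, hence A(3) = 1); splitting
further only shuffles arbitrary subdivisions, so Δ stays below τ = 0.03
from k = 3 on and `k_star_ = 3` — the planted class count. `labels_` then
holds the 3-group clustering of the full data (here it matches the planted
classes exactly). The per-k CDF curves (`cdf_curves_`) remain available for
the visual inspection that practitioners use to double-check Δ-based calls.

The same run from a shell, writing per-k consensus matrices, curve tables,
`prediction.json` and optional PNG plots:

```bash
fastconsensus --input matrix.tsv --method fc --algorithm hier-a \
    --H 100 --p 0.8 --kmin 2 --kmax 10 --seed 0 --outdir out/ --plots
fastconsensus --simulate gaussian3 --seed 0 --outdir sim/   # built-in benchmarks
```

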