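# apconsensus

Consensus clustering of time-series gene expression by interpolation,
sliding-window features and affinity propagation.

## The problem

Time-course microarray or RNA expression experiments measure each gene at a
handful of time points (often 7–20). Grouping genes with similar temporal
behavior is the first step toward reading regulatory programs out of such
data, but the classic tools (k-means, hierarchical clustering, SOMs) ignore
the temporal ordering, are sensitive to measurement noise, and need the
number of clusters K up front. This package implements a clustering
pipeline designed for exactly this setting: it treats expression as a
continuous function of time, examines every sub-interval of the time
course, and lets the number of clusters emerge from the data.

## The method

Given n genes measured at τ time points, the pipeline runs in five stages:

1. **Spline resampling.** Each gene's profile is interpolated with a cubic
   spline (not-a-knot) and one point is inserted at the temporal midpoint
   of every sampling interval, giving a working grid of p = 2τ − 1 points.
2. **Windowed affinity propagation.** For every window size w in
   [⌊p/2⌋, ⌊3p/4⌋] and every contiguous window of that size (p − w + 1 of
   them), the genes' pairwise Pearson correlations over the window feed an
   affinity-propagation clustering (exemplar-based message passing;
   preference = median pairwise similarity, so K is never supplied).
3. **Consensus.** Each clustering is a binary co-cluster vote. Votes are
   averaged per window size and then across sizes into the *gene-relativity
   matrix* R, where R[i,j] is the empirical probability that genes i and j
   belong together.
4. **Graph partitioning.** R is thresholded at σ (edge iff R[i,j] ≥ σ) for
   σ = 0.50, 0.51, …, 0.80; the connected components at each σ are the
   initial clusters, and the σ* maximizing the Silhouette index of the
   initial partitions is selected (ties to the smallest σ).
5. **Refinement.** Clusters smaller than φ ("sub-clusters") are merged
   back: singletons follow their strongest relativity edge (kept separate
   below relativity 0.5), larger sub-clusters merge into the major cluster
   whose mean profile they correlate with best (kept if even the best
   correlation is negative).

An *extended* mode replaces contiguous windows with random w-point subsets
of the grid, useful for very short series (τ < 10) where sliding windows
alone yield too few votes. A full validity-index suite is included:
adjusted Rand index, pair-counting sensitivity/specificity/Jaccard/
Minkowski, Silhouette, Dunn and Davies–Bouldin.

## Worked example

Simulate a cell-cycle-like dataset — 5 groups of 20 genes whose
phase-shifted sinusoidal prototypes span two cycles over 17 time points,
with Gaussian noise (SD 0.3) — then cluster it and score the result
against the planted labels:

```bash
apconsensus simulate --out-prefix demo --clusters 5 --size 20 \
    --tau 17 --noise-sd 0.3 --seed 1
apconsensus cluster demo.expression.tsv --labels demo.labels.tsv \
    --header-is-time --out-dir demo_out --seed 1
```

which prints

```
selected sigma* = 0.50
clusters K = 5 (votes aggregated: 126)
ari = 1.00000
rand = 1.00000
sensitivity = 1.00000
specificity = 1.00000
jaccard = 1.00000
minkowski = 0.00000
silhouette = 0.56195
dunn = 1.01537
dbi = 0.63822
```

The 17 observed points become 33 working points, the window range defaults
to (16, 24), and those 9 window sizes contribute 126 affinity-propagation
votes. All five planted groups are recovered exactly (ARI = 1); the
internal indices describe the geometry of the recovered clusters on the
interpolated grid. `demo_out/` holds the partition (`partition.tsv`), the
per-threshold metrics table (`metrics.tsv`, one row per σ with K and
Silhouette), and optionally the relativity matrix (`--save-relativity`).

The same pipeline is available as a scikit-learn-style estimator:

```python
from apconsensus import TimeCourseConsensusClustering, generate, SyntheticSpec

X, labels = generate(SyntheticSpec(noise_sd=0.3, seed=1))
model = TimeCourseConsensusClustering(random_state=1).fit(X)
model.n_clusters_      # 5
model.sigma_           # 0.50
model.relativity_      # the gene-relativity matrix R
```

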