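# Methods

## Model and assumptions

The pipeline treats a gene's expression time course as a noisy sample of a
continuous function of time, and co-expression as stability of pairwise
correlation across sub-intervals of the course. Clustering evidence is
accumulated rather than computed once: every feature window yields one
affinity-propagation partition ("vote"), and the fraction of votes placing
two genes together — the relativity R[i,j] — is read as the probability
that they share a cluster. This consensus step is what buys robustness:
a single noisy window cannot flip a pair's assignment, only shift its
probability slightly.

Assumptions worth keeping in mind:

* Pearson correlation is the similarity; co-expression is assumed
  shape-based and affine-invariant per window. Magnitude differences are
  invisible (and per-gene standardization removes them entirely).
* The relativity graph's connected components define clusters, so two
  genes can share a cluster through a chain of intermediates without being
  similar themselves. The threshold sweep plus Silhouette selection exists
  to control exactly this chaining.
* Time stamps are trusted: splines interpolate in *time* units, so
  irregular designs (0, 0.5, 2, 5, 7, 9, 11 h) place midpoints where the
  experiment was sparse, not at index midpoints.

## Pipeline stages and tunables

| parameter | default | meaning |
|---|---|---|
| `interpolate` | on | resample p observed points to 2p − 1 via cubic spline |
| `window_range` | (⌊p/2⌋, ⌊3p/4⌋) | inclusive window sizes on the working grid |
| `extended` / `max_subsets` | off / 200 | random w-subsets instead of sliding windows |
| `damping` | 0.9 | AP message damping, in [0.5, 1) |
| `max_iterations` | 1000 | AP iteration cap; non-convergence is tolerated |
| `convergence_window` | 100 | iterations the exemplar set must hold to stop |
| `sigma_grid` | 0.50…0.80 step 0.01 | relativity thresholds (31 values) |
| `phi` | max(2, ⌈0.01 n⌉) | minor-cluster size threshold for refinement |
| `refine_max_iterations` | 500 | refinement safety cap |
| `dissimilarity` | euclidean | distance for SI/DI/DBI; `correlation` = 1 − r |

**Spline boundary condition.** Not-a-knot, the standard interpolating
default; nothing in the problem supplies end derivatives, and not-a-knot
avoids inventing them. Interpolation passes through observations exactly
(checked to < 1e−9 at the knots), so it adds points without altering data.

**Window counts.** On a p-point grid there are p − w + 1 contiguous
windows of size w. Over the default range this gives 126 votes for p = 33,
51 for p = 20, and 14 for p = 13 — the per-size counts and totals the
method is characterized by. The recommended range trades feature length
(too-short windows make AP unstable, inflating vote noise) against vote
count (too-long windows leave too few).

**Affinity propagation.** Implemented as the standard vectorized
responsibility/availability updates with damping. The preference is the
median of the off-diagonal similarities (each unordered pair once), which
yields a moderate number of exemplars without specifying K. A seeded
jitter of relative magnitude 1e−12 breaks exact similarity ties that can
otherwise sustain oscillation; all per-window seeds derive deterministically
from the single pipeline seed, so results are independent of execution
order. Non-convergence at the iteration cap returns the current exemplar
estimate with a warning rather than failing: one unstable window
contributes one imperfect vote out of many.

**Consensus weighting.** Votes are averaged within a window size first,
then across sizes with equal weight per size — so sizes contributing more
windows are *not* upweighted. A vote-weighted variant would be a one-line
change in `VoteAccumulator.relativity`, but the two-stage equal-weight
average is the method's definition and the default is deliberately not
configurable from the estimator. Accumulation is by running sums: memory
stays O(n²) regardless of vote count.

**Threshold selection.** Connected components are extracted per σ with
scipy's csgraph machinery and relabeled to first-appearance order.
Silhouette selection uses only the *initial* partitions — refinement is
excluded from the decision because merge order makes it the least stable
stage — and ties go to the smallest σ, the leftmost maximizer. Partitions
with K = 1 or K = n carry no Silhouette information and are skipped; if
every σ yields one, the run aborts with guidance rather than returning an
arbitrary partition.

**Refinement order.** The merge rules leave the processing order open and
order can matter when sub-clusters merge with each other; sub-clusters are
handled smallest-first with cluster index as tie-break, one merge per
iteration, so behavior is deterministic. Singletons that survive (best
relativity < 0.5) and sub-clusters anticorrelated with every major mean
are terminal: they are not revisited unless something merges *into* them.
With no major cluster at all, Rule 2 has no target and all sub-clusters
are kept. Each productive iteration reduces the cluster count, so the
500-iteration cap is a safety net, not an expected stop.

**φ default.** No principled value exists a priori; max(2, 1% of n) makes
singletons always minor, scales with dataset size, and stays conservative
(at n = 384 it is 4). It is a flag (`--phi`) because the right value is a
judgment about the dataset.

## Validity indices

ARI, and the pair-counting sensitivity, specificity, Jaccard and Minkowski
measures, are computed through the contingency table (verified in tests
against O(n²) pair enumeration). "Specificity" here is pair precision
TP/(TP+FP), the usage conventional in this literature, not 1 − FPR.
ARI is chance-corrected and can be slightly negative for worse-than-chance
agreement. For SI, Dunn and DBI the dissimilarity is Euclidean on the
working profiles by default, with 1 − Pearson as an option; Dunn uses
single-linkage separation and diameter (the classical definition, with a
centroid option), DBI the classical centroid dispersion / centroid
separation form. Singleton Silhouette is 0 by convention.

## Synthetic data

The generator plants K groups whose prototypes are sinusoids spanning two
full cycles across the sampled window with K evenly spaced phases —
mimicking cell-cycle phase groups whose members peak at different times —
plus i.i.d. Gaussian noise, followed by per-gene standardization. Defaults
(K = 5, 20 genes per group, τ = 17, noise SD 0.3 against unit prototype
amplitude) match the cell-cycle-like regime the test suite exercises; a
piecewise-switch family (staggered tanh switches, alternating direction)
mimics developmental courses such as sporulation. What it does *not*
emulate: missing values, heteroscedastic or intensity-dependent microarray
noise, outlier genes belonging to no group (available only via an explicit
`outlier_fraction` flag), unequal group sizes unless requested, and
overlapping/ambiguous phase annotations. Consequently, recovery tests
passing (ARI = 1 noiseless, ≥ 0.95 at noise 0.3) demonstrate correctness
of the machinery on well-posed input, not expected accuracy on real
arrays, where annotation ambiguity alone caps achievable ARI well below 1.

## Numerical choices

* Zero-variance window segments have undefined correlation; they
  contribute similarity 0 (no evidence), diagonal stays 1.
* Relativity entries are clipped to [0, 1] after averaging to absorb float
  drift; binarization uses ≥ σ (boundary edges kept).
* Matrix I/O prints 17 significant digits and reads with round-trip float
  parsing, so write→read is bit-exact.
* The estimator's single `random_state` fans out through
  `SeedSequence.spawn`, one child per AP run and per subset draw; per-seed
  determinism is tested.

## Problem sizes in the test suite

Tests run the full pipeline at n ≈ 100 genes and τ = 12–17 points (a few
seconds per fit), the AP-vs-exhaustive-oracle check at n ≤ 8 over 50
instances, component extraction against transitive closure at n ≤ 10, and
pair counting against enumeration at n ≤ 12. These sizes make every oracle
exact while keeping the default suite fast; nothing in the implementation
is specific to them.

## Known limitations

* AP cost is O(n² · iterations) per window and votes multiply it by ~τ²/8;
  thousands of genes at long time courses will be slow in pure
  numpy (no sparse or partial-update AP variant is provided).
* Connected components at σ near 0.5 can chain unrelated groups through
  single spurious votes when the vote count is small; the Silhouette sweep
  mitigates but cannot eliminate this on very short series.
* Exact reproduction of other affinity-propagation implementations is not
  guaranteed under near-ties; tie-breaking differs at the 1e−12 jitter
  scale.
* No missing-value handling beyond reject-or-drop at load time.
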