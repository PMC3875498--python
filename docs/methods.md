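# Methods

This note documents the model assumptions, the parameters that matter, the
numerical choices made where the design was genuinely open, what the
synthetic data do and do not emulate, and the known limitations.

## Data model

A tract is an ordered polyline of ≥ 2 points in mm world coordinates;
consecutive duplicate vertices are collapsed at construction so every
segment has positive length. TRK voxel-order coordinates are converted to
RAS mm at the I/O boundary via the file's affine; nothing downstream ever
sees voxel indices. Tract centroids are length-weighted averages of
segment midpoints, which makes them invariant to vertex density — a plain
vertex mean would drift toward densely sampled stretches. An optional
`min_length_mm` load filter reproduces the usual short-tract
preprocessing; it is off by default because no canonical threshold exists.

## Similarity measures

TCD, TOS and HD are standard. The combined distance CD needs several
choices that its published description leaves to cited prior work; the
package makes them explicit and configurable:

* **Normalization.** Each mm-valued component is mapped into [0, 1) by the
  bounded monotone map d ↦ d/(d + c), with c_tcd = 20 mm and
  c_partial = 10 mm by default; TOS is divided by 180°; the shape term is
  already in [0, 1]. The one-sided CD is the weighted sum of the four
  normalized terms (default weights all 1), and the final CD is the
  minimum of the one-sided values over reversal of the second tract, so
  orientation conventions of the tracking algorithm cannot split bundles.
* **Partial matching.** Both tracts are resampled to 20 points; the
  globally closest point pair anchors the match and equal arc length is
  taken on each side, limited by whichever tract runs out first. Fragments
  are contiguous slices of the resampled tracts, so the sub-tract length
  is equal on both sides up to one resampling step.
* **Shape descriptor.** Fragments are compared by their sequences of
  turning angles after resampling to a common point count, with distance =
  mean absolute angle difference / 180°. This is translation- and
  rotation-invariant, cheap, and discriminates straight from bent
  fragments; it ignores torsion sign (a fragment and its mirror image are
  equivalent), which is acceptable at the role the term plays inside CD.

HD is computed exactly (no segment interpolation) from the pairwise point
distance matrix; a one-against-many variant evaluates one distance matrix
against concatenated point sets with segmented min/max reductions, which
is what makes matrix precomputation and remainder labeling fast without
changing any value.

## Local Outlier Factors

Standard Breunig LOF on the precomputed matrix with exactly k neighbours,
ties broken toward the lower tract id (determinism). k defaults to 15, the
study's setting; k should stay below the smallest expected cluster size or
LOFs inside small bundles are artificially inflated. Duplicate tracts give
infinite local reachability density; whenever a tract and its neighbours
all have infinite LRD the LOF is defined as 1 (a dense stack of identical
tracts is maximally non-outlying), and a finite cap (1e12) is applied in
the mixed case so downstream arithmetic stays finite.

## LOF correction factor

The correction α(l_i, l_j) = √(max(1, l_i) · max(1, l_j)) is symmetric,
equals 1 when both LOFs are ≤ 1 and is strictly increasing in either
argument above 1. Inter-cluster distances are multiplied by α (repulsion
of outliers), intra-cluster distances divided by it (attraction, so
outliers are not selected as representatives). The geometric mean rather
than the plain product is deliberate: reassignment of an eliminated tract
evaluates the same α with the tract's own (high) LOF, and an undamped
product makes the reassignment test nearly impossible to pass for exactly
the tracts that step exists to rescue, defeating its purpose. The square
root preserves the ordering of all repulsion effects while keeping
rescued-tract distances within reach of the assignment threshold.

## Representatives and merging

The representative count follows the two-stage rule m(n) =
max(1, round(ratio·n)) for n below the transition size n_t and m_max
beyond it; defaults ratio = 40/120, n_t = 120, m_max = 40 (the study
configuration, which makes the rule continuous at the transition). The
medoid minimizes mean raw distance to all members; representatives are
selected by greedy farthest-point iteration under the LOF-adjusted
intra-cluster distance, starting from the tract farthest from the medoid.
Every tie in the engine (neighbour sets, medoids, representative picks,
merge pairs) breaks toward the lowest id or lexicographically smallest id
pair, which together with row-block parallelism makes the whole pipeline
bit-reproducible for any worker count.

Merging repeatedly takes the globally closest live pair (minimum over
representative pairs of α-adjusted, optionally atlas-weighted distance).
"After t % of the clustering" is interpreted as after ⌈t % of the merges
planned for that pass⌉, with elimination firing once per pass; merge count
is the pass's natural clock. The per-partition preclustering target is
⌈|partition|/q⌉ with q = 3 (the customary reduction factor for
representative-based preclustering), config-exposed.

## Assignment test

An eliminated or unsampled tract joins its nearest cluster iff the
distance to that cluster's closest representative is ≤ γ·σ_c, where σ_c is
the standard deviation of the cluster's pairwise representative distances;
with fewer than two representative pairs σ_c falls back to the mean
internal member distance, and for singleton clusters to the global median
pairwise distance of the sample. γ defaults to 5 for both reassignment and
labeling. The value is larger than one might naively pick because
farthest-point representatives concentrate their pairwise distances near
the cluster diameter, so σ_c systematically *underestimates* the typical
member-to-nearest-representative distance: on synthetic bundles, genuine
members sit up to ≈ 4 σ_c from their nearest representative while isolated
outliers start at ≈ 10 σ_c, and γ = 5 centres the threshold in that gap.
Assignment is monotone in γ by construction.

## Atlas

Classes are built from labeled bundles: per voxel the ratio of the
bundle's tract density to the total labeled-tract density, averaged over
the datasets containing the bundle (voxels a dataset misses contribute 0),
max-normalized to 1 per class, thresholded at probability 0.3. Tracts are
rasterized by sampling each segment at ≤ ¼ of the grid resolution with
floor-to-index, 0-based, half-open voxel convention; 1 mm isotropic grids
are the default.

Class membership of a tract is the fraction of its voxels inside the
binarized class support (probabilities only gate voxel inclusion through
the cutoff — probabilistic membership weighting is intentionally not
done); cluster membership is the mean over members, maintained exactly as
a weighted mean across merges. The guidance factor has four cases from the
two clusters' best memberships s_a, s_b: neither on the atlas → 1; exactly
one → 1 + s (repulsion); both on the same class → 1 − s_a·s_b/2
(attraction, bounded at ½); different classes → 1 + s_a + s_b (repulsion,
strictly stronger than the one-sided case at equal membership). All cases
are symmetric and monotone in the memberships. These forms are this
package's choice; any factor with the same sign structure and monotonicity
behaves qualitatively identically, and the neutral factor 1 reproduces an
unguided run bit-identically (tested).

## Spatial matching

Cluster density maps are per-voxel member counts normalized to max 1. The
matching value of a class probability map p and a cluster density map d is

    M = (1 − mean |p − d| over the intersection)
        − mean p over class-only voxels − mean d over cluster-only voxels,

i.e. agreement on the overlap penalized by uncovered class mass and by
extraneous cluster mass; identity gives 1 and fully disjoint supports are
assigned the range minimum (−2) so they never win a tie. Classes take
clusters greedily, best first, one-to-one. The *post-clustering merge
step* merges a cluster pair when the merged cluster's best matching value
strictly exceeds both parents' best values, repeated to a fixed point. A
coverage-sensitive score is essential here: a membership fraction is a
mean over members and therefore can never strictly exceed both parents,
whereas M rises when the two halves of a split bundle are reunited because
the uncovered-class penalty falls. Evaluation uses the union-voxel spatial
agreement (fraction of the cluster's voxel set inside the class), exposed
separately from the per-tract-mean membership to avoid conflating the two.

## Synthetic data

Bundles are cubic-spline centerlines (arcs centred on their own centre of
mass so grid layouts keep their nominal spacing) sampled at 20–40 points
per tract, with a constant per-tract Gaussian radial offset (default s.d.
1.5 mm) plus small per-point jitter, and optional truncation of up to a
fraction of each end to emulate incomplete tracts. Isolated outliers are
short random walks started uniformly in the data bounding box. The
centroid experiment replaces each tract by its centroid (as a degenerate
two-point tract) so clustering with TCD operates on a labeled 3D point
cloud; a coordinate-noise variant (`perturb_centroids`) that displaces
tracts rigidly is also provided.

Default experiment scales were chosen once to mirror the regimes the
method is designed for: recovery experiments use 8 bundles × 250 tracts at
40 mm spacing (well-separated bundles, sample 1000, 3 partitions); the
centroid experiment uses 16 bundles × 120 tracts at 15 mm spacing —
comparable to the proximity of real bundle centroid clouds — with noise
fractions {0, 33, 66, 99} %. Substantially fewer tracts per bundle makes
the aggressive elimination preset (critical size 4 at 80 % of the
preclustering) liable to wipe entire bundles out of a partition, an
artifact of undersized bundles rather than of the method. ARI assertions
on the noise sweep carry a 0.02 allowance because ARI saturates near 1 at
these scales and seed-to-seed fluctuation is of that order.

What the generator does **not** emulate: crossing/kissing fiber geometry,
registration error, scanner noise correlated along tracts, and realistic
bundle size imbalance. Passing tests therefore demonstrate the engine's
correctness and its qualitative noise/elimination behavior, not
segmentation accuracy on real diffusion data.

## Numerical and degenerate-input choices

* Closed-loop tracts (coincident endpoints): orientation falls back to the
  first-to-middle-point direction, logged.
* Fragments with < 3 points have undefined shape: shape distance 0 with a
  warning.
* Non-finite similarity values abort matrix computation with the offending
  pair reported.
* The similarity matrix is persisted as a flat float64 triangle plus a
  JSON sidecar (n, measure tag, SHA-256 checksum); loads verify the
  checksum.
* Sample-size bound: s = f·N + (N/u)·ln(1/δ) + (N/u)·√(ln²(1/δ) +
  2·f·u·ln(1/δ)), ceiled and clamped to N.

## Limitations

* The engine holds the dense sample similarity matrix in memory; samples
  beyond ~30 000 tracts need a blocked/out-of-core store, which is out of
  scope.
* CD's shape term compares matched fragments only; highly similar partial
  shapes from different bundles can depress CD, which is the known reason
  HD tends to yield higher spatial agreement than CD.
* Atlas guidance can only encourage anatomically consistent merges; it
  cannot split a cluster whose members genuinely overlap an atlas class.
* The Ward-linkage baseline and wall-clock speedup benchmarking are
  deliberately not part of this package.
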