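# catser

Atlas-guided clustering of large diffusion-MRI tractography datasets.

Whole-brain fiber tracking produces hundreds of thousands of streamlines
("tracts": ordered 3D polylines in mm) with no structural organization.
Grouping them into anatomically meaningful fiber bundles — corticospinal
tract, uncinate fasciculus, forceps major, … — is needed for bundle-wise
quantitative analysis, neurosurgical planning and visualization, but
conventional agglomerative clustering is quadratic in the number of tracts
and blind to anatomy. This package implements **CATSER** (Cluster Analysis
Through Smartly Extracted Representatives), a CURE-style hierarchical
method that exploits the redundancy of large datasets, together with the
construction of a probabilistic white-matter atlas and the machinery to let
that atlas *guide* the clustering. It is aimed at researchers processing
deterministic-tractography output (TrackVis TRK, MRtrix TCK) who want a
fast, reproducible, optionally atlas-guided bundle segmentation, and it is
fully exercisable on synthetic streamlines.

## The method

For tracts T_a, T_b every similarity measure d(·,·) is symmetric,
non-negative and reflexive. Four are provided:

* **TCD** — Euclidean distance between length-weighted tract centroids
  (each segment's midpoint weighted by its length), in mm;
* **TOS** — angle between endpoint-orientation unit vectors, in degrees;
* **HD** — two-sided point-set Hausdorff distance
  max(max_a min_b ‖x_a − x_b‖, max_b min_a ‖x_a − x_b‖), in mm;
* **CD** — combined distance: sum of normalized centroid, orientation,
  partial-overlap and shape terms, minimized over tract reversal so a tract
  and its reverse are at distance 0.

The clustering pipeline (all randomness from one seed):

1. **Sampling.** A uniform random sample S (Fisher–Yates) whose minimum
   size can be bounded by the CURE Chernoff formula so every cluster of
   size ≥ u is represented with probability ≥ 1 − δ.
2. **Precomputation.** The triangular |S|×|S| similarity matrix, computed
   once, in parallel over row blocks (bit-identical for any worker count),
   and from it the **Local Outlier Factor** LOF(t) of every sampled tract
   (Breunig et al.; k = 15): ≈1 deep inside clusters, ≫1 for isolated
   tracts.
3. **Partitioning and two-pass agglomeration.** Each of N partitions is
   preclustered, the results are joined, and a final pass produces the
   prototype clusters. Clusters are summarized by their medoid plus up to
   m(n) well-spread representative tracts, where m(n) grows linearly to a
   cap (40 representatives from cluster size 120 in the study
   configuration). The inter-cluster distance is the minimum over
   representative pairs of d(p,q)·α(LOF_p, LOF_q) with the correction
   α = √(max(1,LOF_p)·max(1,LOF_q)) ≥ 1 — outlying tracts repel clusters —
   while representative selection uses d/α, pulling outliers inward so
   they are never chosen as representatives. When an atlas is supplied the
   distance is further multiplied by a four-case weighting factor from the
   clusters' best atlas-class memberships (attraction when both match the
   same bundle, repulsion when they match different ones).
4. **Outlier elimination.** After t% of each pass's merges, clusters of
   size ≤ s are removed (presets low/moderate/high per the published
   parameter table); the eliminated tracts are later re-evaluated and
   reassigned to their nearest prototype cluster iff the closest
   representative lies within γ times that cluster's representative
   spread, else they stay outliers.
5. **Labeling.** Tracts outside the sample are assigned by the same rule
   (assuming LOF ≈ 1), in parallel with deterministic output.

A probabilistic atlas is built from labeled bundles: per voxel, the ratio
of bundle tract density to total tract density, averaged over datasets,
max-normalized per class and thresholded at 0.3. Clusters are matched to
atlas classes post hoc by a greedy one-to-one assignment of a
coverage-sensitive matching value, and evaluated by spatial agreement
(fraction of the cluster's voxels inside the class).

## Worked example

```python
import numpy as np
from catser import *
from catser.synthetic import default_bundle_specs

rng = np.random.default_rng(0)
dataset, truth = generate_bundles(default_bundle_specs(n_bundles=8, n_tracts=250), rng)
dataset, truth = add_outlier_tracts(dataset, truth, 0.05, rng)

cfg = RunConfig(measure="hd", sample_size=1000, n_partitions=3,
                target_clusters=8, k=15, strategy="moderate", seed=0)
result = run_catser(dataset, cfg)
metrics = evaluate_clustering(result, truth)
```

This generates eight well-separated synthetic bundles of 250 streamlines
each plus 5 % isolated outlier tracts, clusters a 1000-tract sample with
the Hausdorff measure and moderate outlier elimination, and labels the
rest. Output:

```
2100 tracts (100 injected outliers)
8 clusters, 107 flagged outliers
ARI 0.996  outlier recall 1.00  precision 0.93
cluster 1575: 250 tracts, 23 representatives
cluster 1581: 250 tracts, 29 representatives
cluster 1594: 249 tracts, 16 representatives
```

All eight bundles are recovered almost perfectly (Adjusted Rand Index
0.996 against the generating labels), every injected outlier is flagged,
and the 107 flagged tracts are mostly the injected noise (precision 0.93 —
a handful of genuine stragglers are also rejected).

The same pipeline is available from the shell:

```sh
catser simulate data/ --bundles 8 --tracts-per-bundle 250 --seed 0 --toy-atlas
catser cluster data/tracts.jsonl run/ --measure hd --strategy moderate --seed 0
catser eval run/labels.tsv data/truth.tsv
catser match data/tracts.jsonl run/labels.tsv data/atlas match.tsv
```

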