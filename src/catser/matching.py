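"""Post-hoc spatial matching of clusters to atlas classes.

Clusters are rasterized to normalized tract-density maps on the atlas grid
and compared to the class probability maps with a matching value that
rewards agreement on the intersection and penalizes mass on either side's
non-intersecting voxels.  A greedy best-first pass then assigns clusters to
classes one-to-one.  The evaluation metric is the spatial agreement of the
cluster's union voxel set with the class support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import AtlasClass, ProbabilisticAtlas, Voxel, VoxelGrid, rasterize_tract
from .tracts import Tract

#: score assigned to pairs with no intersecting voxels: the minimum of the
#: score's range, so disjoint pairs never win a tie
DISJOINT_SCORE = -2.0


@dataclass
class DensityMap:
    """Per-voxel normalized tract density of one cluster (max value 1)."""

    grid: VoxelGrid
    values: dict[Voxel, float]


def cluster_density_map(tracts: list[Tract], grid: VoxelGrid) -> DensityMap:
    """Count member tracts per voxel, normalized to a maximum of 1."""
    if not tracts:
        raise ValueError("empty cluster")
    counts: dict[Voxel, int] = {}
    for t in tracts:
        for v in rasterize_tract(t, grid):
            counts[v] = counts.get(v, 0) + 1
    peak = max(counts.values())
    return DensityMap(grid, {v: c / peak for v, c in counts.items()})


def matching_value(cls: AtlasClass | dict[Voxel, float], cd: DensityMap) -> float:
    """Spatial resemblance score of a class probability map and a cluster map.

    score = (1 - mean |p - d| over intersecting voxels)
            - mean class probability over class-only voxels
            - mean cluster density over cluster-only voxels

    Identity gives 1; any missing overlap or extraneous mass lowers the
    score; fully disjoint supports score the range minimum (-2).
    """
    probs = cls.prob if isinstance(cls, AtlasClass) else cls
    inter = probs.keys() & cd.values.keys()
    if not inter:
        return DISJOINT_SCORE
    diff = float(np.mean([abs(probs[v] - cd.values[v]) for v in inter]))
    only_cls = probs.keys() - inter
    only_cd = cd.values.keys() - inter
    mu_cls = float(np.mean([probs[v] for v in only_cls])) if only_cls else 0.0
    mu_cd = float(np.mean([cd.values[v] for v in only_cd])) if only_cd else 0.0
    return (1.0 - diff) - mu_cls - mu_cd


def greedy_one_to_one(
    scores: list[tuple[str, int, float]],
    n_classes: int,
    n_clusters: int,
) -> dict[str, tuple[int, float]]:
    """Best-first injective assignment from a (class, cluster, score) table.

    Repeatedly takes the globally best unassigned pair until every class has
    a cluster or clusters run out; ties break on lexicographic class name,
    then lowest cluster id.
    """
    assignment: dict[str, tuple[int, float]] = {}
    used: set[int] = set()
    while len(assignment) < n_classes and len(used) < n_clusters:
        best = None
        for name, cid, s in scores:
            if name in assignment or cid in used:
                continue
            if best is None or s > best[2] \
                    or (s == best[2] and (name, cid) < (best[0], best[1])):
                best = (name, cid, s)
        if best is None:
            break
        assignment[best[0]] = (best[1], best[2])
        used.add(best[1])
    return assignment


def match_clusters_to_atlas(
    clusters: dict[int, list[Tract]],
    atlas: ProbabilisticAtlas,
) -> dict[str, tuple[int, float]]:
    """Greedy one-to-one assignment of clusters to atlas classes.

    Returns class name -> (cluster id, matching value); see
    :func:`greedy_one_to_one` for the tie rules.
    """
    if not clusters:
        raise ValueError("need at least one cluster")
    dmaps = {cid: cluster_density_map(tr, atlas.grid) for cid, tr in clusters.items()}
    scores = [
        (cls.name, cid, matching_value(cls, dmaps[cid]))
        for cls in atlas.classes
        for cid in sorted(clusters)
    ]
    return greedy_one_to_one(scores, len(atlas.classes), len(clusters))


def spatial_agreement(tracts: list[Tract], cls: AtlasClass, grid: VoxelGrid) -> float:
    """Fraction of the cluster's union voxel set lying inside the class.

    This is the cluster-level (voxelized) variant used for evaluation; the
    per-tract-averaged variant is
    :func:`catser.atlas.cluster_class_membership`.
    """
    vox: set[Voxel] = set()
    for t in tracts:
        vox |= rasterize_tract(t, grid)
    if not vox:
        return 0.0
    return len(vox & cls.voxels) / len(vox)
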