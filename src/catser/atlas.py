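"""Probabilistic white-matter atlas: construction, membership and guidance.

An atlas is a set of named classes (fiber bundles) on a common voxel grid;
each class stores, per voxel, the probability that the voxel belongs to the
bundle.  Classes may overlap.  Class membership of a tract is the fraction
of its rasterized voxels that fall inside the (binarized) class support;
probabilistic weighting of the membership itself is deliberately not done.

The atlas guides clustering by multiplying inter-cluster distances with a
weighting factor derived from the clusters' best-matching classes:

* neither cluster lies on the atlas        -> w = 1 (neutral);
* exactly one does, with membership s      -> w = 1 + s          (repulsion);
* both match the same class, s_a and s_b   -> w = 1 - s_a*s_b/2  (attraction);
* both match different classes             -> w = 1 + s_a + s_b  (repulsion,
  stronger than the one-sided case at equal membership).

All four cases are symmetric in the cluster arguments and monotone in the
memberships.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tracts import Tract, TractDataset

logger = logging.getLogger("catser")

OUTLIER_LABEL = "OUTLIER"

Voxel = tuple[int, int, int]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel grid: shape, index->world affine, isotropic resolution in mm.

    World -> index follows the half-open voxel convention [i, i+1): apply the
    inverse affine, then floor.  Indices are 0-based.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    resolution: float = 1.0

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=np.float64)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def from_bounds(cls, lo, hi, resolution: float = 1.0) -> "VoxelGrid":
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        shape = tuple(int(np.ceil((h - l) / resolution)) + 1 for l, h in zip(lo, hi))
        aff = np.eye(4)
        aff[:3, :3] *= resolution
        aff[:3, 3] = lo
        return cls(shape, aff, resolution)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        idx = pts @ inv[:3, :3].T + inv[:3, 3]
        return np.floor(idx).astype(np.int64)

    def in_bounds(self, idx: np.ndarray) -> np.ndarray:
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)


def rasterize_tract(t: Tract, grid: VoxelGrid) -> set[Voxel]:
    """Voxels traversed by the polyline.

    Each segment is sampled at a step of at most a quarter of the grid
    resolution so no crossed voxel is skipped at practical segment lengths.
    Points outside the grid are clipped with a warning; a tract entirely
    outside the grid is an error.
    """
    step = 0.25 * grid.resolution
    samples = [t.points[:1]]
    for p, q in zip(t.points[:-1], t.points[1:]):
        seg = np.linalg.norm(q - p)
        n = max(int(np.ceil(seg / step)), 1)
        frac = np.linspace(0.0, 1.0, n + 1)[1:]
        samples.append(p + frac[:, None] * (q - p))
    pts = np.vstack(samples)
    idx = grid.world_to_index(pts)
    ok = grid.in_bounds(idx)
    if not ok.any():
        raise ValueError(f"tract {t.id} lies entirely outside the grid")
    if not ok.all():
        logger.warning("tract %d partially outside grid: %d samples clipped",
                       t.id, int((~ok).sum()))
    return set(map(tuple, idx[ok]))


@dataclass
class AtlasClass:
    """One bundle of the atlas: a set of voxels with probabilities in (0, 1]."""

    name: str
    prob: dict[Voxel, float] = field(default_factory=dict)

    @property
    def voxels(self) -> set[Voxel]:
        return set(self.prob)


@dataclass
class ProbabilisticAtlas:
    grid: VoxelGrid
    classes: list[AtlasClass]

    def __post_init__(self):
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("atlas class names must be unique")

    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def __getitem__(self, name: str) -> AtlasClass:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    # -- NIfTI persistence --------------------------------------------
    def save(self, directory: str | Path) -> None:
        """One NIfTI probability volume per class plus a JSON manifest."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in self.classes:
            vol = np.zeros(self.grid.shape, dtype=np.float32)
            for v, p in c.prob.items():
                vol[v] = p
            nib.save(nib.Nifti1Image(vol, self.grid.affine),
                     str(directory / f"{c.name}.nii"))
        manifest = {
            "classes": self.class_names(),
            "shape": list(self.grid.shape),
            "affine": np.asarray(self.grid.affine).tolist(),
            "resolution": self.grid.resolution,
        }
        (directory / "atlas.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ProbabilisticAtlas":
        import nibabel as nib

        directory = Path(directory)
        manifest = json.loads((directory / "atlas.json").read_text())
        grid = VoxelGrid(tuple(manifest["shape"]), np.array(manifest["affine"]),
                         manifest["resolution"])
        classes = []
        for name in manifest["classes"]:
            vol = np.asarray(nib.load(str(directory / f"{name}.nii")).dataobj)
            vox = np.argwhere(vol > 0)
            classes.append(AtlasClass(name, {tuple(v): float(vol[tuple(v)]) for v in vox}))
        return cls(grid, classes)


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------

def tract_class_membership(t: Tract, cls: AtlasClass, grid: VoxelGrid) -> float:
    """Fraction of the tract's voxels intersecting the class support."""
    vox = rasterize_tract(t, grid)
    if not vox:
        return 0.0
    return len(vox & cls.voxels) / len(vox)


def cluster_class_membership(tracts: list[Tract], cls: AtlasClass, grid: VoxelGrid) -> float:
    """Mean of the member tracts' class memberships."""
    if not tracts:
        raise ValueError("empty cluster")
    return float(np.mean([tract_class_membership(t, cls, grid) for t in tracts]))


# ---------------------------------------------------------------------------
# atlas-guided distance weighting
# ---------------------------------------------------------------------------

def weighting_from_memberships(
    memb_a: np.ndarray,
    memb_b: np.ndarray,
    min_membership: float = 0.0,
) -> float:
    """Four-case weighting factor from per-class membership vectors."""
    memb_a = np.asarray(memb_a, dtype=np.float64)
    memb_b = np.asarray(memb_b, dtype=np.float64)
    ia, ib = int(np.argmax(memb_a)), int(np.argmax(memb_b))
    sa, sb = float(memb_a[ia]), float(memb_b[ib])
    has_a, has_b = sa > min_membership, sb > min_membership
    if not has_a and not has_b:          # case 1: off-atlas, neutral
        return 1.0
    if has_a != has_b:                   # case 2: one-sided repulsion
        return 1.0 + (sa if has_a else sb)
    if ia == ib:                         # case 3: same bundle, attraction
        return 1.0 - 0.5 * sa * sb
    return 1.0 + sa + sb                 # case 4: different bundles, repulsion


def weighting_factor(tracts_a: list[Tract], tracts_b: list[Tract],
                     atlas: ProbabilisticAtlas, grid: VoxelGrid | None = None,
                     min_membership: float = 0.0) -> float:
    """Atlas weighting for two clusters given as member-tract lists."""
    grid = grid or atlas.grid
    ma = np.array([cluster_class_membership(tracts_a, c, grid) for c in atlas.classes])
    mb = np.array([cluster_class_membership(tracts_b, c, grid) for c in atlas.classes])
    return weighting_from_memberships(ma, mb, min_membership)


class AtlasGuidance:
    """Caches per-tract membership vectors and serves weighting factors.

    Membership vectors are exact means over cluster members, so the engine
    can maintain them incrementally as weighted means on merge.  With
    ``neutral=True`` every weight is forced to 1, which must reproduce an
    unguided run bit-identically.
    """

    def __init__(self, atlas: ProbabilisticAtlas, min_membership: float = 0.0,
                 neutral: bool = False):
        self.atlas = atlas
        self.grid = atlas.grid
        self.min_membership = min_membership
        self.neutral = neutral
        self._cache: dict[int, np.ndarray] = {}

    @property
    def n_classes(self) -> int:
        return len(self.atlas.classes)

    def tract_membership(self, t: Tract) -> np.ndarray:
        vec = self._cache.get(t.id)
        if vec is None:
            vox = rasterize_tract(t, self.grid)
            vec = np.array(
                [len(vox & c.voxels) / len(vox) if vox else 0.0
                 for c in self.atlas.classes])
            self._cache[t.id] = vec
        return vec

    def weight(self, memb_a: np.ndarray, memb_b: np.ndarray) -> float:
        if self.neutral:
            return 1.0
        return weighting_from_memberships(memb_a, memb_b, self.min_membership)


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

def build_atlas(
    bundled_datasets: list[tuple[TractDataset, dict[int, str]]],
    grid: VoxelGrid,
    prob_cutoff: float = 0.3,
    bundle_names: list[str] | None = None,
) -> ProbabilisticAtlas:
    """Build a probabilistic atlas from labeled bundles.

    For every dataset the per-voxel bundle probability is the ratio of the
    bundle's tract density to the total labeled-tract density in that voxel.
    The class probability is the average of the dataset probabilities over
    all datasets containing the bundle (voxels a dataset's bundle misses
    contribute 0), normalized per class to a maximum of 1; voxels below
    ``prob_cutoff`` are then removed.  Tracts labeled OUTLIER are ignored.
    """
    if not bundled_datasets:
        raise ValueError("need at least one labeled dataset")
    if bundle_names is None:
        seen: set[str] = set()
        for _, labels in bundled_datasets:
            seen |= {b for b in labels.values() if b != OUTLIER_LABEL}
        bundle_names = sorted(seen)

    per_dataset: list[dict[str, dict[Voxel, float]]] = []
    has_bundle: list[set[str]] = []
    for dataset, labels in bundled_datasets:
        total: dict[Voxel, int] = {}
        per_bundle: dict[str, dict[Voxel, int]] = {}
        for t in dataset:
            b = labels.get(t.id)
            if b is None or b == OUTLIER_LABEL:
                continue
            vox = rasterize_tract(t, grid)
            counts = per_bundle.setdefault(b, {})
            for v in vox:
                total[v] = total.get(v, 0) + 1
                counts[v] = counts.get(v, 0) + 1
        probs = {
            b: {v: c / total[v] for v, c in counts.items()}
            for b, counts in per_bundle.items()
        }
        per_dataset.append(probs)
        has_bundle.append(set(per_bundle))

    classes = []
    for name in bundle_names:
        contributing = [i for i in range(len(per_dataset)) if name in has_bundle[i]]
        if not contributing:
            logger.warning("build_atlas: bundle %r empty in all datasets, omitted", name)
            continue
        union: set[Voxel] = set()
        for i in contributing:
            union |= set(per_dataset[i][name])
        prob = {
            v: float(np.mean([per_dataset[i][name].get(v, 0.0) for i in contributing]))
            for v in union
        }
        peak = max(prob.values())
        prob = {v: p / peak for v, p in prob.items()}
        prob = {v: p for v, p in prob.items() if p >= prob_cutoff}
        classes.append(AtlasClass(name, prob))
    return ProbabilisticAtlas(grid, classes)


# ---------------------------------------------------------------------------
# post-clustering atlas-driven merging
# ---------------------------------------------------------------------------

def post_merge_by_atlas(result, dataset: TractDataset, atlas: ProbabilisticAtlas,
                        grid: VoxelGrid | None = None):
    """Greedily merge cluster pairs that improve best-class spatial matching.

    A pair is merged when the merged cluster matches its best atlas class
    strictly better than either parent matches its own best class, where
    "matches" is the coverage-sensitive matching value used for spatial
    matching (a fraction of a bundle leaves uncovered class voxels, so
    re-uniting a split bundle raises the value; a membership fraction alone
    cannot do this, being a mean over members).  Repeats to a fixed point;
    merges are appended to the merge tree with the merged matching value
    recorded as the "distance".  Mutates and returns ``result``.
    """
    from .matching import DensityMap, matching_value  # deferred: avoids cycle

    grid = grid or atlas.grid
    vox_cache: dict[int, set[Voxel]] = {}

    def tract_vox(tid: int) -> set[Voxel]:
        if tid not in vox_cache:
            vox_cache[tid] = rasterize_tract(dataset[tid], grid)
        return vox_cache[tid]

    def counts_of(member_ids) -> dict[Voxel, int]:
        counts: dict[Voxel, int] = {}
        for tid in member_ids:
            for v in tract_vox(tid):
                counts[v] = counts.get(v, 0) + 1
        return counts

    def best_match(counts: dict[Voxel, int]) -> float:
        peak = max(counts.values())
        dm = DensityMap(grid, {v: c / peak for v, c in counts.items()})
        return max(matching_value(cls, dm) for cls in atlas.classes)

    clusters = {c.id: c for c in result.clusters}
    counts = {c.id: counts_of(c.member_ids) for c in result.clusters}
    best = {cid: best_match(cnt) for cid, cnt in counts.items()}
    while len(clusters) > 1:
        best_pair, best_gain = None, -np.inf
        cids = sorted(clusters)
        for x in range(len(cids)):
            for y in range(x + 1, len(cids)):
                a, b = cids[x], cids[y]
                merged = dict(counts[a])
                for v, c in counts[b].items():
                    merged[v] = merged.get(v, 0) + c
                m_best = best_match(merged)
                if m_best > best[a] and m_best > best[b] and m_best > best_gain:
                    best_gain, best_pair = m_best, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        ca, cb = clusters.pop(a), clusters.pop(b)
        new_id = result.tree.next_id()
        from .cluster import Cluster  # local import to avoid a cycle

        bigger = ca if len(ca.member_ids) >= len(cb.member_ids) else cb
        merged_cluster = Cluster(
            id=new_id,
            member_ids=sorted(set(ca.member_ids) | set(cb.member_ids)),
            medoid_id=bigger.medoid_id,
            representative_ids=list(ca.representative_ids) + list(cb.representative_ids),
            birth_step=result.tree.n_steps(),
            core_member_ids=sorted(set(ca.core_member_ids) | set(cb.core_member_ids)),
        )
        result.tree.record_merge(a, b, new_id, best_gain)
        merged_counts = dict(counts.pop(a))
        for v, c in counts.pop(b).items():
            merged_counts[v] = merged_counts.get(v, 0) + c
        counts[new_id] = merged_counts
        best.pop(a), best.pop(b)
        best[new_id] = best_gain
        clusters[new_id] = merged_cluster
        for i in merged_cluster.member_ids:
            result.labels[i] = new_id
    result.clusters = [clusters[c] for c in sorted(clusters)]
    return result
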