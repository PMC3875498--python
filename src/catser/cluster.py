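"""The CATSER two-pass clustering engine.

CATSER (Cluster Analysis Through Smartly Extracted Representatives) is an
agglomerative hierarchical method in the CURE family, adapted to streamline
data: a random sample of the dataset is clustered in two passes (per-partition
preclustering, then a final pass over the joined clusters), with clusters
summarized by a medoid plus a small set of well-spread representative tracts.
Local Outlier Factors adjust both intra-cluster distances (attraction, so
outlying tracts are not picked as representatives) and inter-cluster
distances (repulsion, so outlying clusters merge late or never).  Slowly
growing clusters are eliminated as outliers at a fixed point of each pass,
then re-evaluated for reassignment, and finally all tracts outside the
sample are labeled against the prototype clusters.

An optional probabilistic white-matter atlas modulates inter-cluster
distances (see :mod:`catser.atlas`), steering merges toward anatomically
coherent bundles.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .atlas import AtlasGuidance, ProbabilisticAtlas
from .lof import compute_lofs
from .similarity import CDParams, SimilarityMatrix, compute_similarity_matrix, pairwise_measure
from .tracts import TractDataset

logger = logging.getLogger("catser")

OUTLIER = -1


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepCountConfig:
    """Piecewise representative-count rule.

    Stage 1 (growing clusters, n < n_t): the count follows the cluster size
    linearly, ``max(1, round(ratio * n))``.  Stage 2 (n >= n_t): a constant
    ``m_max`` keeps the cost of cluster comparisons bounded.  With the
    default ratio = m_max / n_t the rule is continuous at the transition.
    """

    ratio: float = 40.0 / 120.0
    n_t: int = 120
    m_max: int = 40

    def __post_init__(self):
        if self.ratio <= 0 or self.n_t < 1 or self.m_max < 1:
            raise ValueError("invalid representative-count configuration")


@dataclass(frozen=True)
class OutlierStrategy:
    """Two-stage outlier elimination parameters.

    After ``t1`` % of the preclustering merges, clusters of size <= ``s1``
    are removed; after ``t2`` % of the final-pass merges, clusters of size
    <= ``s2`` are removed.  Elimination fires once per stage.
    """

    t1: float
    s1: int
    t2: float
    s2: int

    def __post_init__(self):
        if not (0 < self.t1 <= 100 and 0 < self.t2 <= 100):
            raise ValueError("time points must be in (0, 100]")
        if self.s1 < 1 or self.s2 < 1:
            raise ValueError("critical sizes must be >= 1")


#: low / moderate / high intensities, plus the default two-stage setting
#: (eliminate size <3 after 80% of preclustering, size <4 after 60% of the
#: final pass) used for the whole-brain runs.
STRATEGY_PRESETS: dict[str, OutlierStrategy] = {
    "low": OutlierStrategy(95, 1, 85, 4),
    "moderate": OutlierStrategy(80, 2, 85, 6),
    "high": OutlierStrategy(80, 4, 85, 8),
    "default": OutlierStrategy(80, 2, 60, 3),
}


@dataclass
class Cluster:
    id: int
    member_ids: list[int]
    medoid_id: int
    representative_ids: list[int]
    birth_step: int = 0
    #: members at the end of the final clustering pass, before outlier
    #: reassignment and remainder labeling grow the cluster
    core_member_ids: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class MergeRecord:
    a: int
    b: int
    new: int
    distance: float
    step: int


@dataclass
class MergeTree:
    """Full record of merges; leaf cluster ``i`` holds tract ``leaf_ids[i]``."""

    leaf_ids: list[int]
    merges: list[MergeRecord] = field(default_factory=list)
    removed: list[tuple[int, int]] = field(default_factory=list)  # (cid, step)
    _next: int = 0

    def __post_init__(self):
        if self._next == 0:
            self._next = len(self.leaf_ids)

    def next_id(self) -> int:
        cid = self._next
        self._next += 1
        return cid

    def n_steps(self) -> int:
        return len(self.merges)

    def record_merge(self, a: int, b: int, new: int, distance: float) -> None:
        self.merges.append(MergeRecord(a, b, new, float(distance), len(self.merges)))

    def record_removed(self, cid: int) -> None:
        self.removed.append((cid, len(self.merges)))

    def replay(self) -> dict[int, set[int]]:
        """Reconstruct live clusters (cid -> set of tract ids) from the log."""
        live: dict[int, set[int]] = {i: {t} for i, t in enumerate(self.leaf_ids)}
        for rec in self.merges:
            live[rec.new] = live.pop(rec.a) | live.pop(rec.b)
        for cid, _ in self.removed:
            live.pop(cid, None)
        return live


@dataclass
class ClusteringResult:
    clusters: list[Cluster]
    outlier_ids: set[int]
    labels: np.ndarray  # tract id -> cluster id, or OUTLIER (-1)
    tree: MergeTree
    config: dict
    seed: int

    def labels_of(self, ids) -> np.ndarray:
        return self.labels[np.asarray(ids)]


# ---------------------------------------------------------------------------
# sampling and partitioning
# ---------------------------------------------------------------------------

def estimate_sample_size(
    n_total: int,
    min_cluster_size: int,
    fraction: float,
    confidence_delta: float,
) -> int:
    """Chernoff-bound minimum sample size (CURE derivation).

    Smallest s such that with probability >= 1 - delta a uniform sample of
    size s contains at least ``fraction * u`` tracts of every cluster of
    size >= u = ``min_cluster_size``:

        s = f*N + (N/u) * ln(1/d) + (N/u) * sqrt(ln(1/d)^2 + 2*f*u*ln(1/d))

    clamped to ``n_total``.
    """
    if not (0 < fraction <= 1 and 0 < confidence_delta < 1):
        raise ValueError("fraction in (0,1], confidence_delta in (0,1)")
    if not (1 <= min_cluster_size <= n_total):
        raise ValueError("min_cluster_size must be in [1, n_total]")
    log_term = math.log(1.0 / confidence_delta)
    ratio = n_total / min_cluster_size
    s = (fraction * n_total
         + ratio * log_term
         + ratio * math.sqrt(log_term ** 2 + 2.0 * fraction * min_cluster_size * log_term))
    return min(n_total, math.ceil(s))


def fisher_yates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unbiased Fisher-Yates (Durstenfeld) shuffle of 0..n-1."""
    arr = np.arange(n)
    if n < 2:
        return arr
    # one uniform draw per step; floor(u * (i+1)) is an unbiased index
    u = rng.random(n - 1)
    for i in range(n - 1, 0, -1):
        j = int(u[n - 1 - i] * (i + 1))
        arr[i], arr[j] = arr[j], arr[i]
    return arr


def draw_sample(dataset, size: int, seed: int | np.random.Generator):
    """Uniform random (sample, remainder) split of the dataset's tract ids."""
    n = len(dataset) if not isinstance(dataset, (int, np.integer)) else int(dataset)
    if not 1 <= size <= n:
        raise ValueError(f"sample size {size} out of range for {n} tracts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = fisher_yates(n, rng)
    return perm[:size], perm[size:]


def partition(sample_ids, n_parts: int, seed: int | np.random.Generator) -> list[np.ndarray]:
    """Shuffle then split into parts whose sizes differ by at most one."""
    sample_ids = np.asarray(sample_ids)
    if not 1 <= n_parts <= len(sample_ids):
        raise ValueError("n_parts out of range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = sample_ids[fisher_yates(len(sample_ids), rng)]
    return list(np.array_split(shuffled, n_parts))


# ---------------------------------------------------------------------------
# representative selection and distances
# ---------------------------------------------------------------------------

def num_representatives(n_tracts: int, cfg: RepCountConfig) -> int:
    if n_tracts < 1:
        raise ValueError("cluster must have at least one tract")
    if n_tracts >= cfg.n_t:
        m = cfg.m_max
    else:
        m = max(1, int(math.floor(cfg.ratio * n_tracts + 0.5)))
    return min(m, n_tracts)


def find_medoid(members, dense: np.ndarray) -> int:
    """Member with minimal mean raw distance to all members; ties -> lowest id."""
    members = np.asarray(sorted(members))
    sub = dense[np.ix_(members, members)]
    means = sub.mean(axis=1)
    return int(members[np.lexsort((members, means))[0]])


def lof_correction(lof_i: float, lof_j: float) -> float:
    """Symmetric correction factor >= 1; neutral when both LOFs are <= 1.

    alpha = sqrt(max(1, l_i) * max(1, l_j)): the geometric mean damps the
    product so that a single moderately outlying tract is repelled (or, in
    the intra-cluster inverse application, attracted) without its own LOF
    making it unassignable during outlier reassignment.
    """
    if lof_i <= 0 or lof_j <= 0:
        raise ValueError("LOFs must be positive")
    return math.sqrt(max(1.0, lof_i) * max(1.0, lof_j))


def intra_distance(i: int, j: int, dense: np.ndarray, lofs: np.ndarray) -> float:
    """Raw distance divided by the correction factor: attraction of outliers."""
    return float(dense[i, j] / lof_correction(lofs[i], lofs[j]))


def _select_reps(members, medoid: int, dense: np.ndarray, rlof: np.ndarray,
                 count: int) -> list[int]:
    """Greedy farthest-point representative selection under intra distances."""
    members = np.asarray(sorted(members))
    if count >= len(members):
        return [int(m) for m in members]
    adj = dense[np.ix_(members, [medoid])].ravel() / (rlof[members] * rlof[medoid])
    chosen: list[int] = []
    min_adj = adj.copy()  # min adjusted distance to {medoid} U chosen
    taken = np.zeros(len(members), dtype=bool)
    for _ in range(count):
        cand = np.where(~taken)[0]
        best = cand[np.lexsort((members[cand], -min_adj[cand]))[0]]
        chosen.append(int(members[best]))
        taken[best] = True
        d_new = dense[members, members[best]] / (rlof[members] * rlof[members[best]])
        min_adj = np.minimum(min_adj, d_new)
    return chosen


def select_representatives(c: Cluster, m: SimilarityMatrix | np.ndarray,
                           lofs: np.ndarray, cfg: RepCountConfig) -> list[int]:
    """Ordered, deterministic representative set for a cluster."""
    dense = m.to_dense() if isinstance(m, SimilarityMatrix) else m
    rlof = np.sqrt(np.maximum(np.asarray(lofs, dtype=np.float64), 1.0))
    count = num_representatives(len(c.member_ids), cfg)
    if len(c.member_ids) == 1:
        return [c.member_ids[0]]
    return _select_reps(c.member_ids, c.medoid_id, dense, rlof, count)


def _pair_distance(reps_a, reps_b, dense: np.ndarray, rlof: np.ndarray) -> float:
    sub = dense[np.ix_(reps_a, reps_b)] * np.outer(rlof[reps_a], rlof[reps_b])
    return float(sub.min())


def _distance_row(reps_a, other_clusters, dense: np.ndarray, rlof: np.ndarray) -> np.ndarray:
    """LOF-adjusted distances from one cluster to many, vectorized.

    Stacks the representatives of all other clusters and reduces the
    adjusted distance matrix segment-wise; identical to per-pair
    :func:`_pair_distance` values.
    """
    lens = [len(c.representative_ids) for c in other_clusters]
    concat = np.concatenate([np.asarray(c.representative_ids) for c in other_clusters])
    offsets = np.concatenate([[0], np.cumsum(lens)[:-1]]).astype(np.intp)
    reps_a = np.asarray(reps_a)
    M = dense[np.ix_(reps_a, concat)] * np.outer(rlof[reps_a], rlof[concat])
    return np.minimum.reduceat(M.min(axis=0) if M.shape[0] > 1 else M[0], offsets)


def cluster_distance(a: Cluster, b: Cluster, m: SimilarityMatrix | np.ndarray,
                     lofs: np.ndarray, guidance_weight: float = 1.0) -> float:
    """LOF-adjusted (and optionally atlas-weighted) inter-cluster distance."""
    dense = m.to_dense() if isinstance(m, SimilarityMatrix) else m
    rlof = np.sqrt(np.maximum(np.asarray(lofs, dtype=np.float64), 1.0))
    return _pair_distance(a.representative_ids, b.representative_ids, dense, rlof) \
        * guidance_weight


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

class _GuideState:
    """Per-cluster membership vectors maintained incrementally during merging."""

    def __init__(self, guidance: AtlasGuidance | None, memb: dict[int, np.ndarray],
                 sizes: dict[int, int]):
        self.guidance = guidance
        self.memb = memb
        self.sizes = sizes

    def weight(self, a: int, b: int) -> float:
        if self.guidance is None:
            return 1.0
        return self.guidance.weight(self.memb[a], self.memb[b])

    def on_merge(self, a: int, b: int, new: int) -> None:
        if self.guidance is None:
            return
        na, nb = self.sizes.pop(a), self.sizes.pop(b)
        self.memb[new] = (na * self.memb.pop(a) + nb * self.memb.pop(b)) / (na + nb)
        self.sizes[new] = na + nb


def agglomerate(
    initial: list[Cluster],
    target_k: int,
    stage: tuple[float, int] | None,
    dense: np.ndarray,
    lofs: np.ndarray,
    tree: MergeTree,
    rep_cfg: RepCountConfig,
    guide: _GuideState | None = None,
) -> tuple[list[Cluster], list[int]]:
    """Merge the globally closest pair until ``target_k`` clusters remain.

    ``stage`` = (t_percent, critical_size) schedules one outlier-elimination
    sweep after ceil(t% of the planned merges); eliminated members are
    returned separately.  Ties on the minimum distance break toward the
    lexicographically smallest (cid, cid) pair, so the procedure is fully
    deterministic.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    rlof = np.sqrt(np.maximum(np.asarray(lofs, dtype=np.float64), 1.0))
    guide = guide or _GuideState(None, {}, {})

    live: dict[int, Cluster] = {c.id: c for c in initial}
    slots = list(live.keys())          # slot index -> cid (or None)
    slot_of = {cid: i for i, cid in enumerate(slots)}
    n_slots = len(slots)
    D = np.full((n_slots, n_slots), np.inf)
    cl = list(live.values())
    if all(len(c.representative_ids) == 1 for c in cl):
        # singleton start: the whole matrix in one vectorized expression
        reps = np.array([c.representative_ids[0] for c in cl])
        D[:] = dense[np.ix_(reps, reps)] * np.outer(rlof[reps], rlof[reps])
        if guide.guidance is not None:
            for x in range(n_slots):
                for y in range(x + 1, n_slots):
                    w = guide.weight(cl[x].id, cl[y].id)
                    D[x, y] *= w
                    D[y, x] = D[x, y]
        np.fill_diagonal(D, np.inf)
    else:
        for x in range(1, n_slots):
            row = _distance_row(cl[x].representative_ids, cl[:x], dense, rlof)
            if guide.guidance is not None:
                row = row * np.array([guide.weight(cl[x].id, cl[y].id)
                                      for y in range(x)])
            D[x, :x] = row
            D[:x, x] = row

    planned = len(initial) - target_k
    elim_at = math.ceil(stage[0] / 100.0 * planned) if stage and planned > 0 else None
    outliers: list[int] = []
    merges_done = 0

    # cached per-row minima (value + one achieving column) so each merge
    # scans O(n) instead of the whole matrix
    rowmin = D.min(axis=1)
    rowarg = D.argmin(axis=1)

    def _refresh_row(s: int) -> None:
        rowmin[s] = D[s].min()
        rowarg[s] = int(D[s].argmin())

    def _invalidate_col(col: int) -> None:
        stale = np.flatnonzero(rowarg == col)
        for s in stale:
            _refresh_row(int(s))

    def _remove(cid: int) -> None:
        c = live.pop(cid)
        outliers.extend(c.member_ids)
        s = slot_of.pop(cid)
        slots[s] = None
        D[s, :] = np.inf
        D[:, s] = np.inf
        rowmin[s] = np.inf
        _invalidate_col(s)
        tree.record_removed(cid)

    while len(live) > target_k:
        mval = rowmin.min()
        if not np.isfinite(mval):
            break
        cand_rows = np.flatnonzero(rowmin == mval)
        pairs = sorted(
            (min(slots[x], slots[int(y)]), max(slots[x], slots[int(y)]))
            for x in cand_rows
            for y in np.flatnonzero(D[x] == mval)
        )
        a, b = pairs[0]
        ca, cb = live.pop(a), live.pop(b)
        new_id = tree.next_id()
        members = sorted(set(ca.member_ids) | set(cb.member_ids))
        medoid = find_medoid(members, dense)
        count = num_representatives(len(members), rep_cfg)
        reps = _select_reps(members, medoid, dense, rlof, count) \
            if len(members) > 1 else list(members)
        nc = Cluster(new_id, members, medoid, reps, birth_step=tree.n_steps(),
                     core_member_ids=members)
        tree.record_merge(a, b, new_id, mval)
        guide.on_merge(a, b, new_id)

        sa, sb = slot_of.pop(a), slot_of.pop(b)
        slots[sb] = None
        D[sb, :] = np.inf
        D[:, sb] = np.inf
        rowmin[sb] = np.inf
        slots[sa] = new_id
        slot_of[new_id] = sa
        live[new_id] = nc
        D[sa, :] = np.inf
        D[:, sa] = np.inf
        others = [cid for cid in slot_of if cid != new_id]
        if others:
            row = _distance_row(nc.representative_ids,
                                [live[c] for c in others], dense, rlof)
            if guide.guidance is not None:
                row = row * np.array([guide.weight(new_id, c) for c in others])
            for c, d in zip(others, row):
                s = slot_of[c]
                D[sa, s] = D[s, sa] = d
                if d < rowmin[s]:
                    rowmin[s] = d
                    rowarg[s] = sa
        _refresh_row(sa)
        _invalidate_col(sa)
        _invalidate_col(sb)

        merges_done += 1
        if elim_at is not None and merges_done == elim_at:
            crit = stage[1]
            for cid in sorted(live):
                if len(live[cid].member_ids) <= crit:
                    _remove(cid)
            elim_at = None

    for c in live.values():
        c.core_member_ids = list(c.member_ids)
    return sorted(live.values(), key=lambda c: c.id), outliers


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _cluster_sigma(c: Cluster, dense: np.ndarray, global_median: float) -> float:
    """Spread of a cluster's internal representative distances.

    Falls back to the mean internal member distance when fewer than two
    representative pairs exist, and to the global median pairwise distance
    of the sample for singletons.
    """
    reps = c.representative_ids
    pair_d = [dense[i, j] for i, j in combinations(reps, 2)]
    if len(pair_d) >= 2:
        return float(np.std(pair_d))
    mem = c.member_ids
    if len(mem) >= 2:
        sub = dense[np.ix_(mem, mem)]
        return float(sub[np.triu_indices(len(mem), k=1)].mean())
    return global_median


def reassign_or_label(
    dist_to_reps: dict[int, np.ndarray],
    sigmas: dict[int, float],
    gamma: float,
) -> int:
    """Nearest-cluster assignment under the spread test.

    ``dist_to_reps`` maps cluster id to the (adjusted) distances from the
    tract to that cluster's representatives.  The tract joins the cluster
    with the smallest closest-representative distance iff that distance is
    within ``gamma`` times the cluster's representative spread; otherwise
    it is an outlier.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    best_cid, best_d = OUTLIER, np.inf
    for cid in sorted(dist_to_reps):
        d = float(np.min(dist_to_reps[cid]))
        if d < best_d:
            best_cid, best_d = cid, d
    if best_cid == OUTLIER:
        return OUTLIER
    return best_cid if best_d <= gamma * sigmas[best_cid] else OUTLIER


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_catser(
    dataset: TractDataset,
    config,
    atlas: ProbabilisticAtlas | None = None,
) -> ClusteringResult:
    """Run the complete two-pass pipeline on a dataset.

    Steps: draw the random sample; precompute the similarity matrix and the
    LOFs; partition; precluster each partition with the first elimination
    stage; join; final clustering with the second elimination stage;
    reassign eliminated tracts; label the remainder of the dataset.  With an
    ``atlas``, inter-cluster distances are weighted by class membership in
    all of those stages, and an extra atlas-driven merge pass runs at the
    end (configurable).
    """
    n_total = len(dataset)
    if n_total == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    size = min(config.sample_size, n_total)
    sample_ids, remainder_ids = draw_sample(n_total, size, rng)
    sample_tracts = [dataset[int(i)] for i in sample_ids]

    cd_params = getattr(config, "cd_params", None) or CDParams()
    matrix = compute_similarity_matrix(sample_tracts, config.measure,
                                       config.n_workers, cd_params)
    dense = matrix.to_dense()
    k = min(config.k, size - 1)
    if getattr(config, "lof_neutral", False) or k < 1 or size <= k:
        lofs = np.ones(size)
    else:
        lofs = compute_lofs(matrix, k).lof
    rlof = np.sqrt(np.maximum(lofs, 1.0))

    guidance = None
    memb: dict[int, np.ndarray] = {}
    sizes: dict[int, int] = {}
    if atlas is not None:
        guidance = AtlasGuidance(atlas,
                                 min_membership=getattr(config, "min_membership", 0.0),
                                 neutral=getattr(config, "atlas_neutral", False))
        for pos, t in enumerate(sample_tracts):
            memb[pos] = guidance.tract_membership(t)
            sizes[pos] = 1
    guide = _GuideState(guidance, memb, sizes)

    tree = MergeTree(leaf_ids=[int(i) for i in sample_ids])
    strategy: OutlierStrategy = config.strategy
    rep_cfg: RepCountConfig = config.rep

    parts = partition(np.arange(size), min(config.n_partitions, size), rng)
    joined: list[Cluster] = []
    outlier_pos: list[int] = []
    for part in parts:
        init = [Cluster(int(p), [int(p)], int(p), [int(p)]) for p in sorted(part)]
        tgt = max(1, math.ceil(len(part) / config.precluster_reduction))
        stage1 = (strategy.t1, strategy.s1) if strategy else None
        cl, outs = agglomerate(init, tgt, stage1, dense, lofs, tree, rep_cfg, guide)
        joined.extend(cl)
        outlier_pos.extend(outs)

    target = min(config.target_clusters, len(joined))
    stage2 = (strategy.t2, strategy.s2) if strategy else None
    clusters, outs = agglomerate(joined, target, stage2, dense, lofs, tree,
                                 rep_cfg, guide)
    outlier_pos.extend(outs)

    # ---- step 7: reassign eliminated tracts --------------------------
    global_median = float(np.median(matrix.values)) if matrix.values.size else 0.0
    sigmas = {c.id: _cluster_sigma(c, dense, global_median) for c in clusters}
    assigned_extra: dict[int, list[int]] = {c.id: [] for c in clusters}
    final_outlier_pos: list[int] = []
    for p in sorted(outlier_pos):
        dists = {}
        for c in clusters:
            reps = np.asarray(c.representative_ids)
            d = dense[p, reps] * rlof[p] * rlof[reps]
            if guidance is not None:
                d = d * guidance.weight(memb[p] if p in memb
                                        else guidance.tract_membership(sample_tracts[p]),
                                        guide.memb[c.id])
            dists[c.id] = d
        cid = reassign_or_label(dists, sigmas, config.gamma_reassign) if dists else OUTLIER
        if cid == OUTLIER:
            final_outlier_pos.append(p)
        else:
            assigned_extra[cid].append(p)

    # ---- step 8: label tracts outside the sample ---------------------
    if config.measure == "hd":
        from .similarity import hausdorff_one_to_many

        def many_fn(t, rep_tracts):
            return hausdorff_one_to_many(t, rep_tracts)
    else:
        measure_fn = pairwise_measure(config.measure, cd_params)

        def many_fn(t, rep_tracts):
            return np.array([measure_fn(t, r) for r in rep_tracts])
    rep_info = []
    for c in clusters:
        reps = c.representative_ids
        rep_info.append((c.id, [sample_tracts[r] for r in reps],
                         rlof[np.asarray(reps)],
                         guide.memb.get(c.id) if guidance is not None else None))

    def _label_chunk(ids: np.ndarray) -> list[int]:
        out = []
        for tid in ids:
            t = dataset[int(tid)]
            tvec = guidance.tract_membership(t) if guidance is not None else None
            dists = {}
            for cid, rep_tracts, rep_lofs, cvec in rep_info:
                d = many_fn(t, rep_tracts) * rep_lofs
                if guidance is not None:
                    d = d * guidance.weight(tvec, cvec)
                dists[cid] = d
            out.append(reassign_or_label(dists, sigmas, config.gamma_label)
                       if dists else OUTLIER)
        return out

    labels = np.full(n_total, OUTLIER, dtype=np.int64)
    if len(remainder_ids) and clusters:
        chunks = np.array_split(remainder_ids, max(1, config.n_workers))
        if config.n_workers <= 1:
            results = [_label_chunk(ch) for ch in chunks]
        else:
            with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
                results = list(pool.map(_label_chunk, chunks))
        for ch, res in zip(chunks, results):
            for tid, lab in zip(ch, res):
                labels[int(tid)] = lab

    # ---- assemble result in global tract ids -------------------------
    final_clusters: list[Cluster] = []
    for c in clusters:
        members = [int(sample_ids[p]) for p in c.member_ids]
        members += [int(sample_ids[p]) for p in assigned_extra[c.id]]
        final_clusters.append(Cluster(
            id=c.id,
            member_ids=sorted(members),
            medoid_id=int(sample_ids[c.medoid_id]),
            representative_ids=[int(sample_ids[r]) for r in c.representative_ids],
            birth_step=c.birth_step,
            core_member_ids=sorted(int(sample_ids[p]) for p in c.core_member_ids),
        ))
        for m in final_clusters[-1].member_ids:
            labels[m] = c.id
    # remainder assignments already in labels; add them to cluster membership
    by_cid = {c.id: c for c in final_clusters}
    for tid in remainder_ids:
        cid = int(labels[int(tid)])
        if cid != OUTLIER:
            by_cid[cid].member_ids.append(int(tid))
    for c in final_clusters:
        c.member_ids = sorted(set(c.member_ids))

    outlier_ids = set(int(i) for i in np.flatnonzero(labels == OUTLIER))
    try:  # pydantic models iterate as (field, value) pairs
        snapshot = {kk: str(vv) for kk, vv in dict(config).items()}
    except TypeError:
        snapshot = {kk: str(vv) for kk, vv in vars(config).items()}
    result = ClusteringResult(
        clusters=final_clusters,
        outlier_ids=outlier_ids,
        labels=labels,
        tree=tree,
        config=snapshot,
        seed=config.seed,
    )
    if atlas is not None and getattr(config, "atlas_post_merge", True) \
            and not getattr(config, "atlas_neutral", False) and final_clusters:
        from .atlas import post_merge_by_atlas

        post_merge_by_atlas(result, dataset, atlas)
    logger.info("run_catser: %d clusters, %d outliers of %d tracts",
                len(result.clusters), len(result.outlier_ids), n_total)
    return result
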