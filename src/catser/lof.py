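"""Local Outlier Factors from a precomputed similarity matrix.

Density-based outlier scores in the sense of Breunig et al.: for each tract
the k nearest neighbours are found in the precomputed distance matrix, the
local reachability density (LRD) is estimated from reachability distances,
and the LOF is the ratio of the mean neighbour LRD to the tract's own LRD.
Tracts deep inside a cluster score approximately 1; isolated tracts score
well above 1.

Neighbour sets here contain exactly k members with ties broken toward the
lower tract id, which keeps every downstream computation deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

#: enough neighbours for a statistically stable density estimate, but no
#: more than the smallest expected cluster size.
DEFAULT_K = 15


@dataclass
class LofResult:
    k: int
    lof: np.ndarray         # per-tract LOF, finite and > 0
    k_distance: np.ndarray  # distance to the k-th neighbour
    lrd: np.ndarray         # local reachability density (may be inf for duplicates)
    neighbors: np.ndarray   # (n, k) neighbour ids, ascending by (distance, id)


def k_nearest(m: SimilarityMatrix, i: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """The k most similar tracts to ``i``: (ids, distances).

    Sorted ascending by (distance, id); ties go to the lower id.
    """
    if not 1 <= k <= m.n - 1:
        raise ValueError(f"k={k} out of range for n={m.n}")
    d = m.row(i).copy()
    ids = np.delete(np.arange(m.n), i)
    d = np.delete(d, i)
    order = np.lexsort((ids, d))[:k]
    return ids[order], d[order]


def compute_lofs(m: SimilarityMatrix, k: int = DEFAULT_K) -> LofResult:
    """Standard LOF over all tracts of the similarity matrix.

    Zero-distance duplicates yield infinite LRDs; whenever a tract and all
    of its neighbours have infinite LRD the LOF is defined as 1 (a dense
    stack of identical tracts is maximally non-outlying).
    """
    n = m.n
    if n <= k:
        raise ValueError(f"need more tracts than k (n={n}, k={k})")
    dense = m.to_dense()
    ids_grid = np.broadcast_to(np.arange(n), (n, n))
    # sort each row by (distance, id), skipping self (always first: d=0, tie->lowest id
    # could pick another zero-distance duplicate, so drop column of self explicitly)
    neigh = np.empty((n, k), dtype=np.int64)
    kdist = np.empty(n)
    for i in range(n):
        d = dense[i]
        other = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        order = np.lexsort((other, d[other]))[:k]
        neigh[i] = other[order]
        kdist[i] = d[other[order[-1]]]
    # reachability distance reach(i -> j) = max(kdist[j], d(i, j))
    reach = np.maximum(kdist[neigh], dense[np.arange(n)[:, None], neigh])
    mean_reach = reach.mean(axis=1)
    with np.errstate(divide="ignore"):
        lrd = np.where(mean_reach > 0.0, 1.0 / mean_reach, np.inf)
    LOF_CAP = 1e12  # finite stand-in where a duplicate neighbour makes the ratio diverge
    lof = np.empty(n)
    for i in range(n):
        if np.isinf(lrd[i]):
            # duplicates: self and neighbours at distance 0 -> by convention LOF = 1
            lof[i] = 1.0
        else:
            nb_lrd = lrd[neigh[i]]
            if np.any(np.isinf(nb_lrd)):
                lof[i] = LOF_CAP
            else:
                lof[i] = float(nb_lrd.mean() * mean_reach[i])
    lof = np.clip(lof, np.finfo(float).tiny, LOF_CAP)
    return LofResult(k=k, lof=lof, k_distance=kdist, lrd=lrd, neighbors=neigh)
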