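"""Tract similarity measures and the precomputed triangular similarity matrix.

Four measures are provided, all satisfying symmetry, non-negativity and
reflexivity:

* TCD  — Euclidean distance between the length-weighted tract centroids (mm);
* TOS  — angle between the endpoint-orientation vectors (degrees);
* HD   — two-sided point-set Hausdorff distance (mm, no segment interpolation);
* CD   — combined distance: weighted sum of normalized location, orientation,
  partial-overlap and shape components, minimized over tract reversal so that
  a tract and its reverse are identical.

The CD components in mm are mapped into [0, 1) with the bounded monotone map
d -> d / (d + c); the scale constants are configurable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .tracts import (
    Tract,
    TractDataset,
    arc_positions,
    endpoint_orientation,
    resample_tract,
    tract_centroid,
)

logger = logging.getLogger("catser")

MEASURES = ("tcd", "tos", "hd", "cd")


# ---------------------------------------------------------------------------
# pairwise measures
# ---------------------------------------------------------------------------

def tcd(a: Tract, b: Tract) -> float:
    """Tract centroid distance in mm."""
    return float(np.linalg.norm(tract_centroid(a) - tract_centroid(b)))


def tos(a: Tract, b: Tract) -> float:
    """Tract orientation similarity: angle between endpoint orientations, degrees."""
    dot = float(np.dot(endpoint_orientation(a), endpoint_orientation(b)))
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))


def hausdorff(a: Tract, b: Tract) -> float:
    """Two-sided point-set Hausdorff distance in mm (exact, no interpolation)."""
    d = cdist(a.points, b.points)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def hausdorff_one_to_many(t: Tract, others: list[Tract]) -> np.ndarray:
    """Exact two-sided Hausdorff distances from one tract to many.

    One distance-matrix evaluation against the concatenated point sets with
    segmented min/max reductions; identical values to :func:`hausdorff`.
    """
    if not others:
        return np.empty(0)
    sizes = np.array([o.n_points for o in others])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    concat = np.vstack([o.points for o in others])
    D = cdist(t.points, concat)
    # forward side: for each other tract, max over t's points of the min distance
    side1 = np.minimum.reduceat(D, offsets, axis=1).max(axis=0)
    # backward side: max over the other tract's points of the min distance to t
    colmin = D.min(axis=0)
    side2 = np.maximum.reduceat(colmin, offsets)
    return np.maximum(side1, side2)


@dataclass(frozen=True)
class SubTractPair:
    """Equal-arc-length fragments produced by partial tract matching.

    Each fragment is a contiguous slice of its resampled source tract.
    """

    sub_a: Tract
    sub_b: Tract
    anchor_a: int
    anchor_b: int


def partial_match(a: Tract, b: Tract, n_resample: int = 20) -> SubTractPair:
    """Match possibly incomplete tracts around the closest resampled point pair.

    Both tracts are resampled to ``n_resample`` points; the globally closest
    point pair anchors the match, and sub-tracts of equal arc length extend
    from the anchors toward both ends, limited on each side by whichever
    tract runs out of arc length first.
    """
    if n_resample < 2:
        raise ValueError("n_resample must be >= 2")
    ra, rb = resample_tract(a, n_resample), resample_tract(b, n_resample)
    table = cdist(ra.points, rb.points)
    i, j = np.unravel_index(int(np.argmin(table)), table.shape)
    step_a = arc_positions(ra)[-1] / (n_resample - 1)
    step_b = arc_positions(rb)[-1] / (n_resample - 1)
    left = min(i * step_a, j * step_b)
    right = min((n_resample - 1 - i) * step_a, (n_resample - 1 - j) * step_b)
    # contiguous slices covering ~`left` mm before and ~`right` mm after anchor
    na_l = int(np.floor(left / step_a + 1e-9)) if step_a > 0 else i
    nb_l = int(np.floor(left / step_b + 1e-9)) if step_b > 0 else j
    na_r = int(np.floor(right / step_a + 1e-9)) if step_a > 0 else n_resample - 1 - i
    nb_r = int(np.floor(right / step_b + 1e-9)) if step_b > 0 else n_resample - 1 - j
    sa = ra.points[max(i - na_l, 0): i + na_r + 1]
    sb = rb.points[max(j - nb_l, 0): j + nb_r + 1]
    if len(sa) < 2:
        sa = ra.points[max(i - 1, 0): i + 2]
    if len(sb) < 2:
        sb = rb.points[max(j - 1, 0): j + 2]
    return SubTractPair(Tract(sa, a.id), Tract(sb, b.id), int(i), int(j))


def _turning_angles(points: np.ndarray) -> np.ndarray:
    """Unsigned turning angle (degrees) at each interior vertex."""
    seg = np.diff(points, axis=0)
    norm = np.linalg.norm(seg, axis=1)
    norm[norm == 0.0] = 1.0
    u = seg / norm[:, None]
    dots = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def shape_distance(pair: SubTractPair, n_points: int = 12) -> float:
    """Rigid-motion-invariant shape dissimilarity of the matched fragments.

    The fragments are resampled to a common point count and described by
    their sequences of turning angles; the distance is the mean absolute
    angle difference scaled into [0, 1].  Congruent fragments score 0.
    """
    if pair.sub_a.n_points < 3 or pair.sub_b.n_points < 3:
        logger.warning("shape_distance: fragment with <3 points, shape undefined -> 0")
        return 0.0
    n = max(3, n_points)
    ang_a = _turning_angles(resample_tract(pair.sub_a, n).points)
    ang_b = _turning_angles(resample_tract(pair.sub_b, n).points)
    return float(np.mean(np.abs(ang_a - ang_b)) / 180.0)


@dataclass(frozen=True)
class CDParams:
    """Weights and normalization constants of the combined distance."""

    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    c_tcd: float = 20.0      # mm scale of the centroid component
    c_partial: float = 10.0  # mm scale of the partial-match centroid component
    n_resample: int = 20

    def __post_init__(self):
        if any(w < 0 for w in self.weights):
            raise ValueError("CD weights must be nonnegative")
        if self.c_tcd <= 0 or self.c_partial <= 0:
            raise ValueError("CD normalization constants must be positive")


def _bounded(d: float, c: float) -> float:
    return d / (d + c)


def _one_sided_cd(a: Tract, b: Tract, p: CDParams) -> float:
    w1, w2, w3, w4 = p.weights
    total = 0.0
    if w1:
        total += w1 * _bounded(tcd(a, b), p.c_tcd)
    if w2:
        total += w2 * (tos(a, b) / 180.0)
    if w3 or w4:
        pair = partial_match(a, b, p.n_resample)
        if w3:
            total += w3 * _bounded(tcd(pair.sub_a, pair.sub_b), p.c_partial)
        if w4:
            total += w4 * shape_distance(pair)
    return total


def combined_distance(a: Tract, b: Tract, params: CDParams | None = None) -> float:
    """Combined distance, minimized over reversal of the second tract."""
    p = params or CDParams()
    return min(_one_sided_cd(a, b, p), _one_sided_cd(a, b.reversed(), p))


# ---------------------------------------------------------------------------
# the similarity matrix
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Dense symmetric pairwise-distance store for a tract sample.

    Stored as the strict lower triangle in row-major (condensed) order;
    ``get``/``row`` expose a symmetric view with zero diagonal.
    """

    n: int
    values: np.ndarray  # condensed, length n*(n-1)/2
    measure_tag: str

    def __post_init__(self):
        expected = self.n * (self.n - 1) // 2
        if self.values.shape != (expected,):
            raise ValueError("condensed length does not match n")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("similarity matrix entries must be finite and >= 0")

    def _idx(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        return self.n * i - (i * (i + 1)) // 2 + (j - i - 1)

    def get(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        return float(self.values[self._idx(i, j)])

    def to_dense(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values)

    def row(self, i: int) -> np.ndarray:
        return self.to_dense()[i]

    def submatrix(self, ids: np.ndarray) -> np.ndarray:
        return self.to_dense()[np.ix_(ids, ids)]

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.values.astype(np.float64).tofile(path)
        sidecar = {
            "n": self.n,
            "measure_tag": self.measure_tag,
            "checksum": hashlib.sha256(self.values.tobytes()).hexdigest(),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityMatrix":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        values = np.fromfile(path, dtype=np.float64)
        if hashlib.sha256(values.tobytes()).hexdigest() != meta["checksum"]:
            raise IOError(f"checksum mismatch loading {path}")
        return cls(int(meta["n"]), values, meta["measure_tag"])


def pairwise_measure(measure: str, cd_params: CDParams | None = None):
    """Return the pairwise callable for a measure tag."""
    if measure == "tcd":
        return tcd
    if measure == "tos":
        return tos
    if measure == "hd":
        return hausdorff
    if measure == "cd":
        p = cd_params or CDParams()
        return lambda a, b: combined_distance(a, b, p)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def _row_entries(tracts, i, fn) -> np.ndarray:
    return np.array([fn(tracts[i], tracts[j]) for j in range(i)], dtype=np.float64)


def compute_similarity_matrix(
    sample: TractDataset | list[Tract],
    measure: str = "hd",
    n_workers: int = 1,
    cd_params: CDParams | None = None,
) -> SimilarityMatrix:
    """Precompute the triangular pairwise distance matrix for a sample.

    The lower triangle is split into contiguous row blocks; each worker owns
    every entry of its rows, so the result is bit-identical for any worker
    count.  Centroid and orientation measures are evaluated in closed
    vectorized form.
    """
    tracts = list(sample)
    n = len(tracts)
    if n == 0:
        raise ValueError("empty sample")
    if measure == "tcd":
        cents = np.array([tract_centroid(t) for t in tracts])
        dense = cdist(cents, cents)
        values = dense[np.triu_indices(n, k=1)]
    elif measure == "tos":
        vecs = np.array([endpoint_orientation(t) for t in tracts])
        gram = np.clip(vecs @ vecs.T, -1.0, 1.0)
        dense = np.degrees(np.arccos(gram))
        np.fill_diagonal(dense, 0.0)
        values = dense[np.triu_indices(n, k=1)]
    else:
        if measure == "hd":
            row_fn = lambda i: hausdorff_one_to_many(tracts[i], tracts[:i])
        else:
            fn = pairwise_measure(measure, cd_params)
            row_fn = lambda i: _row_entries(tracts, i, fn)
        rows: list[np.ndarray | None] = [None] * n
        if n_workers <= 1:
            for i in range(n):
                rows[i] = row_fn(i)
        else:
            with ThreadPoolExecutor(max_workers=n_workers) as pool:
                futs = {pool.submit(row_fn, i): i for i in range(n)}
                for fut, i in futs.items():
                    rows[i] = fut.result()
        # condensed upper-triangular order from per-row lower entries
        dense = np.zeros((n, n))
        for i in range(n):
            dense[i, :i] = rows[i]
        dense = dense + dense.T
        values = dense[np.triu_indices(n, k=1)]
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise FloatingPointError(f"non-finite distance at condensed index {bad}")
    return SimilarityMatrix(n, np.ascontiguousarray(values), measure)
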