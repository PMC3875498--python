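"""Streamline data model, geometry primitives and file I/O.

A fiber tract is an ordered polyline of at least two points in millimetre
world coordinates.  All geometry in this package works in that one frame;
voxel-order conventions of on-disk formats are resolved at the I/O boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("catser")

FORMATS = ("trk", "tck", "jsonl")


class TractError(ValueError):
    """Raised for degenerate tract geometry."""


@dataclass(frozen=True)
class Tract:
    """An ordered 3D polyline in mm with an integer identifier.

    Consecutive duplicate points (zero-length segments) are collapsed on
    construction; at least two distinct points must remain.
    """

    points: np.ndarray
    id: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise TractError(f"tract {self.id}: need an (n>=2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise TractError(f"tract {self.id}: non-finite coordinates")
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
        pts = pts[keep]
        if len(pts) < 2:
            raise TractError(f"tract {self.id}: fewer than two distinct points")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def reversed(self) -> "Tract":
        return Tract(self.points[::-1].copy(), self.id)


@dataclass
class TractDataset:
    """A list of tracts with dense ids 0..N-1 plus provenance metadata."""

    tracts: list[Tract]
    space_tag: str = "native"
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tracts]
        if ids != list(range(len(ids))):
            raise ValueError("tract ids must be dense 0..N-1")

    def __len__(self) -> int:
        return len(self.tracts)

    def __iter__(self):
        return iter(self.tracts)

    def __getitem__(self, i: int) -> Tract:
        return self.tracts[i]

    @classmethod
    def from_arrays(cls, arrays: Iterable[np.ndarray], **kw) -> "TractDataset":
        return cls([Tract(a, i) for i, a in enumerate(arrays)], **kw)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def segment_lengths(t: Tract) -> np.ndarray:
    return np.linalg.norm(np.diff(t.points, axis=0), axis=1)


def tract_length(t: Tract) -> float:
    """Total arc length in mm (sum of segment Euclidean lengths)."""
    return float(segment_lengths(t).sum())


def tract_centroid(t: Tract) -> np.ndarray:
    """Length-weighted centre of gravity of the polyline.

    Each segment contributes its midpoint weighted by its length, so the
    centroid is invariant under resampling of the same geometry and is not
    biased by unevenly distributed vertices.
    """
    lengths = segment_lengths(t)
    total = lengths.sum()
    if total <= 0.0:
        raise TractError(f"tract {t.id}: zero total length")
    midpoints = 0.5 * (t.points[:-1] + t.points[1:])
    return (midpoints * lengths[:, None]).sum(axis=0) / total


def endpoint_orientation(t: Tract, closed_loop_fallback: bool = True) -> np.ndarray:
    """Unit vector from the first to the last point.

    For closed loops (coincident endpoints) the orientation is undefined;
    we fall back to the first-to-middle-point direction and log the event,
    unless ``closed_loop_fallback`` is disabled, in which case an error is
    raised.
    """
    v = t.points[-1] - t.points[0]
    n = np.linalg.norm(v)
    if n == 0.0:
        if not closed_loop_fallback:
            raise TractError(f"tract {t.id}: coincident endpoints")
        logger.warning("tract %d: closed loop, orientation from first-to-middle point", t.id)
        v = t.points[len(t.points) // 2] - t.points[0]
        n = np.linalg.norm(v)
        if n == 0.0:
            raise TractError(f"tract {t.id}: degenerate orientation")
    return v / n


def arc_positions(t: Tract) -> np.ndarray:
    """Cumulative arc length at each vertex (starts at 0)."""
    return np.concatenate([[0.0], np.cumsum(segment_lengths(t))])


def resample_tract(t: Tract, n: int) -> Tract:
    """Resample to ``n`` points equally spaced by arc length.

    Endpoints are preserved exactly.
    """
    if n < 2:
        raise ValueError("resample needs n >= 2")
    pos = arc_positions(t)
    target = np.linspace(0.0, pos[-1], n)
    new = np.column_stack([np.interp(target, pos, t.points[:, d]) for d in range(3)])
    new[0] = t.points[0]
    new[-1] = t.points[-1]
    return Tract(new, t.id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown tract format {fmt!r}; expected one of {FORMATS}")
    return fmt


def load_tracts(
    path: str | Path,
    format: str | None = None,
    space_tag: str = "native",
    min_length_mm: float | None = None,
) -> TractDataset:
    """Load streamlines from TRK, TCK or the JSON-lines dialect.

    TRK/TCK coordinates are mapped to mm world (RAS) space via the file's
    affine.  Tracts with fewer than two distinct points are dropped with a
    logged count, as are tracts shorter than ``min_length_mm`` when given.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    raw: list[np.ndarray] = []
    if fmt == "jsonl":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                raw.append(np.asarray(rec["points"], dtype=np.float64))
    else:
        import nibabel as nib

        tf = nib.streamlines.load(str(path))  # applies affine_to_rasmm
        raw = [np.asarray(s, dtype=np.float64) for s in tf.streamlines]

    tracts: list[Tract] = []
    dropped = 0
    for arr in raw:
        try:
            t = Tract(arr, len(tracts))
        except TractError:
            dropped += 1
            continue
        if min_length_mm is not None and tract_length(t) < min_length_mm:
            dropped += 1
            continue
        tracts.append(t)
    if dropped:
        logger.warning("load_tracts(%s): dropped %d degenerate/short tracts", path, dropped)
    logger.info("load_tracts(%s): %d tracts", path, len(tracts))
    return TractDataset(tracts, space_tag=space_tag, provenance=f"{path}:{fmt}")


def save_tracts(dataset: TractDataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset to TRK, TCK or JSON-lines; round-trips with load."""
    if len(dataset) == 0:
        raise ValueError("refusing to save an empty dataset")
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for t in dataset:
                fh.write(json.dumps({"id": t.id, "points": t.points.tolist()}) + "\n")
    else:
        import nibabel as nib
        from nibabel.streamlines import Tractogram

        tg = Tractogram([t.points for t in dataset], affine_to_rasmm=np.eye(4))
        if fmt == "trk":
            # give the TRK header a voxel grid large enough to hold the data
            mx = np.max([t.points.max(axis=0) for t in dataset], axis=0)
            hdr = {
                "voxel_sizes": np.ones(3, dtype=np.float32),
                "dimensions": np.maximum(np.ceil(np.abs(mx)) + 2, 1).astype(np.int16),
                "voxel_to_rasmm": np.eye(4, dtype=np.float32),
                "voxel_order": "RAS",
            }
            nib.streamlines.save(tg, str(path), header=hdr)
        else:
            nib.streamlines.save(tg, str(path))
    logger.info("save_tracts(%s): %d tracts", path, len(dataset))
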