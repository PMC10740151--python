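"""Sparse displacement estimation by exhaustive NCC block matching.

For each registration point a ``(2B+1)`` block of the floating image is
compared, at every integer offset within a ``(2W+1)`` search window, against
the fixed image; the offset maximizing normalized cross-correlation becomes
the point's displacement and the (clamped) NCC its confidence weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import ImageVolume, PointSet, world_to_voxel

__all__ = [
    "BlockMatchConfig",
    "SparseDisplacementField",
    "ncc",
    "match_point",
    "block_match_all",
]


@dataclass
class BlockMatchConfig:
    block_radius: tuple = (1, 1, 1)
    window_radius: tuple = (5, 5, 5)

    def __post_init__(self):
        b = tuple(int(x) for x in self.block_radius)
        w = tuple(int(x) for x in self.window_radius)
        if any(x < 1 for x in b) or any(x < 1 for x in w):
            raise ValueError("block and window radii must be >= 1")
        self.block_radius, self.window_radius = b, w


@dataclass
class SparseDisplacementField:
    """Registration points with block displacements D and confidences (diag S)."""

    points: PointSet
    displacements: np.ndarray   # (n, 3) mm
    confidences: np.ndarray     # (n,) in [0, 1]

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(-1, 3)
        self.confidences = np.asarray(self.confidences, dtype=float).reshape(-1)
        n = len(self.points)
        if len(self.displacements) != n or len(self.confidences) != n:
            raise ValueError("points, displacements, confidences must be equal length")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")
        if self.confidences.size and (
            self.confidences.min() < 0 or self.confidences.max() > 1
        ):
            raise ValueError("confidences must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, idx) -> "SparseDisplacementField":
        return SparseDisplacementField(
            PointSet(self.points.points[idx]),
            self.displacements[idx],
            self.confidences[idx],
        )


def ncc(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Pearson normalized cross-correlation of two equally shaped blocks.

    Returns NaN (the "undefined" sentinel) when either block has zero variance.
    """
    a = np.asarray(block_a, dtype=float)
    b = np.asarray(block_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("blocks need at least 2 voxels")
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def _offsets(window_radius) -> np.ndarray:
    rng = [np.arange(-w, w + 1) for w in window_radius]
    return np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)


def match_point(
    floating: ImageVolume,
    fixed: ImageVolume,
    s,
    cfg: BlockMatchConfig,
) -> tuple[np.ndarray, float]:
    """Best-NCC displacement (mm) and confidence for one registration point.

    Exhaustive search over all ``prod(2W+1)`` integer voxel offsets.  Ties are
    broken by smallest displacement norm, then lexicographic offset; a flat
    block (undefined NCC everywhere) returns zero displacement, confidence 0.
    Raises ``ValueError`` if the block or window does not fit its grid.
    """
    B = np.asarray(cfg.block_radius)
    W = np.asarray(cfg.window_radius)
    v = np.round(world_to_voxel(np.asarray(s, dtype=float), floating)).astype(int)
    shp_f = np.asarray(floating.shape)
    shp_g = np.asarray(fixed.shape)
    if np.any(v - B < 0) or np.any(v + B >= shp_f):
        raise ValueError(f"block around voxel {tuple(v)} exceeds floating grid")
    if np.any(v - W - B < 0) or np.any(v + W + B >= shp_g):
        raise ValueError(f"search window around voxel {tuple(v)} exceeds fixed grid")

    block = np.asarray(
        floating.data[
            v[0] - B[0] : v[0] + B[0] + 1,
            v[1] - B[1] : v[1] + B[1] + 1,
            v[2] - B[2] : v[2] + B[2] + 1,
        ],
        dtype=float,
    )
    region = np.asarray(
        fixed.data[
            v[0] - W[0] - B[0] : v[0] + W[0] + B[0] + 1,
            v[1] - W[1] - B[1] : v[1] + W[1] + B[1] + 1,
            v[2] - W[2] - B[2] : v[2] + W[2] + B[2] + 1,
        ],
        dtype=float,
    )
    scores = _ncc_window_scores(block, region)
    offs = _offsets(W)
    valid = np.isfinite(scores)
    if not valid.any():
        return np.zeros(3), 0.0
    best = np.nanmax(scores)
    ties = np.flatnonzero(valid & (scores == best))
    # smallest displacement norm, then lexicographic offset
    key = np.lexsort((offs[ties, 2], offs[ties, 1], offs[ties, 0],
                      np.sum(offs[ties] ** 2, axis=1)))
    off = offs[ties[key[0]]]
    disp = off * np.asarray(fixed.spacing)
    return disp, float(np.clip(best, 0.0, 1.0))


def _ncc_window_scores(block: np.ndarray, region: np.ndarray) -> np.ndarray:
    """NCC of ``block`` against every block-sized window of ``region``.

    Returns a flat array over offsets in lexicographic (ix, iy, iz) order;
    undefined correlations are NaN.
    """
    wins = sliding_window_view(region, block.shape)
    n = block.size
    w = wins.reshape(-1, n)
    b = block.ravel() - block.mean()
    nb = np.linalg.norm(b)
    if nb == 0.0:
        return np.full(w.shape[0], np.nan)
    wm = w.mean(axis=1, keepdims=True)
    wc = w - wm
    nw = np.linalg.norm(wc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (wc @ b) / (nw * nb)
    scores[nw == 0.0] = np.nan
    return scores


def block_match_all(
    floating: ImageVolume,
    fixed: ImageVolume,
    points: PointSet,
    cfg: BlockMatchConfig,
) -> tuple[SparseDisplacementField, list]:
    """Apply :func:`match_point` to every point.

    Out-of-bounds points are skipped with a recorded ``(index, reason)``;
    flat-block points are kept with confidence 0.
    """
    disps, confs, kept, skipped = [], [], [], []
    for i, p in enumerate(points.points):
        try:
            d, c = match_point(floating, fixed, p, cfg)
        except ValueError as exc:
            skipped.append((i, str(exc)))
            continue
        kept.append(i)
        disps.append(d)
        confs.append(c)
    fld = SparseDisplacementField(
        PointSet(points.points[kept] if kept else np.zeros((0, 3))),
        np.asarray(disps).reshape(-1, 3),
        np.asarray(confs, dtype=float),
    )
    return fld, skipped
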