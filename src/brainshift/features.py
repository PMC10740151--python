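"""Registration-point selection by local intensity variance, and Canny edges."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.feature import canny

from .core import ImageVolume, PointSet, voxel_to_world

__all__ = ["FeatureConfig", "select_registration_points", "canny_edge_points"]


@dataclass
class FeatureConfig:
    selection_fraction: float = 0.05
    block_radius: tuple = (1, 1, 1)
    mask: np.ndarray | None = None     # boolean array matching the volume grid
    min_spacing: float | None = None   # mm; greedy pruning distance
    margin: tuple | None = None        # candidate margin, defaults to block_radius

    def __post_init__(self):
        if not (0.0 < self.selection_fraction <= 1.0):
            raise ValueError("selection_fraction must be in (0, 1]")
        br = tuple(int(b) for b in self.block_radius)
        if any(b < 1 for b in br):
            raise ValueError("block_radius components must be >= 1")
        self.block_radius = br
        if self.margin is not None:
            self.margin = tuple(int(m) for m in self.margin)


def local_variance(data: np.ndarray, radius: tuple) -> np.ndarray:
    """Variance over the (2r+1)^3 neighborhood of every voxel."""
    size = tuple(2 * r + 1 for r in radius)
    x = np.asarray(data, dtype=float)
    m = uniform_filter(x, size=size, mode="constant")
    m2 = uniform_filter(x * x, size=size, mode="constant")
    return np.maximum(m2 - m * m, 0.0)


def select_registration_points(vol: ImageVolume, cfg: FeatureConfig) -> PointSet:
    """Top-variance voxels as world points, ranked by variance descending.

    Candidates are in-mask voxels at least ``margin`` voxels from every grid
    face (default margin = block radius, so the variance block fits).  Exactly
    ``floor(selection_fraction * N_candidates)`` points are returned, fewer if
    not enough candidates have strictly positive variance; zero-variance voxels
    are never selected.  Ties are broken by lexicographic voxel index.
    """
    shape = np.asarray(vol.shape)
    margin = np.asarray(cfg.margin if cfg.margin is not None else cfg.block_radius)
    if np.any(shape <= 2 * margin):
        raise ValueError("margin leaves no candidate voxels")
    if cfg.mask is not None:
        mask = np.asarray(cfg.mask, dtype=bool)
        if mask.shape != vol.data.shape:
            raise ValueError("mask geometry does not match volume")
        if not mask.any():
            raise ValueError("mask is empty")
    else:
        mask = np.ones(vol.data.shape, dtype=bool)

    var = local_variance(vol.data, cfg.block_radius)
    cand = np.zeros_like(mask)
    sl = tuple(slice(m, n - m) for m, n in zip(margin, shape))
    cand[sl] = True
    cand &= mask

    flat_idx = np.flatnonzero(cand)
    n_cand = flat_idx.size
    if n_cand == 0:
        raise ValueError("no candidate voxels (mask/margin too restrictive)")
    k = int(np.floor(cfg.selection_fraction * n_cand))
    v = var.ravel()[flat_idx]
    # stable rank: variance descending, then lexicographic voxel index
    order = np.lexsort((flat_idx, -v))
    order = order[v[order] > 0.0][:k]
    chosen = flat_idx[order]
    vox = np.stack(np.unravel_index(chosen, vol.data.shape), axis=1)
    pts = voxel_to_world(vox, vol)

    if cfg.min_spacing is not None and len(pts) > 1:
        pts = _prune_by_spacing(pts, cfg.min_spacing)
    return PointSet(pts)


def _prune_by_spacing(pts: np.ndarray, min_spacing: float) -> np.ndarray:
    kept: list[np.ndarray] = []
    arr = np.empty((0, 3))
    for p in pts:
        if len(kept) == 0 or np.min(np.linalg.norm(arr - p, axis=1)) >= min_spacing:
            kept.append(p)
            arr = np.asarray(kept)
    return np.asarray(kept)


def canny_edge_points(
    vol: ImageVolume,
    sigma: float = 1.0,
    low_threshold: float | None = None,
    high_threshold: float | None = None,
    axis: int = 2,
) -> PointSet:
    """Slice-wise Canny edge voxels of a volume, returned as world points.

    The detector runs on every 2D slice perpendicular to ``axis`` (axial plane
    by default) and is deterministic for identical inputs.
    """
    data = np.asarray(vol.data, dtype=float)
    edges = np.zeros(data.shape, dtype=bool)
    for i in range(data.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = i
        plane = data[tuple(sl)]
        if plane.max() == plane.min():
            continue
        edges[tuple(sl)] = canny(
            plane, sigma=sigma, low_threshold=low_threshold,
            high_threshold=high_threshold,
        )
    vox = np.argwhere(edges)
    return PointSet(voxel_to_world(vox, vol).reshape(-1, 3))
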