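"""Adaptive registration by incremental warping + remeshing, and
registration-point-aware mesh-sizing metrics (isotropic k-NN spacing,
minimum-volume enclosing ellipsoids, anisotropic SPD metric fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .block_matching import BlockMatchConfig
from .core import (
    DenseDeformationField,
    ImageVolume,
    LabelVolume,
    TetrahedralMesh,
    compose_fields,
    warp_image,
    zero_field_like,
)
from .features import FeatureConfig
from .fem import bcc_mesh_from_labels
from .pbnrr import PBNRRConfig, RegistrationResult, pbnrr_register

__all__ = [
    "ANRRConfig",
    "SizingField",
    "element_quality",
    "anrr_register",
    "isotropic_sizing",
    "min_enclosing_ellipsoid",
    "anisotropic_metric",
    "anisotropic_sizing_field",
    "export_metric_field",
    "read_metric_field",
]


@dataclass
class ANRRConfig:
    n_inc: int = 5
    sliver_dihedral_deg: float = 5.0
    k: int = 5                   # neighbor count for sizing
    inflation: float = 1.0       # ellipsoid enlargement constant a
    edge_length: float = 6.0     # BCC remeshing edge length, mm
    background: float = 0.0      # fill intensity for intermediate warps
    pbnrr: PBNRRConfig = dfield(default_factory=PBNRRConfig)
    feature: FeatureConfig = dfield(default_factory=FeatureConfig)
    match: BlockMatchConfig = dfield(default_factory=BlockMatchConfig)
    max_retries: int = 2         # per-increment quality retries (halved step)

    def __post_init__(self):
        if self.n_inc < 1:
            raise ValueError("n_inc must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.inflation < 1.0:
            raise ValueError("inflation constant must be >= 1")


@dataclass
class SizingField:
    """Per-vertex scalar spacing (mm) or 3x3 SPD metric tensors."""

    scalars: np.ndarray | None = None      # (n,)
    tensors: np.ndarray | None = None      # (n, 3, 3)

    def __post_init__(self):
        if (self.scalars is None) == (self.tensors is None):
            raise ValueError("provide exactly one of scalars or tensors")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=float).ravel()
            if np.any(self.scalars <= 0):
                raise ValueError("scalar spacings must be > 0")
        else:
            self.tensors = np.asarray(self.tensors, dtype=float)
            if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
                raise ValueError("tensors must have shape (n, 3, 3)")
            for M in self.tensors:
                _check_spd(M)

    def __len__(self) -> int:
        arr = self.scalars if self.scalars is not None else self.tensors
        return len(arr)


def _check_spd(M: np.ndarray) -> None:
    if not np.allclose(M, M.T, atol=1e-9 * max(1.0, np.abs(M).max())):
        raise ValueError("metric tensor is not symmetric")
    w = np.linalg.eigvalsh(0.5 * (M + M.T))
    if w.min() <= 0:
        raise ValueError("metric tensor is not positive definite")


# ---------------------------------------------------------------------------
# element quality
# ---------------------------------------------------------------------------

def element_quality(verts) -> tuple[float, float]:
    """Signed volume (mm^3) and minimum dihedral angle (degrees) of a tet."""
    v = np.asarray(verts, dtype=float).reshape(4, 3)
    e = v[1:] - v[:1]
    vol = float(np.linalg.det(e) / 6.0)
    angles = []
    for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
        k, l = [m for m in range(4) if m not in (i, j)]
        edge = v[j] - v[i]
        n1 = np.cross(edge, v[k] - v[i])
        n2 = np.cross(edge, v[l] - v[i])
        den = np.linalg.norm(n1) * np.linalg.norm(n2)
        if den == 0.0:
            angles.append(0.0)
            continue
        c = float(np.clip(np.dot(n1, n2) / den, -1.0, 1.0))
        angles.append(float(np.degrees(np.arccos(c))))
    return vol, float(min(angles))


def _mesh_quality_ok(mesh: TetrahedralMesh, U: np.ndarray, thresh_deg: float) -> bool:
    moved = mesh.vertices + U
    for t in range(mesh.n_tets):
        vol, ang = element_quality(moved[mesh.tets[t]])
        if vol <= 0 or ang < thresh_deg:
            return False
    return True


# ---------------------------------------------------------------------------
# adaptive registration
# ---------------------------------------------------------------------------

def anrr_register(
    floating: ImageVolume,
    fixed: ImageVolume,
    labels: LabelVolume,
    materials,
    cfg: ANRRConfig,
) -> RegistrationResult:
    """Incremental warp-and-remesh registration.

    Each increment meshes the currently warped segmentation, runs one PBNRR
    pass against the fixed image, accepts ``1 / remaining`` of the solved
    field, composes it into the cumulative backward field, and warps the
    floating image and labels forward.  Increments whose accepted displacement
    would invert elements or create slivers are retried with a halved step;
    persistent failure raises with the offending increment.
    """
    cum = zero_field_like(fixed)
    warped = floating
    warped_labels = labels
    mesh = None
    last: RegistrationResult | None = None
    diagnostics = []
    for inc in range(cfg.n_inc):
        mesh = bcc_mesh_from_labels(warped_labels, cfg.edge_length)
        # features track the warped segmentation, not the original one
        feat = FeatureConfig(
            selection_fraction=cfg.feature.selection_fraction,
            block_radius=cfg.feature.block_radius,
            mask=np.asarray(warped_labels.data) > 0,
            min_spacing=cfg.feature.min_spacing,
            margin=cfg.feature.margin,
        )
        last = pbnrr_register(
            warped, fixed, mesh, materials, feat, cfg.match, cfg.pbnrr
        )
        frac = 1.0 / (cfg.n_inc - inc)
        accepted = frac
        for attempt in range(cfg.max_retries + 1):
            if _mesh_quality_ok(mesh, accepted * last.U, cfg.sliver_dihedral_deg):
                break
            accepted *= 0.5
        else:
            raise RuntimeError(
                f"increment {inc}: element quality still failing after "
                f"{cfg.max_retries} remeshing retries"
            )
        step = DenseDeformationField(
            accepted * last.dense_field.vectors,
            last.dense_field.spacing,
            last.dense_field.origin,
        )
        cum = compose_fields(step, cum)
        warped = warp_image(floating, cum, background=cfg.background)
        warped_labels = warp_image(labels, cum, order=0)
        diagnostics.append(
            {"increment": inc, "fraction": accepted,
             "n_tets": mesh.n_tets, "n_vertices": mesh.n_vertices}
        )
    assert last is not None
    return RegistrationResult(
        U=last.U,
        active_matches=last.active_matches,
        rejected_matches=last.rejected_matches,
        iterations=diagnostics,
        dense_field=cum,
        converged=last.converged,
        mesh=mesh,
        extras={"increments": diagnostics, "final_pass": last.extras},
    )


# ---------------------------------------------------------------------------
# sizing metrics
# ---------------------------------------------------------------------------

def isotropic_sizing(vertices, reg_points, k: int, eps: float = 1e-6) -> SizingField:
    """Scalar spacing per vertex: distance to the k-th nearest registration point."""
    pts = np.atleast_2d(np.asarray(reg_points, dtype=float))
    if len(pts) < k:
        raise ValueError(f"need at least k={k} registration points, got {len(pts)}")
    tree = cKDTree(pts)
    d, _ = tree.query(np.atleast_2d(vertices), k=k)
    d = d[:, -1] if k > 1 else np.asarray(d).ravel()
    return SizingField(scalars=np.maximum(d, eps))


def min_enclosing_ellipsoid(
    points, tol: float = 1e-4, max_iter: int = 10000
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-volume enclosing ellipsoid by the Khachiyan iteration.

    Returns ``(center, A)`` with every input point satisfying
    ``(p - c)^T A (p - c) <= 1 + O(tol)``.  Raises on degenerate (affinely
    dependent, e.g. coplanar) input.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = P.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} points, got {n}")
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-9 * max(1.0, np.abs(P).max())) < d:
        raise ValueError("degenerate point set (affinely dependent / coplanar)")
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n) lifted points
    u = np.full(n, 1.0 / n)
    dd = d + 1.0
    # Khachiyan ascent with Wolfe-Atwood away steps (linear convergence)
    for _ in range(max_iter):
        X = Q @ (u[:, None] * Q.T)
        M = np.einsum("ij,jk,ki->i", Q.T, np.linalg.inv(X), Q)
        j_add = int(np.argmax(M))
        support = u > 1e-12
        j_away = int(np.flatnonzero(support)[np.argmin(M[support])])
        gap_add = M[j_add] - dd
        gap_away = dd - M[j_away]
        if gap_add <= tol * dd and gap_away <= tol * dd:
            break
        if gap_add >= gap_away:
            j, mj = j_add, M[j_add]
            step = (mj - dd) / (dd * (mj - 1.0))
        else:
            j, mj = j_away, M[j_away]
            step = max((mj - dd) / (dd * (mj - 1.0)),
                       -u[j] / (1.0 - u[j]))
        u *= 1.0 - step
        u[j] += step
        u = np.maximum(u, 0.0)
        u /= u.sum()
    c = P.T @ u
    cov = (P.T * u) @ P - np.outer(c, c)
    A = np.linalg.inv(cov) / d
    A = 0.5 * (A + A.T)
    # normalize so every point is inside (A stays within the tol envelope)
    q = np.einsum("ij,jk,ik->i", P - c, A, P - c)
    A /= max(float(q.max()), 1e-300)
    return c, A


def anisotropic_metric(
    vertex, reg_points, k: int, a: float = 1.0,
    tol: float = 1e-4,
) -> tuple[np.ndarray, bool]:
    """SPD sizing tensor at a vertex from its k nearest registration points.

    The k neighbors are reflected through the vertex (2k points), the
    minimum-volume enclosing ellipsoid of the union is computed (centered at
    the vertex by symmetry), and its semi-axes are inflated by the constant
    ``a``; the returned matrix is the metric of the inflated ellipsoid.
    Degenerate neighbor configurations fall back to the isotropic spacing
    (second return value True).
    """
    v = np.asarray(vertex, dtype=float).reshape(3)
    pts = np.atleast_2d(np.asarray(reg_points, dtype=float))
    if len(pts) < k:
        raise ValueError(f"need at least k={k} registration points")
    tree = cKDTree(pts)
    _, idx = tree.query(v, k=k)
    nb = pts[np.atleast_1d(idx)]
    cloud = np.vstack([nb, 2.0 * v - nb])
    try:
        _, A = min_enclosing_ellipsoid(cloud, tol=tol)
    except (ValueError, np.linalg.LinAlgError):
        r = float(np.linalg.norm(nb[-1] - v)) if k > 1 else float(
            np.linalg.norm(nb[0] - v)
        )
        r = max(r, 1e-6) * a
        return np.eye(3) / r**2, True
    # inflating semi-axes by a divides the metric by a^2
    return A / a**2, False


def anisotropic_sizing_field(
    mesh: TetrahedralMesh, reg_points, k: int, a: float = 1.0
) -> tuple[SizingField, list[int]]:
    """Per-vertex anisotropic metric field; returns the fallback vertex ids too."""
    tensors = np.empty((mesh.n_vertices, 3, 3))
    fallbacks = []
    for i, v in enumerate(mesh.vertices):
        tensors[i], fb = anisotropic_metric(v, reg_points, k, a)
        if fb:
            fallbacks.append(i)
    return SizingField(tensors=tensors), fallbacks


# ---------------------------------------------------------------------------
# metric-field export (MEDIT .sol dialect)
# ---------------------------------------------------------------------------

def export_metric_field(mesh: TetrahedralMesh, field: SizingField, path) -> None:
    """Write a per-vertex metric file consumable by anisotropic meshers.

    Scalars are written as a 1-component solution; tensors as 6-component
    symmetric records (a11 a12 a22 a13 a23 a33, MEDIT order).  Non-SPD
    tensors are refused at write time.
    """
    if len(field) != mesh.n_vertices:
        raise ValueError(
            f"sizing field has {len(field)} entries for {mesh.n_vertices} vertices"
        )
    with open(path, "w") as fh:
        fh.write("MeshVersionFormatted 2\n\nDimension 3\n\nSolAtVertices\n")
        fh.write(f"{mesh.n_vertices}\n")
        if field.scalars is not None:
            fh.write("1 1\n")
            for s in field.scalars:
                fh.write(f"{s:.12g}\n")
        else:
            fh.write("1 3\n")
            for M in field.tensors:
                _check_spd(M)
                fh.write(
                    f"{M[0, 0]:.12g} {M[0, 1]:.12g} {M[1, 1]:.12g} "
                    f"{M[0, 2]:.12g} {M[1, 2]:.12g} {M[2, 2]:.12g}\n"
                )
        fh.write("\nEnd\n")


def read_metric_field(path) -> SizingField:
    """Read back a .sol-style metric file written by :func:`export_metric_field`."""
    tokens = Path(path).read_text().split()
    try:
        i = tokens.index("SolAtVertices")
    except ValueError as exc:
        raise ValueError(f"{path}: missing SolAtVertices section") from exc
    n = int(tokens[i + 1])
    ntypes, styp = int(tokens[i + 2]), int(tokens[i + 3])
    if ntypes != 1:
        raise ValueError(f"{path}: expected a single solution field")
    vals = [float(t) for t in tokens[i + 4 : i + 4 + n * (1 if styp == 1 else 6)]]
    if styp == 1:
        return SizingField(scalars=np.asarray(vals))
    if styp == 3:
        out = np.empty((n, 3, 3))
        for j in range(n):
            a11, a12, a22, a13, a23, a33 = vals[6 * j : 6 * j + 6]
            out[j] = [[a11, a12, a13], [a12, a22, a23], [a13, a23, a33]]
        return SizingField(tensors=out)
    raise ValueError(f"{path}: unsupported solution type {styp}")
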