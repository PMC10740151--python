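"""Image-to-mesh conversion (BCC lattice), P1 tetrahedral elasticity, and
match-to-vertex barycentric interpolation.

The global system couples the mesh stiffness matrix ``K`` (3n x 3n, built from
per-element ``V B^T C B`` matrices) with the sparse match data through the
interpolation matrix ``H`` (3 rows per located match point, barycentric
weights on vertex coordinate blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import (
    DenseDeformationField,
    LabelVolume,
    TetrahedralMesh,
    world_to_voxel,
)

__all__ = [
    "Material",
    "bcc_mesh_from_labels",
    "element_stiffness",
    "assemble_stiffness",
    "locate_points",
    "build_interpolation",
    "mesh_field_to_grid",
]


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: Young's modulus (Pa), Poisson ratio."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")


def _materials_dict(materials) -> dict[int, Material]:
    out = {}
    for k, v in materials.items():
        out[int(k)] = v if isinstance(v, Material) else Material(*v)
    return out


# ---------------------------------------------------------------------------
# BCC image-to-mesh conversion
# ---------------------------------------------------------------------------

def bcc_mesh_from_labels(labels: LabelVolume, edge_length: float) -> TetrahedralMesh:
    """Multi-tissue BCC tetrahedral mesh of the non-background label region.

    A body-centered cubic lattice (cube corners plus cell centers, cell side
    ``edge_length`` mm) covers the foreground bounding box; each face between
    two adjacent (padded) cells yields four tetrahedra spanning the two centers
    and a face edge.  Tets are kept and labelled by the label of the voxel
    nearest their centroid; all kept tets are positively oriented.
    """
    data = np.asarray(labels.data)
    fg = np.argwhere(data > 0)
    if fg.size == 0:
        raise ValueError("label volume has empty foreground")
    h = float(edge_length)
    if h <= 0:
        raise ValueError("edge_length must be > 0")
    sp_ = np.asarray(labels.spacing)
    lo = np.asarray(labels.origin) + (fg.min(axis=0) - 0.5) * sp_
    hi = np.asarray(labels.origin) + (fg.max(axis=0) + 0.5) * sp_
    ncell = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)

    # corner lattice (i,j,k) in [0, n]^3 and padded cell centers in [-1, n]^3
    cn = ncell + 1
    pc = ncell + 2  # padded cell count per axis

    def corner_id(i, j, k):
        return (i * cn[1] + j) * cn[2] + k

    def center_id(i, j, k):  # i,j,k are padded (shifted by +1) cell indices
        return cn.prod() + (i * pc[1] + j) * pc[2] + k

    ci, cj, ck = np.meshgrid(*[np.arange(n) for n in cn], indexing="ij")
    corners = lo + np.stack([ci, cj, ck], axis=-1).reshape(-1, 3) * h
    zi, zj, zk = np.meshgrid(*[np.arange(-1, n + 1) for n in ncell], indexing="ij")
    centers = lo + (np.stack([zi, zj, zk], axis=-1).reshape(-1, 3) + 0.5) * h
    verts = np.vstack([corners, centers])

    tets = []
    for axis in range(3):
        # pairs of padded cells adjacent along `axis`
        rng = [np.arange(-1, n + 1) for n in ncell]
        rng[axis] = np.arange(-1, ncell[axis])
        A, B, C = np.meshgrid(*rng, indexing="ij")
        cells = np.stack([A, B, C], axis=-1).reshape(-1, 3)
        nxt = cells.copy()
        nxt[:, axis] += 1
        c1 = center_id(cells[:, 0] + 1, cells[:, 1] + 1, cells[:, 2] + 1)
        c2 = center_id(nxt[:, 0] + 1, nxt[:, 1] + 1, nxt[:, 2] + 1)
        # shared face corners: fixed coord = nxt[axis], free coords in {0,1}^2
        o1, o2 = [a for a in range(3) if a != axis]
        face = np.zeros((len(cells), 2, 2), dtype=np.int64)
        base = cells.copy()
        base[:, axis] += 1  # corner-lattice coordinate of the face plane
        for u in (0, 1):
            for w in (0, 1):
                cc = base.copy()
                cc[:, o1] += u
                cc[:, o2] += w
                valid = np.all((cc >= 0) & (cc <= ncell), axis=1)
                face[:, u, w] = np.where(
                    valid, corner_id(cc[:, 0], cc[:, 1], cc[:, 2]), -1
                )
        # 4 face edges -> 4 tets (c1, c2, e1, e2)
        for e1, e2 in (((0, 0), (0, 1)), ((0, 1), (1, 1)),
                       ((1, 1), (1, 0)), ((1, 0), (0, 0))):
            q1 = face[:, e1[0], e1[1]]
            q2 = face[:, e2[0], e2[1]]
            ok = (q1 >= 0) & (q2 >= 0)
            tets.append(np.stack([c1[ok], c2[ok], q1[ok], q2[ok]], axis=1))
    tets = np.vstack(tets)

    cent = verts[tets].mean(axis=1)
    vox = np.round(world_to_voxel(cent, labels)).astype(int)
    inside = np.all((vox >= 0) & (vox < np.asarray(data.shape)), axis=1)
    lab = np.zeros(len(tets), dtype=np.int32)
    lab[inside] = data[tuple(vox[inside].T)]
    keep = lab > 0
    tets, lab = tets[keep], lab[keep]
    if len(tets) == 0:
        raise ValueError("no tetrahedra had centroids inside the foreground")

    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(-1, 4)
    verts = verts[used]

    # enforce positive orientation
    e = verts[tets][:, 1:] - verts[tets][:, :1]
    neg = np.linalg.det(e) < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    return TetrahedralMesh(verts, tets, lab)


# ---------------------------------------------------------------------------
# linear elasticity
# ---------------------------------------------------------------------------

def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _shape_gradients(verts: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant P1 shape-function gradients (4, 3) and signed volume."""
    e = verts[1:] - verts[:1]
    det = np.linalg.det(e)
    vol = det / 6.0
    if vol <= 0:
        raise ValueError(f"degenerate tetrahedron (signed volume {vol:.3g} <= 0)")
    grads = np.zeros((4, 3))
    # barycentric lam = E^-1 (p - x0) with edge columns E = e.T;
    # grad(lam_i) is row i of E^-1
    grads[1:] = np.linalg.inv(e.T)
    grads[0] = -grads[1:].sum(axis=0)
    return grads, vol


def element_stiffness(verts, E: float, nu: float) -> np.ndarray:
    """12x12 P1 tetrahedral stiffness ``V B^T C B`` (dofs ordered x0 y0 z0 x1 ...).

    Symmetric positive semidefinite with exactly six rigid-body zero modes.
    Raises for non-positive element volume.
    """
    verts = np.asarray(verts, dtype=float).reshape(4, 3)
    grads, vol = _shape_gradients(verts)
    if vol <= 0:
        raise ValueError(f"degenerate tetrahedron (signed volume {vol:.3g} <= 0)")
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    C = _elasticity_matrix(E, nu)
    Ke = vol * B.T @ C @ B
    return 0.5 * (Ke + Ke.T)


def assemble_stiffness(
    mesh: TetrahedralMesh, materials, exclude=()
) -> sp.csr_matrix:
    """Global 3n x 3n stiffness; ``exclude`` is a set of tet ids to skip."""
    mats = _materials_dict(materials)
    missing = set(np.unique(mesh.tet_labels)) - set(mats)
    if missing:
        raise ValueError(f"no material for tissue label(s): {sorted(missing)}")
    excl = set(int(i) for i in exclude)
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for t in range(mesh.n_tets):
        if t in excl:
            continue
        m = mats[int(mesh.tet_labels[t])]
        Ke = element_stiffness(mesh.vertices[mesh.tets[t]], m.E, m.nu)
        dofs = (3 * mesh.tets[t][:, None] + np.arange(3)).ravel()
        rows.append(np.repeat(dofs, 12))
        cols.append(np.tile(dofs, 12))
        vals.append(Ke.ravel())
    if not rows:
        return sp.csr_matrix((3 * n, 3 * n))
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    return 0.5 * (K + K.T)


# ---------------------------------------------------------------------------
# point location / interpolation
# ---------------------------------------------------------------------------

_BARY_TOL = 1e-9


class _TetLocator:
    """Uniform spatial hash over tet bounding boxes; ties at shared faces
    resolve to the lowest tet id."""

    def __init__(self, mesh: TetrahedralMesh):
        self.mesh = mesh
        tv = mesh.tet_vertices()
        self.lo = tv.min(axis=1)
        self.hi = tv.max(axis=1)
        self.cell = max(float((self.hi - self.lo).max()), 1e-9)
        self.origin = mesh.vertices.min(axis=0)
        self.buckets: dict[tuple, list[int]] = {}
        lo_c = np.floor((self.lo - self.origin) / self.cell).astype(int)
        hi_c = np.floor((self.hi - self.origin) / self.cell).astype(int)
        for t in range(mesh.n_tets):
            for i in range(lo_c[t, 0], hi_c[t, 0] + 1):
                for j in range(lo_c[t, 1], hi_c[t, 1] + 1):
                    for k in range(lo_c[t, 2], hi_c[t, 2] + 1):
                        self.buckets.setdefault((i, j, k), []).append(t)
        # precompute barycentric transform per tet
        e = tv[:, 1:] - tv[:, :1]
        self.Tinv = np.linalg.inv(np.transpose(e, (0, 2, 1)))
        self.v0 = tv[:, 0]

    def barycentric(self, tet: int, p: np.ndarray) -> np.ndarray:
        lam = self.Tinv[tet] @ (p - self.v0[tet])
        return np.concatenate([[1.0 - lam.sum()], lam])

    def locate(self, p: np.ndarray) -> tuple[int, np.ndarray | None]:
        key = tuple(np.floor((p - self.origin) / self.cell).astype(int))
        for t in sorted(self.buckets.get(key, ())):
            if np.any(p < self.lo[t] - 1e-9) or np.any(p > self.hi[t] + 1e-9):
                continue
            w = self.barycentric(t, p)
            if w.min() >= -_BARY_TOL:
                return t, w
        return -1, None


def locate_points(mesh: TetrahedralMesh, points) -> tuple[np.ndarray, np.ndarray]:
    """Containing tet id per point (-1 if outside) and barycentric weights."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    loc = _TetLocator(mesh)
    tet_ids = np.full(len(pts), -1, dtype=np.int64)
    weights = np.zeros((len(pts), 4))
    for i, p in enumerate(pts):
        t, w = loc.locate(p)
        tet_ids[i] = t
        if t >= 0:
            weights[i] = w
    return tet_ids, weights


def build_interpolation(
    mesh: TetrahedralMesh, points
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Barycentric interpolation matrix H and per-point containing tet id.

    H has 3 rows per *located* point (row blocks in located-point order);
    unlocated points get tet id -1 and no rows.
    """
    pts = points.points if hasattr(points, "points") else np.atleast_2d(points)
    tet_ids, weights = locate_points(mesh, pts)
    located = np.flatnonzero(tet_ids >= 0)
    rows, cols, vals = [], [], []
    for r, i in enumerate(located):
        vidx = mesh.tets[tet_ids[i]]
        for a in range(3):
            rows.extend([3 * r + a] * 4)
            cols.extend(3 * vidx + a)
            vals.extend(weights[i])
    H = sp.csr_matrix(
        (vals, (rows, cols)), shape=(3 * len(located), 3 * mesh.n_vertices)
    )
    return H, tet_ids


def mesh_field_to_grid(
    mesh: TetrahedralMesh,
    U: np.ndarray,
    like,
) -> DenseDeformationField:
    """Rasterize per-vertex displacements onto a volume grid.

    Barycentric interpolation inside the mesh, zero outside.  ``like`` supplies
    the grid geometry (shape/spacing/origin).
    """
    U = np.asarray(U, dtype=float).reshape(-1, 3)
    if len(U) != mesh.n_vertices:
        raise ValueError("U length must equal vertex count")
    shape = tuple(like.shape[:3])
    sp_ = np.asarray(like.spacing)
    org = np.asarray(like.origin)
    out = np.zeros(shape + (3,))
    filled = np.zeros(shape, dtype=bool)
    tv = mesh.tet_vertices()
    e = tv[:, 1:] - tv[:, :1]
    Tinv = np.linalg.inv(np.transpose(e, (0, 2, 1)))
    for t in range(mesh.n_tets):
        lo = np.maximum(np.ceil((tv[t].min(axis=0) - org) / sp_).astype(int), 0)
        hi = np.minimum(
            np.floor((tv[t].max(axis=0) - org) / sp_).astype(int),
            np.asarray(shape) - 1,
        )
        if np.any(hi < lo):
            continue
        gi, gj, gk = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                                 indexing="ij")
        vox = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)
        w_pts = org + vox * sp_
        lam = (Tinv[t] @ (w_pts - tv[t, 0]).T).T
        w = np.column_stack([1.0 - lam.sum(axis=1), lam])
        ok = w.min(axis=1) >= -_BARY_TOL
        if not ok.any():
            continue
        vox = vox[ok]
        new = ~filled[vox[:, 0], vox[:, 1], vox[:, 2]]
        vox, w = vox[new], w[ok][new]
        out[vox[:, 0], vox[:, 1], vox[:, 2]] = w @ U[mesh.tets[t]]
        filled[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return DenseDeformationField(out, tuple(sp_), tuple(org))
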