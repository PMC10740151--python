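"""Nested expectation-maximization registration with resection-submesh growth.

The cost couples three unknowns: vertex displacements ``U``, a fuzzy point
correspondence ``C`` (rows of non-negative weights summing to 1 over candidate
target points), and a face-connected resection submesh ``M_Rem``::

    J = sum_{e not in M_Rem} U^T K_e U
      + lambda1 * sum_{s not in M_Rem} (HU - D(C))^T W (HU - D(C))
      + lambda2 * sum_{e in M_Rem} V_e

with per-source displacement targets ``d_i = sum_j c_ij t_j - s_i``.  An inner
EM alternates a Gaussian soft-assignment E-step with a linear M-step for U;
an outer loop grows ``M_Rem`` from mesh elements whose displaced centroids
fall in the background of the fixed image (BGI) and are face-connected to the
current submesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import ImageVolume, TetrahedralMesh, backward_from_forward, sample_trilinear
from .features import canny_edge_points
from .fem import assemble_stiffness, build_interpolation, mesh_field_to_grid
from .pbnrr import RegistrationResult, _auto_scale, _diag_S

__all__ = [
    "NEMConfig",
    "eval_cost_J",
    "update_correspondence",
    "update_displacement",
    "detect_background_tets",
    "grow_resection",
    "nemnrr_register",
]


@dataclass
class NEMConfig:
    lambda1: float = 1.0
    lambda2: float = 1.0
    bgi_threshold: float | None = None   # None -> Otsu threshold of fixed image
    candidate_radius: float = 4.0        # mm
    corr_temperature: float = 1.0        # mm
    canny_sigma: float = 2.0             # feature extraction: strong edges only
    canny_low: float | None = 10.0
    canny_high: float | None = 20.0
    inner_tol: float = 1e-2              # mm
    inner_max: int = 10
    outer_max: int = 10
    stiffness_scale: float | None = None
    max_sources: int = 5000              # deterministic stride subsampling cap

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if self.corr_temperature <= 0 or self.candidate_radius <= 0:
            raise ValueError("temperature and candidate radius must be > 0")


# ---------------------------------------------------------------------------
# cost and EM steps
# ---------------------------------------------------------------------------

def _targets_mean(C: sp.csr_matrix, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-weighted target means and a has-row mask."""
    mass = np.asarray(C.sum(axis=1)).ravel()
    mean = np.zeros((C.shape[0], 3))
    nz = mass > 0
    if nz.any():
        mean[nz] = (C @ targets)[nz] / mass[nz, None]
    return mean, nz


def eval_cost_J(
    U,
    C: sp.csr_matrix,
    m_rem,
    mesh: TetrahedralMesh,
    materials,
    sources: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    cfg: NEMConfig,
    H: sp.csr_matrix | None = None,
    source_tets: np.ndarray | None = None,
    K: sp.csr_matrix | None = None,
) -> tuple[float, dict]:
    """Evaluate the three-term cost; returns (J, per-term breakdown).

    ``H`` must carry 3 rows per source (all sources located); ``source_tets``
    maps sources to containing tets so sources inside ``M_Rem`` are excluded
    from the data term.  Precomputed ``K`` (already excluding ``m_rem``) may be
    passed to avoid reassembly.
    """
    u = np.asarray(U, dtype=float).ravel()
    m_rem = set(int(i) for i in m_rem)
    if K is None:
        K = assemble_stiffness(mesh, materials, exclude=m_rem)
    term1 = float(u @ (K @ u))

    if H is None:
        H, source_tets = build_interpolation(mesh, sources)
    hu = (H @ u).reshape(-1, 3)
    tbar, has_row = _targets_mean(C, targets)
    d = tbar - sources
    keep = has_row.copy()
    if source_tets is not None and m_rem:
        in_rem = np.isin(source_tets, list(m_rem))
        keep &= ~in_rem
    r = hu[keep] - d[keep]
    term2 = float(cfg.lambda1 * np.sum(weights[keep] * np.sum(r * r, axis=1)))

    vols = mesh.volumes()
    term3 = float(cfg.lambda2 * sum(vols[i] for i in m_rem))
    J = term1 + term2 + term3
    return J, {"strain": term1, "data": term2, "volume": term3}


def update_correspondence(
    displaced_sources: np.ndarray,
    targets: np.ndarray,
    cfg: NEMConfig,
    tree: cKDTree | None = None,
) -> sp.csr_matrix:
    """E-step: Gaussian soft assignment over candidates within the radius.

    ``c_ij \\propto exp(-||x_i - t_j||^2 / T^2)`` over targets within
    ``candidate_radius`` of the displaced source ``x_i``; rows normalized to 1,
    sources with no candidates get empty rows.
    """
    x = np.atleast_2d(displaced_sources)
    t = np.atleast_2d(targets)
    if tree is None:
        tree = cKDTree(t)
    neigh = tree.query_ball_point(x, cfg.candidate_radius)
    rows, cols, vals = [], [], []
    T2 = cfg.corr_temperature**2
    for i, js in enumerate(neigh):
        if not js:
            continue
        js = np.asarray(js)
        d2 = np.sum((t[js] - x[i]) ** 2, axis=1)
        w = np.exp(-(d2 - d2.min()) / T2)
        w /= w.sum()
        rows.extend([i] * len(js))
        cols.extend(js.tolist())
        vals.extend(w.tolist())
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(x), len(t)))


def update_displacement(
    C: sp.csr_matrix,
    m_rem,
    mesh: TetrahedralMesh,
    materials,
    sources: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    cfg: NEMConfig,
    H: sp.csr_matrix,
    source_tets: np.ndarray,
    K: sp.csr_matrix | None = None,
) -> np.ndarray:
    """M-step: minimize strain + data terms in U with C, M_Rem fixed.

    Solves ``[K_excl + lambda1 H^T W H] U = lambda1 H^T W D(C)`` where rows of
    sources without candidates or inside ``M_Rem`` carry zero weight.  Degrees
    of freedom decoupled from both stiffness and data (vertices interior to the
    removed submesh) are pinned to zero.
    """
    m_rem = set(int(i) for i in m_rem)
    if K is None:
        K = assemble_stiffness(mesh, materials, exclude=m_rem)
    tbar, has_row = _targets_mean(C, targets)
    d = tbar - sources
    w_eff = np.where(has_row, weights, 0.0)
    if m_rem:
        w_eff = np.where(np.isin(source_tets, list(m_rem)), 0.0, w_eff)
    W = _diag_S(w_eff)
    A = (K + cfg.lambda1 * (H.T @ W @ H)).tocsc()
    rhs = cfg.lambda1 * (H.T @ (W @ d.ravel()))
    free = np.asarray(np.abs(A).sum(axis=1)).ravel() > 1e-14
    U = np.zeros(A.shape[0])
    if free.any():
        Af = A[free][:, free]
        lu = spla.splu(Af.tocsc())
        U[free] = lu.solve(np.asarray(rhs).ravel()[free])
        res = np.linalg.norm(Af @ U[free] - np.asarray(rhs).ravel()[free])
        if not np.all(np.isfinite(U)) or res > 1e-6 * max(
            np.linalg.norm(rhs), 1e-30
        ):
            raise ValueError("M-step operator is singular on the retained mesh")
    return U


# ---------------------------------------------------------------------------
# resection submesh
# ---------------------------------------------------------------------------

def detect_background_tets(
    mesh: TetrahedralMesh,
    U,
    fixed: ImageVolume,
    bgi_threshold: float,
) -> set:
    """Tets whose displaced centroid samples fixed-image intensity < threshold."""
    Uv = np.asarray(U, dtype=float).reshape(-1, 3)
    cent = mesh.centroids() + Uv[mesh.tets].mean(axis=1)
    vals = sample_trilinear(fixed, cent, background=0.0)
    return set(np.flatnonzero(vals < bgi_threshold).tolist())


def _face_components(mesh: TetrahedralMesh, tet_ids: np.ndarray) -> np.ndarray:
    """Connected-component label per tet of the sub-collection, via shared faces."""
    faces: dict[tuple, int] = {}
    rows, cols = [], []
    for a, t in enumerate(tet_ids):
        vs = np.sort(mesh.tets[t])
        for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            key = (vs[f[0]], vs[f[1]], vs[f[2]])
            if key in faces:
                b = faces[key]
                rows.extend([a, b])
                cols.extend([b, a])
            else:
                faces[key] = a
    n = len(tet_ids)
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def grow_resection(current, candidates, mesh: TetrahedralMesh) -> set:
    """Grow the resection submesh from face-connected background candidates.

    Empty ``current``: seed with the largest face-connected candidate
    component (ties: component containing the smallest tet id).  Otherwise add
    every candidate face-connected — transitively through candidates — to the
    current submesh.  The result is monotone non-decreasing.
    """
    current = set(int(i) for i in current)
    candidates = set(int(i) for i in candidates)
    if not candidates:
        return set(current)
    pool = sorted(candidates | current)
    ids = np.asarray(pool)
    labels = _face_components(mesh, ids)
    if not current:
        sizes: dict[int, int] = {}
        for lab in labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        best = max(sizes, key=lambda l: (sizes[l], -int(ids[labels == l].min())))
        return set(ids[labels == best].tolist())
    cur_labels = {labels[i] for i, t in enumerate(ids) if t in current}
    grown = set(current)
    for i, t in enumerate(ids):
        if labels[i] in cur_labels:
            grown.add(int(t))
    return grown


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _subsample(points: np.ndarray, cap: int) -> np.ndarray:
    if len(points) <= cap:
        return points
    idx = np.linspace(0, len(points) - 1, cap).astype(int)
    return points[np.unique(idx)]


def nemnrr_register(
    floating: ImageVolume,
    fixed: ImageVolume,
    mesh: TetrahedralMesh,
    materials,
    cfg: NEMConfig,
    sources: np.ndarray | None = None,
    targets: np.ndarray | None = None,
) -> RegistrationResult:
    """Outer EM over M_Rem around an inner EM over (U, C).

    Sources default to Canny edge points of the floating image (subsampled
    deterministically to ``max_sources``), targets to Canny edge points of the
    fixed image.  Returns a :class:`RegistrationResult` whose ``extras`` carry
    the resection submesh, its growth history, the final correspondence and
    the inner-EM objective trace.
    """
    if sources is None:
        sources = canny_edge_points(
            floating, sigma=cfg.canny_sigma, low_threshold=cfg.canny_low,
            high_threshold=cfg.canny_high,
        ).points
    if targets is None:
        targets = canny_edge_points(
            fixed, sigma=cfg.canny_sigma, low_threshold=cfg.canny_low,
            high_threshold=cfg.canny_high,
        ).points
    if len(targets) == 0:
        raise ValueError("no target edge points in the fixed image")
    sources = _subsample(np.asarray(sources, dtype=float), cfg.max_sources)

    H_all, tet_ids = build_interpolation(mesh, sources)
    located = np.flatnonzero(tet_ids >= 0)
    if len(located) < 12:
        raise ValueError("fewer than 12 source points located inside the mesh")
    sources = sources[located]
    source_tets = tet_ids[located]
    H = H_all
    weights = np.ones(len(sources))

    thr = cfg.bgi_threshold
    if thr is None:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(np.asarray(fixed.data, dtype=float)))

    tree = cKDTree(targets)
    K_full = assemble_stiffness(mesh, materials)
    scale = cfg.stiffness_scale
    if scale is None:
        scale = _auto_scale(K_full, H, _diag_S(weights * cfg.lambda1))

    m_rem: set = set()
    history: list[dict] = []
    U = np.zeros(3 * mesh.n_vertices)
    C = sp.csr_matrix((len(sources), len(targets)))
    cost_trace: list[list[float]] = []
    T2 = cfg.corr_temperature**2

    for outer in range(cfg.outer_max):
        K = (scale * assemble_stiffness(mesh, materials, exclude=m_rem)).tocsr()
        inner_costs = []
        for inner in range(cfg.inner_max):
            displaced = sources + (H @ U).reshape(-1, 3)
            C = update_correspondence(displaced, targets, cfg, tree=tree)
            U_new = update_displacement(
                C, m_rem, mesh, materials, sources, targets, weights, cfg,
                H, source_tets, K=K,
            )
            inner_costs.append(
                _free_energy(U_new, C, m_rem, mesh, sources, targets, weights,
                             cfg, H, source_tets, K, tree, T2)
            )
            change = float(np.max(np.abs(U_new - U)))
            U = U_new
            if change < cfg.inner_tol:
                break
        cost_trace.append(inner_costs)

        candidates = detect_background_tets(mesh, U, fixed, thr)
        grown = grow_resection(m_rem, candidates, mesh)
        history.append(
            {"outer": outer, "candidates": len(candidates), "m_rem": len(grown)}
        )
        if grown == m_rem:
            break
        m_rem = grown

    J, terms = eval_cost_J(
        U, C, m_rem, mesh, materials, sources, targets, weights, cfg,
        H=H, source_tets=source_tets,
    )
    forward = mesh_field_to_grid(mesh, U.reshape(-1, 3), fixed)
    dense = backward_from_forward(forward)
    in_rem = np.isin(source_tets, list(m_rem)) if m_rem else np.zeros(len(sources), bool)
    return RegistrationResult(
        U=U.reshape(-1, 3),
        active_matches=np.flatnonzero(~in_rem),
        rejected_matches=np.flatnonzero(in_rem),
        iterations=history,
        dense_field=dense,
        converged=True,
        mesh=mesh,
        extras={
            "m_rem": m_rem,
            "m_rem_history": history,
            "correspondence": C,
            "cost_trace": cost_trace,
            "final_cost": J,
            "final_terms": terms,
            "bgi_threshold": thr,
            "stiffness_scale": scale,
            "sources": sources,
            "targets": targets,
        },
    )


def _free_energy(U, C, m_rem, mesh, sources, targets, weights, cfg,
                 H, source_tets, K, tree, T2) -> float:
    """EM auxiliary objective (monotone under exact alternation).

    ``Q = U^T K U + lambda1 * sum_ij c_ij w_i ||x_i - t_j||^2
        + lambda1 * T^2 * sum_ij c_ij log c_ij  + lambda2 * vol(M_Rem)``.

    The spread term ``sum_j c_ij ||x_i - t_j||^2`` equals
    ``||x_i - tbar_i||^2 + const(C)``, so the M-step on the mean-target system
    minimizes Q exactly; the softmax E-step minimizes it row-wise.
    """
    u = np.asarray(U).ravel()
    x = sources + (H @ u).reshape(-1, 3)
    m_rem = set(int(i) for i in m_rem)
    q = float(u @ (K @ u))
    Cc = C.tocoo()
    excl = (
        np.isin(source_tets, list(m_rem)) if m_rem else np.zeros(len(sources), bool)
    )
    ok = (Cc.data > 0) & ~excl[Cc.row]
    if ok.any():
        i, j, c = Cc.row[ok], Cc.col[ok], Cc.data[ok]
        d2 = np.sum((x[i] - targets[j]) ** 2, axis=1)
        w = weights[i]
        q += cfg.lambda1 * float(np.sum(w * c * d2))
        q += cfg.lambda1 * T2 * float(np.sum(w * c * np.log(c)))
    vols = mesh.volumes()
    q += cfg.lambda2 * float(sum(vols[t] for t in m_rem))
    return q
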