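"""Hybrid approximation/interpolation solver with iterative point-outlier
rejection.

Each iteration solves ``[K + H^T S H] U = H^T S D + F`` with the relaxation
force ``F = K U_i``; after every rejection iteration the matches with the
highest interpolation error ``xi_k = ||(H U)_k - d_k||`` are discarded and
``S, H, D`` are rebuilt by row deletion (no re-matching).  A final relaxation
loop runs until the maximum vertex-displacement change falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .block_matching import BlockMatchConfig, SparseDisplacementField, block_match_all
from .core import DenseDeformationField, ImageVolume, TetrahedralMesh, backward_from_forward
from .features import FeatureConfig, select_registration_points
from .fem import assemble_stiffness, build_interpolation, mesh_field_to_grid

__all__ = [
    "PBNRRConfig",
    "RegistrationResult",
    "rejection_count",
    "solve_hybrid",
    "compute_block_errors",
    "register_sparse",
    "pbnrr_register",
]


@dataclass
class PBNRRConfig:
    f_R: float = 0.25          # total rejection fraction
    n_R: int = 10              # rejection iterations
    n_A: int = 10              # post-rejection approximation/relaxation steps
    tol: float = 1e-3          # mm, max vertex-change convergence threshold
    max_iter: int = 50         # hard cap on relaxation iterations
    stiffness_scale: float | None = None  # None -> auto trace balancing
    stiffness_factor: float = 1.0         # multiplies the auto-balanced scale

    def __post_init__(self):
        if not (0.0 <= self.f_R < 1.0):
            raise ValueError("f_R must be in [0, 1)")
        if self.n_R < 1:
            raise ValueError("n_R must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class RegistrationResult:
    U: np.ndarray                       # (n_vertices, 3) mm
    active_matches: np.ndarray          # indices into the located match set
    rejected_matches: np.ndarray
    iterations: list = dfield(default_factory=list)
    dense_field: DenseDeformationField | None = None
    converged: bool = True
    mesh: TetrahedralMesh | None = None
    extras: dict = dfield(default_factory=dict)


def rejection_count(N: int, f_R: float, n_R: int) -> int:
    """Matches rejected per rejection iteration: ``floor(N * f_R / n_R)``."""
    if N < 0:
        raise ValueError("N must be >= 0")
    return int(np.floor(N * f_R / n_R))


def _diag_S(conf: np.ndarray) -> sp.csr_matrix:
    return sp.diags(np.repeat(np.asarray(conf, dtype=float), 3)).tocsr()


def solve_hybrid(K, H, S, D, F) -> np.ndarray:
    """Solve ``[K + H^T S H] U = H^T S D + F``; verifies the residual."""
    A = (K + H.T @ S @ H).tocsc()
    rhs = np.asarray(H.T @ (S @ np.asarray(D, dtype=float).ravel())).ravel() + np.asarray(F).ravel()
    try:
        lu = spla.splu(A)
        U = lu.solve(rhs)
    except RuntimeError as exc:
        raise ValueError(
            "hybrid operator is singular; matches do not constrain all "
            "rigid modes"
        ) from exc
    res = np.linalg.norm(A @ U - rhs)
    if not np.all(np.isfinite(U)) or res > 1e-8 * max(np.linalg.norm(rhs), 1e-30):
        raise ValueError(
            "hybrid solve failed the residual check; the operator is "
            "rank-deficient (missing rigid-mode constraints)"
        )
    return U


def compute_block_errors(H, U, D) -> np.ndarray:
    """Per-match error ``xi_k = ||(H U)_k - d_k||_2``."""
    r = (H @ np.asarray(U).ravel()).reshape(-1, 3) - np.asarray(D).reshape(-1, 3)
    return np.linalg.norm(r, axis=1)


def _auto_scale(K, H, S) -> float:
    tK = K.diagonal().sum()
    tHSH = (H.T @ S @ H).diagonal().sum()
    if tK <= 0:
        return 1.0
    return float(tHSH / tK) if tHSH > 0 else 1.0


def register_sparse(
    mesh: TetrahedralMesh,
    materials,
    matches: SparseDisplacementField,
    cfg: PBNRRConfig,
    grid_like=None,
) -> RegistrationResult:
    """Run the rejection + relaxation iterations on precomputed matches.

    ``grid_like`` (a volume or field) requests rasterization of the result
    into a dense backward deformation field on that grid.
    """
    K0 = assemble_stiffness(mesh, materials)
    H_all, tet_ids = build_interpolation(mesh, matches.points)
    located = np.flatnonzero(tet_ids >= 0)
    if len(located) < 12:
        raise ValueError(
            f"only {len(located)} matches located inside the mesh; >= 12 required"
        )
    D_all = matches.displacements[located]
    conf_all = matches.confidences[located]

    scale = cfg.stiffness_scale
    if scale is None:
        scale = cfg.stiffness_factor * _auto_scale(K0, H_all, _diag_S(conf_all))
    K = (scale * K0).tocsr()

    N0 = len(located)
    per_iter = rejection_count(N0, cfg.f_R, cfg.n_R)
    active = np.arange(N0)
    rejected: list[int] = []
    U = np.zeros(3 * mesh.n_vertices)
    iterations = []

    def sub_H(idx):
        rows = (3 * idx[:, None] + np.arange(3)).ravel()
        return H_all[rows]

    H = sub_H(active)
    S = _diag_S(conf_all[active])
    D = D_all[active]
    for i in range(cfg.n_R):
        F = K @ U
        U = solve_hybrid(K, H, S, D, F)
        xi = compute_block_errors(H, U, D)
        if per_iter > 0 and len(active) > per_iter:
            order = np.lexsort((active, -xi))  # highest error, ties by index
            drop = order[:per_iter]
            rejected.extend(active[drop].tolist())
            keep = np.ones(len(active), dtype=bool)
            keep[drop] = False
            active = active[keep]
            H = sub_H(active)
            S = _diag_S(conf_all[active])
            D = D_all[active]
        iterations.append(
            {"phase": "rejection", "iter": i, "rejected": per_iter,
             "active": int(len(active)), "max_xi": float(xi.max(initial=0.0))}
        )

    converged = False
    for i in range(min(cfg.n_A, cfg.max_iter)):
        F = K @ U
        U_new = solve_hybrid(K, H, S, D, F)
        change = float(np.max(np.abs(U_new - U)))
        U = U_new
        iterations.append({"phase": "relaxation", "iter": i, "change": change})
        if change < cfg.tol:
            converged = True
            break

    Uv = U.reshape(-1, 3)
    dense = None
    if grid_like is not None:
        forward = mesh_field_to_grid(mesh, Uv, grid_like)
        dense = backward_from_forward(forward)
    return RegistrationResult(
        U=Uv,
        active_matches=active,
        rejected_matches=np.asarray(rejected, dtype=np.int64),
        iterations=iterations,
        dense_field=dense,
        converged=converged,
        mesh=mesh,
        extras={
            "located": located,
            "stiffness_scale": scale,
            "per_iter_rejection": per_iter,
            "initial_matches": N0,
        },
    )


def pbnrr_register(
    floating: ImageVolume,
    fixed: ImageVolume,
    mesh: TetrahedralMesh,
    materials,
    feature_cfg: FeatureConfig,
    match_cfg: BlockMatchConfig,
    cfg: PBNRRConfig,
) -> RegistrationResult:
    """End-to-end PBNRR: feature selection, block matching, rejection solve."""
    fc = feature_cfg
    if fc.margin is None:
        margin = tuple(
            b + w for b, w in zip(match_cfg.block_radius, match_cfg.window_radius)
        )
        fc = FeatureConfig(
            selection_fraction=fc.selection_fraction,
            block_radius=fc.block_radius,
            mask=fc.mask,
            min_spacing=fc.min_spacing,
            margin=margin,
        )
    points = select_registration_points(floating, fc)
    matches, skipped = block_match_all(floating, fixed, points, match_cfg)
    if len(matches) < 12:
        raise ValueError(f"only {len(matches)} usable matches; >= 12 required")
    result = register_sparse(mesh, materials, matches, cfg, grid_like=fixed)
    result.extras["n_feature_points"] = len(points)
    result.extras["n_skipped_matches"] = len(skipped)
    result.extras["matches"] = matches
    return result
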