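import numpy as np
import pytest
import scipy.sparse as sp

from brainshift.core import ImageVolume, TetrahedralMesh
from brainshift.fem import Material, build_interpolation
from brainshift.nemnrr import (
    NEMConfig,
    detect_background_tets,
    eval_cost_J,
    grow_resection,
    update_correspondence,
    update_displacement,
)

MATS = {1: Material(3000.0, 0.45)}


def strip_mesh(n=4):
    """A strip of n cubes along x, each split into 6 tets (face-connected)."""
    verts, tets = [], []
    for i in range(n + 1):
        for y in (0, 1):
            for z in (0, 1):
                verts.append([float(i), float(y), float(z)])
    verts = np.asarray(verts)

    def vid(i, y, z):
        return i * 4 + y * 2 + z

    cube = [[0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
            [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7]]
    for i in range(n):
        corners = [vid(i, 0, 0), vid(i + 1, 0, 0), vid(i, 1, 0), vid(i + 1, 1, 0),
                   vid(i, 0, 1), vid(i + 1, 0, 1), vid(i, 1, 1), vid(i + 1, 1, 1)]
        for t in cube:
            tt = [corners[j] for j in t]
            if np.linalg.det(verts[tt][1:] - verts[tt][0]) < 0:
                tt = [tt[0], tt[1], tt[3], tt[2]]
            tets.append(tt)
    return TetrahedralMesh(verts, tets, np.ones(len(tets), np.int32))


class TestCost:
    def test_all_terms_vanish(self):
        mesh = strip_mesh(2)
        src = mesh.centroids()[:5]
        tgt = src.copy()
        C = sp.csr_matrix(np.eye(5))
        J, terms = eval_cost_J(
            np.zeros(3 * mesh.n_vertices), C, set(), mesh, MATS, src, tgt,
            np.ones(5), NEMConfig(),
        )
        assert J == pytest.approx(0.0, abs=1e-12)

    def test_volume_term_only(self):
        mesh = strip_mesh(2)
        src = mesh.centroids()[:3]
        C = sp.csr_matrix(np.eye(3))
        cfg = NEMConfig(lambda2=2.0)
        vol0 = mesh.volumes()[0]
        J, terms = eval_cost_J(
            np.zeros(3 * mesh.n_vertices), C, {0}, mesh, MATS, src, src,
            np.ones(3), cfg,
        )
        assert terms["strain"] == 0.0
        assert terms["volume"] == pytest.approx(2.0 * vol0)
        # source 0 sits in tet 0 which is in M_Rem: excluded from the data term
        assert terms["data"] == pytest.approx(0.0, abs=1e-12)

    def test_three_loop_oracle(self, rng):
        mesh = strip_mesh(3)
        src = rng.uniform([0.1, 0.1, 0.1], [2.9, 0.9, 0.9], size=(8, 3))
        tgt = rng.uniform([0, 0, 0], [3, 1, 1], size=(12, 3))
        Cd = rng.uniform(size=(8, 12))
        Cd *= (Cd > 0.7)
        rs = Cd.sum(axis=1, keepdims=True)
        Cd = np.divide(Cd, rs, out=np.zeros_like(Cd), where=rs > 0)
        C = sp.csr_matrix(Cd)
        U = 0.05 * rng.normal(size=3 * mesh.n_vertices)
        W = rng.uniform(0.5, 1.0, size=8)
        m_rem = {1, 7}
        cfg = NEMConfig(lambda1=0.7, lambda2=1.3)
        J, terms = eval_cost_J(U, C, m_rem, mesh, MATS, src, tgt, W, cfg)

        # oracle: explicit three-term loop
        from brainshift.fem import assemble_stiffness, element_stiffness

        t1 = 0.0
        for t in range(mesh.n_tets):
            if t in m_rem:
                continue
            Ke = element_stiffness(mesh.vertices[mesh.tets[t]], 3000.0, 0.45)
            dofs = (3 * mesh.tets[t][:, None] + np.arange(3)).ravel()
            t1 += U[dofs] @ Ke @ U[dofs]
        H, tids = build_interpolation(mesh, src)
        hu = (H @ U).reshape(-1, 3)
        t2 = 0.0
        for i in range(8):
            if Cd[i].sum() == 0 or tids[i] in m_rem:
                continue
            d = Cd[i] @ tgt - src[i]
            r = hu[i] - d
            t2 += 0.7 * W[i] * (r @ r)
        t3 = 1.3 * sum(mesh.volumes()[t] for t in m_rem)
        assert J == pytest.approx(t1 + t2 + t3, rel=1e-9)


class TestCorrespondence:
    def test_single_candidate(self):
        C = update_correspondence(
            np.array([[0.0, 0.0, 0.0]]), np.array([[1.0, 0.0, 0.0]]),
            NEMConfig(candidate_radius=2.0),
        )
        assert C[0, 0] == pytest.approx(1.0)

    def test_equidistant_split(self):
        C = update_correspondence(
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
            NEMConfig(candidate_radius=2.0),
        )
        assert C[0, 0] == pytest.approx(0.5)
        assert C[0, 1] == pytest.approx(0.5)

    def test_softmax_oracle(self, rng):
        src = rng.normal(size=(6, 3))
        tgt = rng.normal(size=(15, 3))
        cfg = NEMConfig(candidate_radius=10.0, corr_temperature=1.7)
        C = update_correspondence(src, tgt, cfg).toarray()
        for i in range(6):
            d2 = np.sum((tgt - src[i]) ** 2, axis=1)
            w = np.exp(-d2 / 1.7**2)
            w /= w.sum()
            assert np.allclose(C[i], w, atol=1e-12)

    def test_no_candidates_empty_row(self):
        C = update_correspondence(
            np.array([[0.0, 0.0, 0.0]]), np.array([[50.0, 0.0, 0.0]]),
            NEMConfig(candidate_radius=1.0),
        )
        assert C.nnz == 0

    def test_rows_sum_to_one(self, rng):
        src = rng.normal(size=(10, 3))
        tgt = rng.normal(size=(30, 3)) * 2
        C = update_correspondence(src, tgt, NEMConfig(candidate_radius=3.0))
        sums = np.asarray(C.sum(axis=1)).ravel()
        nz = sums > 0
        assert np.allclose(sums[nz], 1.0)


class TestDisplacementStep:
    def test_zero_targets_zero_solution(self):
        mesh = strip_mesh(2)
        src = mesh.centroids()
        n = len(src)
        C = sp.csr_matrix(np.eye(n))
        H, tids = build_interpolation(mesh, src)
        U = update_displacement(
            C, set(), mesh, MATS, src, src, np.ones(n), NEMConfig(), H, tids
        )
        assert np.abs(U).max() < 1e-10

    def test_translation_limit(self):
        mesh = strip_mesh(2)
        src = mesh.centroids()
        t = np.array([0.04, -0.02, 0.01])
        tgt = src + t
        C = sp.csr_matrix(np.eye(len(src)))
        H, tids = build_interpolation(mesh, src)
        cfg = NEMConfig(lambda1=1e7)
        U = update_displacement(
            C, set(), mesh, MATS, src, tgt, np.ones(len(src)), cfg, H, tids
        )
        assert np.abs(U.reshape(-1, 3) - t).max() < 1e-4

    def test_dense_oracle(self, rng):
        mesh = strip_mesh(2)
        src = mesh.centroids()[::2]
        tgt = src + 0.05 * rng.normal(size=src.shape)
        C = sp.csr_matrix(np.eye(len(src)))
        H, tids = build_interpolation(mesh, src)
        W = rng.uniform(0.5, 1, len(src))
        cfg = NEMConfig(lambda1=3.0)
        from brainshift.fem import assemble_stiffness

        K = assemble_stiffness(mesh, MATS)
        U = update_displacement(C, set(), mesh, MATS, src, tgt, W, cfg, H, tids,
                                K=K)
        Wm = sp.diags(np.repeat(W, 3))
        A = (K + 3.0 * H.T @ Wm @ H).toarray()
        rhs = 3.0 * (H.T @ (Wm @ (tgt - src).ravel()))
        expect = np.linalg.solve(A, rhs)
        assert np.abs(U - expect).max() < 1e-8


class TestBackgroundDetection:
    def test_bright_image_empty(self):
        mesh = strip_mesh(2)
        vol = ImageVolume(np.full((8, 8, 8), 100.0))
        assert detect_background_tets(mesh, np.zeros((mesh.n_vertices, 3)),
                                      vol, 30.0) == set()

    def test_zero_threshold_empty(self):
        mesh = strip_mesh(2)
        vol = ImageVolume(np.zeros((8, 8, 8)))
        assert detect_background_tets(mesh, np.zeros((mesh.n_vertices, 3)),
                                      vol, 0.0) == set()

    def test_dark_region_detected(self):
        mesh = strip_mesh(4)
        data = np.full((8, 8, 8), 100.0)
        data[:2] = 0.0  # x < 2 is dark
        vol = ImageVolume(data)
        cand = detect_background_tets(mesh, np.zeros((mesh.n_vertices, 3)),
                                      vol, 30.0)
        cent = mesh.centroids()
        expect = set(np.flatnonzero(cent[:, 0] < 1.4).tolist())
        assert cand >= expect

    def test_displacement_shifts_sampling(self):
        mesh = strip_mesh(2)
        data = np.full((8, 8, 8), 100.0)
        data[4:] = 0.0
        vol = ImageVolume(data)
        U = np.zeros((mesh.n_vertices, 3))
        U[:, 0] = 3.0  # push centroids into the dark half
        cand = detect_background_tets(mesh, U, vol, 30.0)
        assert len(cand) > 0


class TestGrowResection:
    def test_empty_candidates_noop(self):
        mesh = strip_mesh(3)
        assert grow_resection({1, 2}, set(), mesh) == {1, 2}

    def test_seed_largest_component(self):
        mesh = strip_mesh(4)  # 24 tets, cubes of 6
        # candidates: all of cube 0 (6 tets, connected) and one tet of cube 3
        cand = set(range(6)) | {20}
        grown = grow_resection(set(), cand, mesh)
        assert grown == set(range(6))

    def test_grow_only_connected(self):
        mesh = strip_mesh(4)
        current = set(range(6))           # cube 0
        cand = set(range(6, 12)) | {23}   # cube 1 (touches cube 0) + far tet
        grown = grow_resection(current, cand, mesh)
        assert grown == set(range(12))

    def test_saturation(self):
        mesh = strip_mesh(3)
        grown = grow_resection({0}, set(range(mesh.n_tets)), mesh)
        assert grown == set(range(mesh.n_tets))

    def test_monotone(self):
        mesh = strip_mesh(3)
        cur = {0, 1}
        grown = grow_resection(cur, {2, 3}, mesh)
        assert grown >= cur


class TestDriver:
    def test_no_cavity_empty_m_rem(self, nemnrr_no_cavity):
        assert nemnrr_no_cavity.extras["m_rem"] == set()

    def test_no_cavity_accuracy_comparable_to_pbnrr(
        self, nemnrr_no_cavity, pbnrr_pipeline
    ):
        g = pbnrr_pipeline["truth_vertex_disp"]
        e_nem = np.linalg.norm(nemnrr_no_cavity.U - g, axis=1).mean()
        e_pb = np.linalg.norm(pbnrr_pipeline["result"].U - g, axis=1).mean()
        pre = np.linalg.norm(g, axis=1).mean()
        assert e_nem < pre          # it does register
        assert e_nem < 2.0 * e_pb   # and is in PBNRR's accuracy class

    def test_cavity_volume_recovered(self, resection_case):
        res = resection_case["result"]
        mesh = resection_case["mesh"]
        vols = mesh.volumes()
        v_rem = sum(vols[t] for t in res.extras["m_rem"])
        v_sphere = 4.0 / 3.0 * np.pi * 8.0**3
        assert abs(v_rem - v_sphere) / v_sphere <= 0.3

    def test_m_rem_growth_monotone(self, resection_case):
        hist = [h["m_rem"] for h in res_hist(resection_case)]
        assert all(b >= a for a, b in zip(hist, hist[1:]))
        assert len(hist) <= resection_case["cfg"].outer_max

    def test_inner_em_objective_monotone(self, resection_case):
        for trace in resection_case["result"].extras["cost_trace"]:
            for a, b in zip(trace, trace[1:]):
                assert b <= a + 1e-9 * abs(a)


def res_hist(case):
    return case["result"].extras["m_rem_history"]
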