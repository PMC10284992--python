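"""Dynamic term assembly and the constrained least-squares frame solve."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from meshflow import (
    FlowStatus,
    FrameInput,
    MeshDeformationModel,
    OcclusionConstraintSet,
    SceneFlowField,
    SolverError,
    SyntheticScenario,
    build_differential_edge_matrix,
    build_dynamic_term,
    compute_delta_coordinates,
    ingest_scene_flow,
    naive_update,
    solve_frame,
)
from meshflow.meshopt import MeshOptimizationProblem
from meshflow.synthetic import _grid_mesh
from conftest import random_surface_mesh


def qp_oracle(A, b, lower):
    """Exhaustive active-set enumeration for min ||Ax-b||^2 s.t. x >= lower.

    Solves the equality-constrained problem for every subset of the bounds,
    keeps feasible candidates, and returns the one with the lowest
    objective.  Exponential but exact; only for tiny problems.
    """
    A = np.asarray(A)
    n = A.shape[1]
    bounded = np.flatnonzero(np.isfinite(lower))
    best_x, best_f = None, np.inf
    for r in range(len(bounded) + 1):
        for combo in itertools.combinations(bounded, r):
            fixed = np.array(combo, dtype=int)
            free = np.setdiff1d(np.arange(n), fixed)
            x = np.empty(n)
            x[fixed] = lower[fixed]
            rhs = b - A[:, fixed] @ x[fixed] if len(fixed) else b
            if len(free):
                sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
                x[free] = sol
            if np.all(x[bounded] >= lower[bounded] - 1e-9):
                f = np.sum((A @ x - b) ** 2)
                if f < best_f - 1e-12:
                    best_f, best_x = f, x.copy()
    return best_x


def random_problem(seed, force_violation=True):
    """Small random frame problem with occlusion bounds on a random subset."""
    rng = np.random.default_rng(seed)
    mesh = random_surface_mesh(seed, n=int(rng.integers(12, 30)))
    n = mesh.n_vertices
    n_valid = int(rng.integers(max(2, n // 4), n))
    valid = np.sort(rng.choice(n, size=n_valid, replace=False))
    status = np.full(n, FlowStatus.STRAIN_OUTLIER, dtype=np.int8)
    status[valid] = FlowStatus.VALID
    flow = SceneFlowField(rng.normal(scale=0.5, size=(n, 3)), status)
    I_tilde, c_star = build_dynamic_term(mesh.vertices, flow)
    E = build_differential_edge_matrix(mesh.edges, n)
    delta = compute_delta_coordinates(E, mesh.vertices)
    n_occ = int(rng.integers(1, min(8, n)))
    occ = np.sort(rng.choice(n, size=n_occ, replace=False))
    base_z = mesh.vertices[occ, 2]
    # bounds straddling the unconstrained solution so some become active
    p_z = base_z + rng.uniform(-1.0, 1.0 if force_violation else 0.0, size=n_occ)
    problem = MeshOptimizationProblem(
        I_tilde=I_tilde, c_star=c_star, S=E, delta=delta,
        alpha=float(rng.uniform(1.0, 2.0)), c_prev=mesh.vertices,
        occlusion=OcclusionConstraintSet(occ, p_z),
        component_labels=mesh.component_labels(),
    )
    return mesh, problem


class TestDynamicTerm:
    def test_identity_when_all_valid_zero_flow(self):
        c = np.arange(12, dtype=float).reshape(4, 3)
        flow = ingest_scene_flow(np.zeros((4, 3)))
        I_tilde, c_star = build_dynamic_term(c, flow)
        assert np.array_equal(I_tilde.toarray(), np.eye(4))
        np.testing.assert_array_equal(c_star, c)

    def test_selector_layout(self):
        c = np.zeros((3, 3))
        status = np.array([0, 1, 0], dtype=np.int8)  # valid {0, 2}
        flow = SceneFlowField(np.zeros((3, 3)), status)
        I_tilde, _ = build_dynamic_term(c, flow)
        assert np.array_equal(I_tilde.toarray(), [[1, 0, 0], [0, 0, 1]])

    @pytest.mark.parametrize("seed", range(5))
    def test_targets_match_elementwise_addition(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        c = rng.normal(size=(n, 3))
        status = (rng.random(n) < 0.4).astype(np.int8)  # 1 = VACANT
        status[0] = 0
        flow = SceneFlowField(rng.normal(size=(n, 3)), status)
        I_tilde, c_star = build_dynamic_term(c, flow)
        valid = np.flatnonzero(status == 0)
        for r, i in enumerate(valid):
            np.testing.assert_array_equal(c_star[r], c[i] + flow.vectors[i])

    def test_no_valid_vertices_raises(self):
        flow = SceneFlowField(np.zeros((4, 3)),
                              np.full(4, FlowStatus.VACANT, dtype=np.int8))
        with pytest.raises(SolverError):
            build_dynamic_term(np.zeros((4, 3)), flow)


class TestSolveFrame:
    def test_uniform_translation_exact(self):
        mesh = _grid_mesh(SyntheticScenario(nx=15, ny=15, n_frames=2))
        t = np.array([0.7, -0.4, 1.3])
        flow = ingest_scene_flow(np.tile(t, (mesh.n_vertices, 1)))
        model = MeshDeformationModel(mesh, alpha=1.5)
        fit = model.fit_frame(mesh.vertices, FrameInput(flow=flow),
                              apply_filter=False)
        assert np.abs(fit.positions - (mesh.vertices + t)).max() < 1e-8

    def test_large_alpha_consistent_system(self):
        mesh = random_surface_mesh(3, n=25)
        flow = ingest_scene_flow(np.zeros((mesh.n_vertices, 3)))
        model = MeshDeformationModel(mesh, alpha=50.0)
        fit = model.fit_frame(mesh.vertices, FrameInput(flow=flow),
                              apply_filter=False)
        assert np.abs(fit.positions - mesh.vertices).max() < 1e-8

    def test_inactive_bounds_match_unconstrained(self):
        mesh, problem = random_problem(11)
        # push all bounds far below any plausible z: never active
        problem.occlusion = OcclusionConstraintSet(
            problem.occlusion.indices,
            np.full(problem.occlusion.n, -1e6),
        )
        c_bounded = solve_frame(problem)
        problem.occlusion = OcclusionConstraintSet.empty()
        c_free = solve_frame(problem)
        np.testing.assert_allclose(c_bounded, c_free, atol=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_bounds_satisfied_and_kkt(self, seed):
        _, problem = random_problem(seed)
        c = solve_frame(problem)
        lb = problem.occlusion.lower_bounds(len(c))
        assert np.all(c[:, 2] >= lb - 1e-9)
        # KKT: multipliers of active bounds are non-negative
        A = sp.vstack([problem.I_tilde, problem.alpha * problem.S])
        bz = np.concatenate([problem.c_star[:, 2],
                             problem.alpha * problem.delta[:, 2]])
        grad = A.T @ (A @ c[:, 2] - bz)
        active = np.isfinite(lb) & (c[:, 2] <= lb + 1e-9)
        assert np.all(grad[active] >= -1e-7)
        assert np.abs(grad[~active]).max() < 1e-7

    def test_frozen_component_carried_at_previous(self):
        # two islands; only the first has valid vertices
        v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                      [5, 5, 5], [6, 5, 5], [5, 6, 5]])
        mesh_faces = np.array([[0, 1, 2], [3, 4, 5]])
        from meshflow import TriangleMesh

        mesh = TriangleMesh(v, mesh_faces)
        status = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
        flow = SceneFlowField(np.tile([1.0, 0, 0], (6, 1)), status)
        model = MeshDeformationModel(mesh, alpha=1.0)
        fit = model.fit_frame(v, FrameInput(flow=flow), apply_filter=False)
        np.testing.assert_allclose(fit.positions[:3], v[:3] + [1, 0, 0], atol=1e-9)
        np.testing.assert_array_equal(fit.positions[3:], v[3:])

    def test_separability_without_active_bounds(self):
        """Identical per-column operator: xyz solved jointly == independently."""
        _, problem = random_problem(21)
        problem.occlusion = OcclusionConstraintSet.empty()
        c = solve_frame(problem)
        A = sp.vstack([problem.I_tilde, problem.alpha * problem.S]).toarray()
        for col in range(3):
            b = np.concatenate([problem.c_star[:, col],
                                problem.alpha * problem.delta[:, col]])
            ref, *_ = np.linalg.lstsq(A, b, rcond=None)
            np.testing.assert_allclose(c[:, col], ref, atol=1e-8)


class TestRunSequence:
    def test_zero_flow_sequence_static(self):
        mesh = _grid_mesh(SyntheticScenario(nx=12, ny=12, n_frames=2))
        frames = [FrameInput(flow=ingest_scene_flow(np.zeros((mesh.n_vertices, 3))))
                  for _ in range(5)]
        model = MeshDeformationModel(mesh)
        res = model.run_sequence(frames, apply_filter=False)
        for m in res.meshes:
            assert np.abs(m.vertices - mesh.vertices).max() < 1e-8

    def test_noiseless_indentation_tracked(self):
        """With exact flow the error stays well below the deformation and
        shrinks as the smoothness weight decreases (dynamic term exact)."""
        s = SyntheticScenario(nx=25, ny=25, sigma_n=0.0, p_out=0.0,
                              occluder=False, vacant_margin=0, seed=0)
        from meshflow import generate_sequence

        seq = generate_sequence(s)
        errs = {}
        for alpha in (1.5, 0.1):
            model = MeshDeformationModel(seq.mesh0, alpha=alpha)
            res = model.run_sequence(seq.frames, apply_filter=False)
            err = res.meshes[-1].vertices - seq.true_vertices[-1]
            errs[alpha] = np.linalg.norm(err, axis=1).mean()
        # smoothness bias only: mean error a small fraction of the 5 mm
        # indentation, vanishing ~alpha^2 as the weight is reduced
        assert errs[1.5] < 0.15 * s.max_depth
        assert errs[0.1] < errs[1.5] / 20

    def test_occluded_z_respects_bounds_every_frame(self, default_recovery):
        for fit in default_recovery.fits[1:]:
            if fit.occlusion.n == 0:
                continue
            z = fit.positions[fit.occlusion.indices, 2]
            assert np.all(z >= fit.occlusion.p_z + fit.occlusion.delta - 1e-9)

    def test_failed_frame_skipped_with_carry_forward(self):
        mesh = _grid_mesh(SyntheticScenario(nx=8, ny=8, n_frames=2))
        n = mesh.n_vertices
        good = FrameInput(flow=ingest_scene_flow(np.zeros((n, 3))))
        dead = FrameInput(flow=SceneFlowField(
            np.zeros((n, 3)), np.full(n, FlowStatus.VACANT, dtype=np.int8)))
        model = MeshDeformationModel(mesh)
        res = model.run_sequence([good, dead, good], apply_filter=False)
        assert res.skipped == [2]
        assert np.array_equal(res.meshes[2].vertices, res.meshes[1].vertices)
        assert len(res.meshes) == 4

    def test_alpha_tradeoff_monotone(self, default_sequence):
        """Dynamic residual grows and smoothness residual falls with alpha."""
        seq = default_sequence
        dyn, smo = [], []
        for alpha in (1.0, 1.5, 2.0):
            model = MeshDeformationModel(seq.mesh0, alpha=alpha)
            fit = model.fit_frame(seq.mesh0.vertices, seq.frames[0])
            dyn.append(fit.dynamic_residual)
            smo.append(fit.smoothness_residual)
        assert dyn[0] < dyn[1] < dyn[2]
        assert smo[0] > smo[1] > smo[2]

    def test_summary_mentions_frames(self, default_recovery):
        text = default_recovery.summary()
        assert "frames" in text and "smoothness" in text


class TestNaiveUpdate:
    def test_moves_all_observed_vertices(self):
        c = np.zeros((4, 3))
        status = np.array([0, 1, 2, 3], dtype=np.int8)  # VACANT stays put
        flow = SceneFlowField(np.ones((4, 3)), status)
        out = naive_update(c, flow)
        assert np.array_equal(out[1], [0, 0, 0])
        for i in (0, 2, 3):
            assert np.array_equal(out[i], [1, 1, 1])
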