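"""VWLS gradients, strain tensors, and outlier filtering."""

import numpy as np
import pytest

from meshflow import (
    FilterConfig,
    FlowStatus,
    SceneFlowField,
    TriangleMesh,
    estimate_gradient_vwls,
    filter_scene_flow,
    ingest_scene_flow,
    strain_from_gradient,
)
from meshflow.strainfilter import compute_strain_field
from conftest import random_surface_mesh


class TestVWLSGradient:
    def test_uniform_translation_gives_zero_gradient(self):
        mesh = random_surface_mesh(0, n=30, z_scale=1.0)
        flow = ingest_scene_flow(np.tile([0.5, -0.2, 1.0], (mesh.n_vertices, 1)))
        g = estimate_gradient_vwls(5, mesh, flow)
        assert g is not None
        assert np.abs(g).max() < 1e-10

    def test_linear_field_recovered_exactly(self):
        mesh = random_surface_mesh(1, n=30, z_scale=1.0)
        u = 0.1 * mesh.vertices[:, 0]
        flow = ingest_scene_flow(np.column_stack([u, 0 * u, 0 * u]))
        g = estimate_gradient_vwls(7, mesh, flow)
        expected = np.zeros((3, 3))
        expected[0, 0] = 0.1
        np.testing.assert_allclose(g, expected, atol=1e-10)

    def test_collinear_neighborhood_undetermined(self):
        # valid connectivity but all vertices on one spatial line
        n = 10
        vertices = np.column_stack([np.arange(n, dtype=float),
                                    np.zeros(n), np.zeros(n)])
        faces = np.array([[i, i + 1, i + 2] for i in range(n - 2)])
        mesh = TriangleMesh(vertices, faces)
        flow = ingest_scene_flow(np.zeros((n, 3)))
        assert estimate_gradient_vwls(4, mesh, flow) is None

    def test_too_few_neighbors_undetermined(self):
        mesh = random_surface_mesh(2, n=30)
        status = np.full(mesh.n_vertices, FlowStatus.VACANT, dtype=np.int8)
        status[3] = FlowStatus.VALID
        flow = SceneFlowField(np.zeros((mesh.n_vertices, 3)), status)
        assert estimate_gradient_vwls(3, mesh, flow) is None


class TestStrainFromGradient:
    def test_zero_gradient(self):
        st = strain_from_gradient(np.zeros((3, 3)))
        assert st.eps_max == 0.0
        assert np.all(st.principal == 0.0)

    def test_pure_shear_analytic(self):
        g = np.zeros((3, 3))
        g[0, 1] = 0.2  # du/dy
        st = strain_from_gradient(g)
        assert st.eps[0, 1] == st.eps[1, 0] == pytest.approx(0.1)
        np.testing.assert_allclose(st.principal, [0.1, 0.0, -0.1], atol=1e-12)
        assert st.eps_max == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_eigenvalues_match_characteristic_polynomial(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=(3, 3))
        st = strain_from_gradient(g)
        e = st.eps
        # cubic characteristic polynomial coefficients (independent oracle)
        c2 = -np.trace(e)
        c1 = 0.5 * (np.trace(e) ** 2 - np.trace(e @ e))
        c0 = -np.linalg.det(e)
        roots = np.sort(np.roots([1.0, c2, c1, c0]).real)[::-1]
        np.testing.assert_allclose(st.principal, roots, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_added_rotation(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=(3, 3))
        w = rng.normal(size=(3, 3))
        skew = 0.5 * (w - w.T)
        st0 = strain_from_gradient(g)
        st1 = strain_from_gradient(g + skew)
        np.testing.assert_allclose(st0.eps, st1.eps, atol=1e-12)
        assert abs(st0.eps_max - st1.eps_max) < 1e-12

    def test_nonfinite_rejected(self):
        g = np.zeros((3, 3))
        g[1, 1] = np.inf
        with pytest.raises(ValueError):
            strain_from_gradient(g)


class TestAffineExactness:
    """VWLS reproduces any affine displacement field to machine precision."""

    def test_random_affine_fields(self):
        mesh = random_surface_mesh(4, n=40, z_scale=1.0)
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            G = rng.normal(scale=0.3, size=(3, 3))
            c = rng.normal(size=3)
            vec = mesh.vertices @ G.T + c
            flow = ingest_scene_flow(vec)
            i = int(rng.integers(mesh.n_vertices))
            g = estimate_gradient_vwls(i, mesh, flow)
            if g is None:  # boundary vertex with thin neighbourhood
                continue
            worst = max(worst, np.abs(g - G).max())
        assert worst < 1e-9


class TestFilter:
    def _smooth_setup(self, seed=0):
        mesh = random_surface_mesh(seed, n=60, z_scale=1.0)
        # gentle smooth field: strain ~0.02 everywhere
        v = mesh.vertices
        vec = np.column_stack([0.02 * v[:, 0], -0.01 * v[:, 1], 0.015 * v[:, 2]])
        return mesh, vec

    def test_smooth_field_all_valid(self):
        mesh, vec = self._smooth_setup()
        flow = ingest_scene_flow(vec)
        filtered, strains = filter_scene_flow(mesh, flow)
        assert np.all(filtered.status == FlowStatus.VALID)
        assert np.nanmax(strains.score) <= 0.1

    def test_gross_spike_flagged(self):
        mesh, vec = self._smooth_setup()
        h = mesh.mean_edge_length()
        vec = vec.copy()
        vec[10] += np.array([0.0, 0.0, 8 * h])  # gross local inconsistency
        filtered, strains = filter_scene_flow(mesh, ingest_scene_flow(vec))
        assert filtered.status[10] == FlowStatus.STRAIN_OUTLIER
        assert strains.score[10] > 1.0
        # vectors are preserved, only statuses change
        np.testing.assert_array_equal(filtered.vectors, vec)

    def test_instrument_mask_takes_precedence(self):
        mesh, vec = self._smooth_setup()
        vec = vec.copy()
        vec[5] = 0.0  # perfectly benign flow
        mask = np.zeros(mesh.n_vertices, dtype=bool)
        mask[5] = True
        filtered, _ = filter_scene_flow(mesh, ingest_scene_flow(vec), mask)
        assert filtered.status[5] == FlowStatus.INSTRUMENT

    def test_vacant_preserved(self):
        mesh, vec = self._smooth_setup()
        status = np.zeros(mesh.n_vertices, dtype=np.int8)
        status[7] = FlowStatus.VACANT
        filtered, _ = filter_scene_flow(mesh, SceneFlowField(vec, status))
        assert filtered.status[7] == FlowStatus.VACANT

    def test_idempotent_on_default_scenario(self, default_sequence):
        seq = default_sequence
        frame = seq.frames[2]
        once, _ = filter_scene_flow(seq.mesh0, frame.flow,
                                    frame.instrument_vertex_mask)
        twice, _ = filter_scene_flow(seq.mesh0, once,
                                     frame.instrument_vertex_mask)
        assert np.array_equal(once.status, twice.status)
        assert np.array_equal(once.vectors, twice.vectors)

    def test_isolated_vertex_is_conservatively_rejected(self):
        mesh, vec = self._smooth_setup()
        status = np.full(mesh.n_vertices, FlowStatus.VACANT, dtype=np.int8)
        status[12] = FlowStatus.VALID  # no usable neighbours -> undetermined
        filtered, _ = filter_scene_flow(mesh, SceneFlowField(vec, status))
        assert filtered.status[12] == FlowStatus.STRAIN_OUTLIER


class TestOperatingCharacteristics:
    """Consistency-hypothesis check at small scale: gross outliers injected
    into a smooth field are caught without sacrificing clean vertices."""

    def test_injected_outliers_detected(self):
        mesh = random_surface_mesh(7, n=200, z_scale=1.0)
        rng = np.random.default_rng(7)
        v = mesh.vertices
        vec = np.column_stack([0.01 * v[:, 0], 0.01 * v[:, 1], -0.02 * v[:, 2]])
        h = mesh.mean_edge_length()
        inj = rng.choice(mesh.n_vertices, size=20, replace=False)
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        vec[inj] = 6 * h * dirs
        filtered, _ = filter_scene_flow(mesh, ingest_scene_flow(vec))
        flagged = filtered.status == FlowStatus.STRAIN_OUTLIER
        assert flagged[inj].mean() >= 0.95
        clean = np.setdiff1d(np.arange(mesh.n_vertices), inj)
        assert flagged[clean].mean() <= 0.05
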