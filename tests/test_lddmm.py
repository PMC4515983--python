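"""Geodesic shooting, current-norm data term, surface matching, label transport."""

import numpy as np
import pytest

from mtlshape.lddmm import (
    Deformation,
    IntegrationError,
    KernelParams,
    _backprop,
    _field,
    _field_vjp,
    _mismatch_value_grad,
    current_mismatch,
    current_representation,
    deformed_mesh,
    kernel_matrix,
    match_surfaces,
    shoot,
    transport_labels,
)
from mtlshape.mesh import LabelMap, log_surface_jacobian
from mtlshape.synthetic import icosphere

RNG = np.random.default_rng(42)
PARAMS = KernelParams(sigma_v=8.0, sigma_w=4.0, lam=50.0, n_timesteps=10)


class TestKernel:
    def test_diagonal_is_one(self):
        pts = RNG.normal(size=(5, 3))
        K = kernel_matrix(pts, pts, 2.0)
        assert np.allclose(np.diag(K), 1.0)

    def test_one_sigma_separation(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[1.5, 0, 0]])
        assert np.isclose(kernel_matrix(a, b, 1.5)[0, 0], np.exp(-1.0))

    def test_positive_semidefinite(self):
        pts = RNG.normal(size=(5, 3)) * 3
        K = kernel_matrix(pts, pts, 2.0)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            kernel_matrix(np.zeros((1, 3)), np.zeros((1, 3)), 0.0)


class TestShoot:
    def test_zero_momentum_is_identity_flow(self):
        q0 = RNG.normal(size=(6, 3))
        defo = shoot(q0, np.zeros_like(q0), PARAMS)
        assert np.allclose(defo.final_vertices, q0)
        assert np.allclose(defo.trajectory_q, q0[None])

    def test_single_particle_travels_straight(self):
        # self-interaction gradient vanishes: q(t) = q0 + t k(0) p0 = q0 + t p0
        q0 = np.array([[1.0, -2.0, 0.5]])
        p0 = np.array([[0.3, 0.1, -0.2]])
        defo = shoot(q0, p0, KernelParams(sigma_v=2.0, n_timesteps=7))
        assert np.allclose(defo.final_vertices, q0 + p0, atol=1e-12)
        assert np.allclose(defo.trajectory_q[3], q0 + (3 / 7) * p0, atol=1e-12)

    def test_energy_conserved_and_refines(self):
        q0 = RNG.normal(size=(10, 3)) * 2
        p0 = RNG.normal(size=(10, 3)) * 0.5
        ke20 = shoot(q0, p0, KernelParams(sigma_v=1.5, n_timesteps=20)).kinetic_energy
        drift20 = (ke20.max() - ke20.min()) / ke20[0]
        assert drift20 < 0.01
        ke80 = shoot(q0, p0, KernelParams(sigma_v=1.5, n_timesteps=80)).kinetic_energy
        drift80 = (ke80.max() - ke80.min()) / ke80[0]
        assert drift80 < drift20 / 4  # at least the integrator's order

    def test_nonfinite_state_reported(self):
        q0 = np.zeros((2, 3))
        p0 = np.full((2, 3), 1e200)
        with pytest.raises((IntegrationError, FloatingPointError)):
            with np.errstate(over="raise", invalid="raise"):
                shoot(q0, p0, KernelParams(sigma_v=1.0, n_timesteps=5))


class TestAdjointGradients:
    def test_field_vjp_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(6, 3))
        p = rng.normal(size=(6, 3)) * 0.3
        aq = rng.normal(size=(6, 3))
        ap = rng.normal(size=(6, 3))
        sigma = 1.5
        gq, gp = _field_vjp(q, p, sigma, aq, ap)

        def val(q_, p_):
            dq, dp = _field(q_, p_, sigma)
            return (aq * dq).sum() + (ap * dp).sum()

        eps = 1e-6
        for arr, grad in [(q, gq), (p, gp)]:
            fd = np.zeros_like(arr)
            for i in range(arr.shape[0]):
                for d in range(3):
                    pert = arr.copy()
                    pert[i, d] += eps
                    fd[i, d] = ((val(pert, p) if arr is q else val(q, pert))
                                - val(q, p)) / eps
            assert np.abs(grad - fd).max() < 1e-5

    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        q0 = rng.normal(size=(5, 3))
        p0 = rng.normal(size=(5, 3)) * 0.3
        w = rng.normal(size=(5, 3))
        params = KernelParams(sigma_v=1.5, n_timesteps=8)

        def loss(p):
            return (w * shoot(q0, p, params).trajectory_q[-1]).sum()

        g = _backprop(shoot(q0, p0, params), {params.n_timesteps: w})
        eps = 1e-6
        fd = np.zeros_like(p0)
        for i in range(5):
            for d in range(3):
                pert = p0.copy()
                pert[i, d] += eps
                fd[i, d] = (loss(pert) - loss(p0)) / eps
        assert np.abs(g - fd).max() < 1e-5

    def test_mismatch_gradient_matches_finite_differences(self):
        mesh = icosphere(0, radius=1.0)
        tgt = icosphere(0, radius=0.9)
        tc, tn = current_representation(tgt)
        E, G = _mismatch_value_grad(mesh.vertices, mesh.faces, tc, tn, 1.0)
        assert np.isclose(E, current_mismatch(mesh, tgt, 1.0))
        eps = 1e-6
        fd = np.zeros_like(mesh.vertices)
        for i in range(mesh.n_vertices):
            for d in range(3):
                v = mesh.vertices.copy()
                v[i, d] += eps
                fd[i, d] = (_mismatch_value_grad(v, mesh.faces, tc, tn, 1.0)[0] - E) / eps
        assert np.abs(G - fd).max() < 1e-5


class TestCurrentMismatch:
    def test_identical_meshes_zero(self, sphere):
        assert current_mismatch(sphere, sphere, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_orientation_reversal(self, sphere):
        flipped = sphere.copy()
        flipped.faces = flipped.faces[:, [0, 2, 1]]
        # mu_b = -mu_a, so E = |2 mu_a|^2 = 4 |mu_a|^2
        c, n = current_representation(sphere)
        norm_sq = np.einsum("ab,ab->", kernel_matrix(c, c, 4.0), n @ n.T)
        assert np.isclose(current_mismatch(sphere, flipped, 4.0), 4 * norm_sq,
                          rtol=1e-10)

    def test_distant_surfaces_sum_of_norms(self):
        a = icosphere(0, 1.0)
        b = a.with_vertices(a.vertices + np.array([200.0, 0, 0]))
        sigma = 1.0
        e = current_mismatch(a, b, sigma)
        ca, na = current_representation(a)
        norm_a = np.einsum("ab,ab->", kernel_matrix(ca, ca, sigma), na @ na.T)
        cb, nb = current_representation(b)
        norm_b = np.einsum("ab,ab->", kernel_matrix(cb, cb, sigma), nb @ nb.T)
        assert abs(e - (norm_a + norm_b)) < 1e-6 * e

    def test_rigid_invariance(self, sphere):
        from conftest import perturbed_mesh

        other = perturbed_mesh(sphere, seed=3)
        theta = 0.6
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t = np.array([5.0, 1.0, -3.0])
        e0 = current_mismatch(sphere, other, 4.0)
        e1 = current_mismatch(sphere.with_vertices(sphere.vertices @ R.T + t),
                              other.with_vertices(other.vertices @ R.T + t), 4.0)
        assert np.isclose(e0, e1, rtol=1e-9)

    def test_triangle_type_bound(self):
        # ||mu_a - mu_c|| <= ||mu_a - mu_b|| + ||mu_b - mu_c|| on a test triple
        a = icosphere(0, 1.0)
        b = icosphere(0, 0.9)
        c = icosphere(0, 0.8)
        dab = np.sqrt(current_mismatch(a, b, 1.0))
        dbc = np.sqrt(current_mismatch(b, c, 1.0))
        dac = np.sqrt(current_mismatch(a, c, 1.0))
        assert dac <= dab + dbc + 1e-12


class TestMatchSurfaces:
    def test_identity_returns_zero_momentum(self, sphere):
        defo = match_surfaces(sphere, sphere, PARAMS)
        assert np.allclose(defo.p0, 0.0)

    def test_translation_recovered(self, sphere):
        shift = np.array([0.5 * PARAMS.sigma_v, 0.0, 0.0])
        target = sphere.with_vertices(sphere.vertices + shift)
        defo = match_surfaces(sphere, target, PARAMS)
        e0 = current_mismatch(sphere, target, PARAMS.sigma_w)
        e1 = current_mismatch(deformed_mesh(sphere, defo), target, PARAMS.sigma_w)
        assert e1 <= 0.05 * e0  # mismatch reduced by >= 95%
        disp = defo.final_vertices - sphere.vertices
        assert disp[:, 0].std() / disp[:, 0].mean() < 0.1

    def test_uniform_shrink_jacobian(self, sphere):
        target = sphere.with_vertices(sphere.vertices * 0.9)
        defo = match_surfaces(sphere, target, PARAMS)
        j = log_surface_jacobian(sphere, deformed_mesh(sphere, defo))
        assert abs(j.mean() - np.log(0.81)) <= 0.15 * abs(np.log(0.81))

    def test_multi_target_time_series(self, sphere):
        # two targets along a shrinking trajectory; the match tracks both
        t1 = sphere.with_vertices(sphere.vertices * 0.97)
        t2 = sphere.with_vertices(sphere.vertices * 0.94)
        defo = match_surfaces(sphere, [t1, t2], PARAMS)
        mid = sphere.with_vertices(defo.trajectory_q[PARAMS.n_timesteps // 2])
        assert current_mismatch(mid, t1, PARAMS.sigma_w) < current_mismatch(
            sphere, t1, PARAMS.sigma_w)
        final = deformed_mesh(sphere, defo)
        assert current_mismatch(final, t2, PARAMS.sigma_w) < 0.05 * current_mismatch(
            sphere, t2, PARAMS.sigma_w)

    def test_deformation_archive_roundtrip(self, sphere, tmp_path):
        target = sphere.with_vertices(sphere.vertices * 0.95)
        defo = match_surfaces(sphere, target, PARAMS)
        path = tmp_path / "defo.h5"
        defo.save(path)
        back = Deformation.load(path)
        assert np.allclose(back.p0, defo.p0)
        assert np.allclose(back.trajectory_q, defo.trajectory_q)
        assert back.params.sigma_v == PARAMS.sigma_v


class TestTransportLabels:
    def test_identity_keeps_labels(self, sphere):
        labels = LabelMap(np.arange(sphere.n_vertices) % 3, {0: "a", 1: "b", 2: "c"})
        defo = shoot(sphere.vertices, np.zeros_like(sphere.vertices), PARAMS)
        out = transport_labels(sphere, labels, defo, sphere)
        assert np.array_equal(out.labels, labels.labels)

    def test_single_label_is_preserved(self, sphere):
        labels = LabelMap(np.zeros(sphere.n_vertices, dtype=int), {0: "only"})
        p0 = RNG.normal(size=(sphere.n_vertices, 3)) * 0.3
        defo = shoot(sphere.vertices, p0, PARAMS)
        out = transport_labels(sphere, labels, defo, sphere)
        assert (out.labels == 0).all()

    def test_hemisphere_boundary_after_rotation(self):
        atlas = icosphere(2, radius=10.0)
        labels = LabelMap((atlas.vertices[:, 2] >= 0).astype(int), {0: "south", 1: "north"})
        theta = np.deg2rad(20.0)
        R = np.array([[1, 0, 0], [0, np.cos(theta), -np.sin(theta)],
                      [0, np.sin(theta), np.cos(theta)]])
        target = atlas.with_vertices(atlas.vertices @ R.T)
        defo = match_surfaces(atlas, target, KernelParams(sigma_v=8.0, sigma_w=4.0,
                                                          lam=100.0, n_timesteps=10))
        out = transport_labels(atlas, labels, defo, target)
        truth = (target.vertices @ R[:, 2] >= 0).astype(int)  # rotated hemisphere
        edge = np.median(np.linalg.norm(
            atlas.vertices[atlas.faces[:, 0]] - atlas.vertices[atlas.faces[:, 1]], axis=1))
        dist_to_boundary = np.abs(target.vertices @ R[:, 2])
        wrong = out.labels != truth
        assert not np.any(wrong & (dist_to_boundary > 2 * edge))

    def test_empty_labels_rejected(self, sphere):
        defo = shoot(sphere.vertices, np.zeros_like(sphere.vertices), PARAMS)
        with pytest.raises(ValueError, match="empty"):
            transport_labels(sphere, LabelMap(np.empty(0, dtype=int), {}), defo, sphere)
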