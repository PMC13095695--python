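"""Laplace–Beltrami operator, eigenbasis, projection and heat diffusion."""

import numpy as np
import pytest
import scipy.sparse as sp
import trimesh
from scipy.linalg import expm

from morphoforge.mesh_core import MeshValidationError, TriangleMesh
from morphoforge.spectral_geometry import (
    SpectralBasis,
    cotan_laplacian,
    eigenbasis,
    heat_diffuse,
    reconstruct,
    spectral_project,
)


def naive_cotan_assembly(mesh):
    """Independent O(m) per-face assembly of stiffness and lumped mass."""
    n = mesh.n_vertices
    L = np.zeros((n, n))
    M = np.zeros(n)
    for tri in mesh.faces:
        pts = mesh.vertices[tri]
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        for c in range(3):
            i, j, k = tri[(c + 1) % 3], tri[(c + 2) % 3], tri[c]
            u = mesh.vertices[i] - mesh.vertices[k]
            w = mesh.vertices[j] - mesh.vertices[k]
            cot = np.dot(u, w) / np.linalg.norm(np.cross(u, w))
            L[i, j] -= 0.5 * cot
            L[j, i] -= 0.5 * cot
            L[i, i] += 0.5 * cot
            L[j, j] += 0.5 * cot
            M[tri[c]] += area / 3.0
    return L, M


@pytest.fixture(scope="module")
def sphere_basis(icosphere):
    return eigenbasis(icosphere, 16)


class TestCotanLaplacian:
    def test_flat_unit_square_mass_trace(self):
        V = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        F = np.array([[0, 1, 2], [0, 2, 3]])
        L, M = cotan_laplacian(TriangleMesh(V, F))
        assert abs(M.diagonal().sum() - 1.0) < 1e-9

    def test_constant_in_kernel(self, small_bone):
        L, _ = cotan_laplacian(small_bone)
        assert np.abs(L @ np.ones(small_bone.n_vertices)).max() < 1e-9

    def test_symmetry_and_row_sums(self, small_bone):
        L, M = cotan_laplacian(small_bone)
        assert abs(L - L.T).max() < 1e-10
        assert np.abs(np.asarray(L.sum(axis=1))).max() < 1e-9
        assert (M.diagonal() > 0).all()
        assert abs(M.diagonal().sum() - small_bone.face_areas().sum()) < 1e-8

    def test_matches_naive_per_face_assembly(self):
        ico = trimesh.creation.icosphere(subdivisions=1)
        rng = np.random.default_rng(0)
        V = np.asarray(ico.vertices) + rng.normal(0, 0.02, ico.vertices.shape)
        mesh = TriangleMesh(V, np.asarray(ico.faces))
        L, M = cotan_laplacian(mesh)
        L_ref, M_ref = naive_cotan_assembly(mesh)
        assert np.abs(L.toarray() - L_ref).max() < 1e-10
        assert np.abs(M.diagonal() - M_ref).max() < 1e-10

    def test_nonmanifold_edge_rejected(self):
        V = np.array([[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0],
                      [0.5, 0, 1]], dtype=float)
        F = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge (0,1) in 3 faces
        with pytest.raises(MeshValidationError):
            cotan_laplacian(TriangleMesh(V, F))


class TestEigenbasis:
    def test_unit_sphere_spectrum_l_l_plus_1(self, sphere_basis):
        expected = np.array([2.0] * 3 + [6.0] * 5 + [12.0] * 7)
        got = sphere_basis.eigenvalues[1:16]
        assert np.all(np.abs(got - expected) / expected < 0.05)

    def test_first_eigenpair_constant(self, sphere_basis):
        assert sphere_basis.eigenvalues[0] < 1e-8
        phi0 = sphere_basis.eigenfunctions[:, 0]
        assert phi0.std() / abs(phi0.mean()) < 1e-6

    def test_mass_orthonormality(self, sphere_basis):
        Phi = sphere_basis.eigenfunctions
        G = Phi.T @ (sphere_basis.mass_diag[:, None] * Phi)
        assert np.abs(G - np.eye(sphere_basis.k)).max() < 1e-6

    def test_generalized_eigen_residual(self, sphere_basis):
        L = sphere_basis.stiffness
        Phi = sphere_basis.eigenfunctions
        lhs = L @ Phi
        rhs = sphere_basis.mass_diag[:, None] * Phi * sphere_basis.eigenvalues
        assert np.abs(lhs - rhs).max() / max(np.abs(lhs).max(), 1) < 1e-5

    def test_deterministic_sign_and_repeatability(self, small_bone):
        b1 = eigenbasis(small_bone, 12)
        b2 = eigenbasis(small_bone, 12)
        assert np.allclose(b1.eigenfunctions, b2.eigenfunctions, atol=1e-9)

    def test_rigid_motion_invariance_and_scaling(self, small_bone):
        base = eigenbasis(small_bone, 10)
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        rot = eigenbasis(TriangleMesh(small_bone.vertices @ R.T + 3.0,
                                      small_bone.faces), 10)
        assert np.allclose(base.eigenvalues, rot.eigenvalues, rtol=1e-8)
        scaled = eigenbasis(TriangleMesh(2.0 * small_bone.vertices,
                                         small_bone.faces), 10)
        assert np.allclose(scaled.eigenvalues[1:] * 4.0, base.eigenvalues[1:],
                           rtol=1e-6)

    def test_scaled_helper_matches_recomputation(self, small_bone):
        base = eigenbasis(small_bone, 10)
        scaled = eigenbasis(TriangleMesh(1.5 * small_bone.vertices,
                                         small_bone.faces), 10)
        helper = base.scaled(1.5)
        assert np.allclose(helper.eigenvalues, scaled.eigenvalues, rtol=1e-6)
        assert np.allclose(np.abs(helper.eigenfunctions[:, 1:4]),
                           np.abs(scaled.eigenfunctions[:, 1:4]), atol=1e-5)

    def test_k_must_be_below_n(self, small_bone):
        with pytest.raises(ValueError):
            eigenbasis(small_bone, small_bone.n_vertices)


class TestProjection:
    def test_basis_function_projects_to_unit_vector(self, sphere_basis):
        z = spectral_project(sphere_basis, sphere_basis.eigenfunctions[:, 3])
        e3 = np.zeros(16)
        e3[3] = 1.0
        assert np.abs(z - e3).max() < 1e-8

    def test_constant_projects_onto_first_mode(self, sphere_basis):
        z = spectral_project(sphere_basis, np.full(sphere_basis.n, 2.5))
        assert np.abs(z[1:]).max() < 1e-8 * abs(z[0])

    def test_rank_k_reconstruction_is_l2_optimal(self, sphere_basis):
        rng = np.random.default_rng(1)
        signal = rng.normal(size=sphere_basis.n)
        recon = reconstruct(sphere_basis, spectral_project(sphere_basis, signal))
        w = sphere_basis.mass_diag
        err_opt = np.sum(w * (signal - recon) ** 2)
        Phi = sphere_basis.eigenfunctions
        for _ in range(100):
            alt = Phi @ rng.normal(size=sphere_basis.k)
            assert np.sum(w * (signal - alt) ** 2) >= err_opt - 1e-12

    def test_dimension_mismatch(self, sphere_basis):
        with pytest.raises(ValueError):
            spectral_project(sphere_basis, np.zeros(17))


class TestHeatDiffusion:
    def test_t0_equals_projection(self, sphere_basis):
        rng = np.random.default_rng(2)
        sig = rng.normal(size=(sphere_basis.n, 2))
        out = heat_diffuse(sphere_basis, sig, 0.0)
        ref = reconstruct(sphere_basis, spectral_project(sphere_basis, sig))
        assert np.abs(out - ref).max() < 1e-12

    def test_large_t_limit_is_mass_weighted_mean(self, sphere_basis):
        rng = np.random.default_rng(3)
        sig = rng.normal(size=sphere_basis.n)
        out = heat_diffuse(sphere_basis, sig, 1e6)
        w = sphere_basis.mass_diag
        mean = np.sum(w * sig) / w.sum()
        assert np.abs(out - mean).max() < 1e-8

    def test_mean_conserved_for_all_t(self, sphere_basis):
        rng = np.random.default_rng(4)
        sig = rng.normal(size=sphere_basis.n)
        w = sphere_basis.mass_diag
        m0 = np.sum(w * sig) / w.sum()
        for t in (0.0, 0.01, 0.3, 10.0):
            mt = np.sum(w * heat_diffuse(sphere_basis, sig, t)) / w.sum()
            assert abs(mt - m0) < 1e-9

    def test_semigroup_property(self, sphere_basis):
        rng = np.random.default_rng(5)
        sig = rng.normal(size=sphere_basis.n)
        once = heat_diffuse(sphere_basis, sig, 0.3)
        twice = heat_diffuse(sphere_basis, heat_diffuse(sphere_basis, sig, 0.1), 0.2)
        assert np.abs(once - twice).max() < 1e-8

    def test_delta_matches_dense_expm_oracle(self):
        """Near-full truncation reproduces exp(−t M⁻¹L) to 1e-4."""
        from morphoforge.synthetic_anatomy import generate_template

        mesh = generate_template(200)
        mesh = TriangleMesh(mesh.vertices / np.sqrt(mesh.face_areas().sum()),
                            mesh.faces)
        basis = eigenbasis(mesh, 180)
        L, M = cotan_laplacian(mesh)
        t = 0.1
        delta = np.zeros(mesh.n_vertices)
        delta[7] = 1.0
        dense = expm(-t * np.linalg.inv(M.toarray()) @ L.toarray()) @ delta
        ours = heat_diffuse(basis, delta, t)
        assert np.abs(dense - ours).max() < 1e-4

    def test_negative_time_rejected(self, sphere_basis):
        with pytest.raises(ValueError):
            heat_diffuse(sphere_basis, np.zeros(sphere_basis.n), -1.0)


def test_basis_round_trips_through_disk_cache(tmp_path, small_bone):
    basis = eigenbasis(small_bone, 8)
    basis.save(tmp_path / "basis.npz")
    back = SpectralBasis.load(tmp_path / "basis.npz")
    assert np.allclose(back.eigenvalues, basis.eigenvalues)
    assert np.allclose(back.eigenfunctions, basis.eigenfunctions)
    assert np.abs((back.stiffness - basis.stiffness)).max() < 1e-12
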