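"""Spiral topology, VAE encode/decode, ELBO, sampling and traversal."""

import numpy as np
import pytest
import trimesh
from scipy.stats import spearmanr

from morphoforge.mesh_core import MeshValidationError, TriangleMesh, validate_mesh
from morphoforge.spiral_vae import (
    VaeConfig,
    VaeWeights,
    build_spirals,
    decode,
    elbo_loss,
    encode,
    latent_traverse,
    synthesize,
    train_vae,
)
from morphoforge.synthetic_anatomy import BoneParams, generate_bone, generate_template


class TestBuildSpirals:
    def test_icosahedron_ring_is_full_1_ring(self):
        ico = trimesh.creation.icosahedron()
        mesh = TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        topo = build_spirals(mesh, 6)
        for i in range(12):                # valence 5 everywhere
            row = topo.spirals[i]
            assert row[0] == i
            ring = set(row[1:])
            assert len(ring) == 5 and i not in ring

    def test_valence6_length10_reaches_ring2(self):
        tpl = generate_template(302)
        topo = build_spirals(tpl, 10)
        # BFS oracle for ring membership
        adj = [set() for _ in range(tpl.n_vertices)]
        for a, b, c in tpl.faces:
            adj[a] |= {b, c}
            adj[b] |= {a, c}
            adj[c] |= {a, b}
        i = 50                              # interior valence-6 vertex
        assert len(adj[i]) == 6
        row = topo.spirals[i].tolist()
        assert row[0] == i
        assert set(row[1:7]) == adj[i]      # full 1-ring first
        ring2 = set().union(*(adj[v] for v in adj[i])) - adj[i] - {i}
        assert set(row[7:]).issubset(ring2)

    def test_deterministic(self, template_1083):
        t1 = build_spirals(template_1083, 10)
        t2 = build_spirals(template_1083, 10)
        assert np.array_equal(t1.spirals, t2.spirals)

    def test_padding_repeats_center(self):
        V = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        F = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        topo = build_spirals(TriangleMesh(V, F), 8)
        for i in range(4):
            row = topo.spirals[i]
            assert row[0] == i and set(row[:4]) == {0, 1, 2, 3}
            assert (row[4:] == i).all()     # exhausted → pad with center

    def test_open_mesh_rejected(self):
        V = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        F = np.array([[0, 1, 2], [1, 3, 2]])
        with pytest.raises(MeshValidationError):
            build_spirals(TriangleMesh(V, F), 5)


@pytest.fixture(scope="module")
def tiny_setup():
    tpl = generate_template(152)
    cfg = VaeConfig(channels=16, epochs=2, latent_dim=4, seed=0)
    topo = build_spirals(tpl, cfg.spiral_length)
    w = VaeWeights(cfg, tpl.n_vertices)
    return tpl, topo, w


class TestEncodeDecode:
    def test_zero_weights_zero_posterior(self, tiny_setup):
        tpl, topo, _ = tiny_setup
        w = VaeWeights(VaeConfig(channels=16, latent_dim=4, seed=1), tpl.n_vertices)
        for p in w.parameters():
            p.data[:] = 0.0
        mu, lv = encode(tpl.vertices, topo, w)
        assert np.all(mu == 0) and np.all(lv == 0)

    def test_deterministic(self, tiny_setup):
        tpl, topo, w = tiny_setup
        m1, l1 = encode(tpl.vertices, topo, w)
        m2, l2 = encode(tpl.vertices, topo, w)
        assert np.array_equal(m1, m2) and np.array_equal(l1, l2)
        z = np.array([0.3, -1.0, 0.0, 2.0])
        assert np.array_equal(decode(z, topo, w), decode(z, topo, w))

    def test_relabeling_equivariance(self, tiny_setup):
        """Permuting vertex rows together with spiral indices fixes the output."""
        import copy

        tpl, topo, w = tiny_setup
        rng = np.random.default_rng(0)
        perm = rng.permutation(tpl.n_vertices)   # new vertex j = old perm[j]
        inv = np.argsort(perm)                   # old i → new inv[i]
        coords_p = tpl.vertices[perm]
        spirals_p = inv[topo.spirals[perm]]
        topo_p = type(topo)(spirals=spirals_p,
                            template_faces=inv[topo.template_faces],
                            length=topo.length)
        w_p = copy.deepcopy(w)
        w_p.mean_shape = w.mean_shape[perm] if w.mean_shape.ndim == 2 else w.mean_shape
        mu1, lv1 = encode(tpl.vertices, topo, w)
        mu2, lv2 = encode(coords_p, topo_p, w_p)
        assert np.allclose(mu1, mu2, atol=1e-10)
        assert np.allclose(lv1, lv2, atol=1e-10)

    def test_decode_output_is_valid_template_mesh(self, trained_vae):
        coords = decode(np.zeros(6), trained_vae.topo, trained_vae.weights)
        mesh = TriangleMesh(coords, trained_vae.topo.template_faces)
        rep = validate_mesh(mesh, require_watertight=True)
        assert rep.watertight
        assert mesh.n_faces == 2 * mesh.n_vertices - 4

    def test_nonfinite_latent_rejected(self, tiny_setup):
        _, topo, w = tiny_setup
        with pytest.raises(ValueError):
            decode(np.array([np.nan, 0, 0, 0]), topo, w)


class TestElboLoss:
    def test_zero_at_perfect_reconstruction_standard_posterior(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        total, recon, kl = elbo_loss(x, x, np.zeros(6), np.zeros(6))
        assert total == recon == kl == 0.0

    def test_kl_hand_values(self):
        x = np.zeros((4, 3))
        mu = np.zeros(6)
        mu[0] = 1.0
        _, _, kl = elbo_loss(x, x, mu, np.zeros(6))
        assert abs(kl - 0.5) < 1e-12

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        mu, lv = rng.normal(size=4), rng.normal(size=4)
        total, recon, kl = elbo_loss(a, b, mu, lv, beta=0.9, lambda_kl=0.1)
        recon_ref = sum(abs(a[i, j] - b[i, j]) for i in range(5)
                        for j in range(3)) / 15
        kl_ref = 0.5 * sum(mu[i]**2 + np.exp(lv[i]) - lv[i] - 1 for i in range(4))
        assert abs(recon - recon_ref) < 1e-10
        assert abs(kl - kl_ref) < 1e-10
        assert abs(total - (0.9 * recon_ref + 0.1 * kl_ref)) < 1e-10

    def test_kl_zero_iff_standard_normal(self):
        for mu0 in (-1.0, -0.1, 0.0, 0.1, 1.0):
            for lv0 in (-0.5, 0.0, 0.5):
                _, _, kl = elbo_loss(np.zeros((2, 3)), np.zeros((2, 3)),
                                     np.full(3, mu0), np.full(3, lv0))
                if mu0 == 0.0 and lv0 == 0.0:
                    assert kl == 0.0
                else:
                    assert kl > 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            elbo_loss(np.array([[np.inf, 0, 0]]), np.zeros((1, 3)),
                      np.zeros(2), np.zeros(2))


class TestTraining:
    def test_connectivity_mismatch_rejected(self):
        a = generate_template(152)
        b = generate_template(200)
        with pytest.raises(MeshValidationError):
            train_vae([a, b], VaeConfig(channels=8, epochs=1))

    def test_single_shape_memorization(self):
        """With no KL pressure one shape is reconstructed nearly exactly."""
        tpl = generate_template(152)
        shapes = [tpl.copy(), tpl.copy(), tpl.copy()]
        cfg = VaeConfig(channels=16, epochs=150, batch=3, lr=1e-2,
                        lambda_kl=0.0, latent_dim=2, seed=0)
        w, topo, log = train_vae(shapes, cfg, test_fraction=0.0)
        assert log.epochs[-1]["recon"] < 0.1 * log.epochs[0]["recon"]

    def test_heldout_reconstruction_improves(self, trained_vae):
        first = trained_vae.log.epochs[9]["heldout_recon"]
        last = trained_vae.log.epochs[-1]["heldout_recon"]
        assert last < first

    def test_aggregate_posterior_matches_prior_softly(self, trained_vae):
        mus, sig2 = [], []
        for mesh in trained_vae.meshes:
            mu, lv = encode(mesh.vertices, trained_vae.topo, trained_vae.weights)
            mus.append(mu)
            sig2.append(np.exp(lv))
        mus = np.stack(mus)
        assert np.all(np.abs(mus.mean(axis=0)) <= 0.5)
        assert 0.3 <= float(np.mean(sig2)) <= 1.5


class TestSynthesize:
    def test_counts_connectivity_and_determinism(self, trained_vae):
        s1 = synthesize(trained_vae.weights, trained_vae.topo, 10, seed=3)
        s2 = synthesize(trained_vae.weights, trained_vae.topo, 10, seed=3)
        assert len(s1) == 10
        for a, b in zip(s1, s2):
            assert np.array_equal(a.vertices, b.vertices)
            assert np.array_equal(a.faces, trained_vae.topo.template_faces)

    def test_prior_samples_are_watertight(self, trained_vae):
        for s in synthesize(trained_vae.weights, trained_vae.topo, 20, seed=9):
            assert validate_mesh(s, require_watertight=True).watertight


class TestLatentSemantics:
    def test_traversal_counts_and_zero_value(self, trained_vae):
        w, topo = trained_vae.weights, trained_vae.topo
        out = latent_traverse(w, topo, 0, [0.0])
        assert np.array_equal(out[0].vertices, decode(np.zeros(6), topo, w))
        sweep = latent_traverse(w, topo, 2, np.linspace(-3, 3, 7))
        assert len(sweep) == 7

    def test_parameter_recovery_spearman(self, trained_vae):
        """Each varying generator parameter is recovered by some latent dim."""
        mus = np.stack([encode(m.vertices, trained_vae.topo, trained_vae.weights)[0]
                        for m in trained_vae.meshes])
        for getter in (lambda p: p.length, lambda p: p.bend_curvature):
            vals = np.array([getter(p) for p in trained_vae.params])
            rhos = [abs(spearmanr(vals, mus[:, d]).statistic) for d in range(6)]
            assert max(rhos) >= 0.8

    def test_dim_out_of_range(self, trained_vae):
        with pytest.raises(ValueError):
            latent_traverse(trained_vae.weights, trained_vae.topo, 6, [0.0])
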