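"""Thin-plate splines, the synthetic baseline solid, morphing, deck export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoforge.correspondence import RefinementConfig
from morphoforge.fe_mapping import (
    export_deck,
    farthest_point_subsample,
    map_baseline,
    read_deck,
    synthetic_baseline,
    tps_apply,
    tps_fit,
)
from morphoforge.mesh_core import validate_mesh
from morphoforge.synthetic_anatomy import BoneParams, generate_bone


@pytest.fixture(scope="module")
def controls():
    rng = np.random.default_rng(0)
    return rng.normal(size=(50, 3)) * 50


class TestTps:
    def test_identity_warp(self, controls):
        warp = tps_fit(controls, controls)
        assert np.abs(warp.weights).max() < 1e-8
        assert np.abs(warp.affine - np.hstack([np.zeros((3, 1)), np.eye(3)])).max() < 1e-8
        pts = np.random.default_rng(1).normal(size=(20, 3)) * 30
        assert np.abs(tps_apply(warp, pts) - pts).max() < 1e-8

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=1000))
    def test_affine_reproduction_zero_kernel_weights(self, controls, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3)) + np.eye(3)
        b = rng.normal(size=3) * 10
        warp = tps_fit(controls, controls @ A.T + b)
        assert np.abs(warp.weights).max() < 1e-8
        grid = rng.normal(size=(30, 3)) * 40
        assert np.abs(tps_apply(warp, grid) - (grid @ A.T + b)).max() < 1e-6

    def test_random_deformation_interpolates_controls(self, controls):
        rng = np.random.default_rng(3)
        targets = controls + rng.normal(0, 3, controls.shape)
        warp = tps_fit(controls, targets)
        assert np.abs(tps_apply(warp, controls) - targets).max() < 1e-6
        # side conditions
        assert np.abs(warp.weights.sum(axis=0)).max() < 1e-8
        moment = np.einsum("ci,cj->ij", warp.weights, warp.control_points)
        assert np.abs(moment).max() < 1e-6

    def test_matches_dense_solve_oracle(self, controls):
        rng = np.random.default_rng(4)
        targets = controls + rng.normal(0, 2, controls.shape)
        warp = tps_fit(controls, targets)
        # independent assembly of the bordered system
        n = len(controls)
        K = np.linalg.norm(controls[:, None] - controls[None], axis=-1)
        P = np.hstack([np.ones((n, 1)), controls])
        A = np.block([[K, P], [P.T, np.zeros((4, 4))]])
        sol = np.linalg.solve(A, np.vstack([targets, np.zeros((4, 3))]))
        assert np.abs(warp.weights - sol[:n]).max() < 1e-8

    def test_coincident_point_maps_to_target(self, controls):
        rng = np.random.default_rng(5)
        targets = controls + rng.normal(0, 2, controls.shape)
        warp = tps_fit(controls, targets)
        out = tps_apply(warp, controls[7])
        assert np.abs(out - targets[7]).max() < 1e-6

    def test_coplanar_controls_rejected(self):
        pts = np.random.default_rng(6).normal(size=(10, 3))
        pts[:, 2] = 0.0
        with pytest.raises(ValueError):
            tps_fit(pts, pts + 1.0)

    def test_duplicate_controls_named(self):
        pts = np.random.default_rng(7).normal(size=(8, 3))
        pts[5] = pts[2]
        with pytest.raises(ValueError, match="duplicate"):
            tps_fit(pts, pts)


class TestBaseline:
    def test_positive_jacobians_and_watertight_boundary(self):
        model = synthetic_baseline(resolution=600)
        assert (model.jacobians() > 0).all()
        surf = model.boundary_surface()
        assert validate_mesh(surf, require_watertight=True).watertight

    def test_farthest_point_subsample_spreads(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(500, 3))
        idx = farthest_point_subsample(pts, 50)
        assert len(np.unique(idx)) == 50


class TestMapBaseline:
    def test_identity_morph_small_interior_motion(self, pretrained):
        base = synthetic_baseline(resolution=700)
        morphed, rep = map_baseline(base, base.boundary_surface(),
                                    pretrained.net,
                                    refine=RefinementConfig(steps=30))
        interior = np.setdiff1d(np.arange(base.n_nodes), base.surface_node_ids)
        move = np.linalg.norm(morphed.nodes[interior] - base.nodes[interior],
                              axis=1)
        diag = base.boundary_surface().bbox_diagonal()
        assert move.max() < 0.01 * diag
        assert rep["positive_jacobian_fraction"] >= 0.99

    def test_morph_onto_longer_bone(self, pretrained):
        from morphoforge.geom import MeshLocator

        base = synthetic_baseline(resolution=700)
        target = generate_bone(BoneParams(length=460.0, shaft_radius_ml=15.0),
                               1800)
        morphed, rep = map_baseline(base, target, pretrained.net,
                                    refine=RefinementConfig(steps=30))
        assert np.array_equal(morphed.elements, base.elements)
        assert morphed.labels == base.labels
        surf_nodes = morphed.nodes[morphed.surface_node_ids]
        proj, _, _ = MeshLocator(target.vertices, target.faces).query(surf_nodes)
        dist = np.linalg.norm(proj - surf_nodes, axis=1)
        assert dist.max() < 0.01 * target.bbox_diagonal()
        assert rep["positive_jacobian_fraction"] >= 0.99


class TestDeckExport:
    @pytest.fixture(scope="class")
    def model(self):
        return synthetic_baseline(resolution=500)

    def test_single_tetra_keyword_cards(self, tmp_path):
        from morphoforge.fe_mapping import VolumetricModel

        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        model = VolumetricModel(nodes, np.array([[0, 1, 2, 3]]),
                                np.arange(4),
                                np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3],
                                          [0, 3, 2]]))
        p = export_deck(model, tmp_path / "one.k", dialect="keyword")
        text = p.read_text()
        assert text.count("\n") >= 8
        node_lines = text.split("*NODE\n")[1].split("*ELEMENT_SOLID")[0]
        assert len(node_lines.strip().splitlines()) == 4
        elem_lines = text.split("*ELEMENT_SOLID\n")[1].split("*END")[0]
        assert len(elem_lines.strip().splitlines()) == 1

    @pytest.mark.parametrize("dialect", ["keyword", "abaqus_inp", "vtk"])
    def test_round_trip(self, model, dialect, tmp_path):
        p = export_deck(model, tmp_path / f"m.{dialect}", dialect=dialect)
        nodes, elems = read_deck(p, dialect=dialect)
        assert np.abs(nodes - model.nodes).max() < 1e-6
        assert np.array_equal(elems, model.elements)

    def test_vtk_against_independent_text_parse(self, model, tmp_path):
        """Counts verified by a parser written only from the VTK legacy spec."""
        p = export_deck(model, tmp_path / "m.vtk", dialect="vtk")
        lines = p.read_text().splitlines()
        assert lines[0].startswith("# vtk DataFile")
        n_points = n_cells = None
        types = []
        for i, line in enumerate(lines):
            if line.startswith("POINTS"):
                n_points = int(line.split()[1])
            if line.startswith("CELLS"):
                n_cells = int(line.split()[1])
            if line.startswith("CELL_TYPES"):
                types = [int(v) for v in lines[i + 1: i + 1 + int(line.split()[1])]]
        assert n_points == model.n_nodes
        assert n_cells == model.n_elements
        assert set(types) == {10}          # tetrahedra

    def test_unsupported_dialect(self, model, tmp_path):
        with pytest.raises(ValueError):
            export_deck(model, tmp_path / "m.x", dialect="nastran")
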