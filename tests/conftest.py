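"""Shared fixtures: synthetic meshes and the two trained models.

Training fixtures are session-scoped — the pretrained feature extractor and
the shape-prior VAE are each trained once and reused by every test that
needs them. Problem sizes are scaled-down study conditions (small nets,
sub-thousand-vertex meshes) chosen so the whole suite runs on one CPU.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
import trimesh

from morphoforge.feature_net import FeatureExtractorConfig, build_feature_extractor
from morphoforge.mesh_core import TriangleMesh
from morphoforge.spiral_vae import VaeConfig, train_vae
from morphoforge.ssl_pretrain import train_pretext
from morphoforge.synthetic_anatomy import (
    DEFAULT_PARAM_DISTRIBUTIONS,
    BoneParams,
    CohortSpec,
    generate_bone,
    generate_cohort,
    generate_template,
)

TEST_K_EIG = 48
TEST_NET_CONFIG = FeatureExtractorConfig(n_blocks=3, width=64, out_dim=96,
                                         k_eig=TEST_K_EIG)


@pytest.fixture(scope="session")
def template_1083() -> TriangleMesh:
    return generate_template(1083)


@pytest.fixture(scope="session")
def small_bone() -> TriangleMesh:
    return generate_bone(BoneParams(), 700)


@pytest.fixture(scope="session")
def icosphere() -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=4)   # 2562 vertices
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces), "icosphere")


@pytest.fixture(scope="session")
def pretrained() -> SimpleNamespace:
    """Feature extractor pretrained on 10 synthetic shapes for 40 epochs."""
    cohort = [m for m, _ in generate_cohort(
        CohortSpec(n_subjects=10, seed=11, retessellate=False, resolution=1200))]
    net = build_feature_extractor(TEST_NET_CONFIG, seed=0)
    net, log = train_pretext(cohort, net, epochs=40, batch_size=4, lr=2e-3, seed=0)
    return SimpleNamespace(net=net, log=log, cohort=cohort)


def two_parameter_distributions() -> dict:
    """Cohort spec varying only bone length and bending curvature."""
    dist = {k: (m, 0.0) for k, (m, _) in DEFAULT_PARAM_DISTRIBUTIONS.items()}
    dist["length"] = (420.0, 25.0)
    dist["bend_curvature"] = (1.2e-3, 4.0e-4)
    return dist


@pytest.fixture(scope="session")
def trained_vae() -> SimpleNamespace:
    """Shape-prior VAE trained on a 90-shape cohort with 2 varying params."""
    cohort = generate_cohort(CohortSpec(
        n_subjects=90, seed=5, retessellate=False, resolution=302,
        param_distributions=two_parameter_distributions()))
    meshes = [m for m, _ in cohort]
    params = [p for _, p in cohort]
    cfg = VaeConfig(channels=32, epochs=100, batch=8, lr=3e-3, latent_dim=6, seed=0)
    weights, topo, log = train_vae(meshes, cfg)
    return SimpleNamespace(weights=weights, topo=topo, meshes=meshes,
                           params=params, log=log, config=cfg)
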