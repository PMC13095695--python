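"""End-to-end workflow orchestration with seeded reproducibility.

Runs the enabled stages in order — synthesize or load a cohort, rigidly
align it, pretrain the feature extractor, register the template onto every
subject, train the shape-prior VAE, sample novel shapes, measure latent
traversals, and morph the baseline volumetric model onto the samples — and
records a manifest of per-stage inputs, outputs, content hashes and
metrics. One global seed is fanned out deterministically per stage, so any
stage can be rerun in isolation and reproduce its artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .mesh_core import TriangleMesh, gpa_align, validate_mesh, write_mesh

STAGES = ("cohort", "align", "pretrain", "register", "vae", "synthesize",
          "measure", "morph")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "morphoforge_run"
    stages: tuple[str, ...] = STAGES
    # cohort
    n_subjects: int = 20
    retessellate: bool = True
    cohort_resolution: int = 1500
    # template
    template_vertices: int = 1083
    # pretraining (scaled-down defaults; the full-scale configuration is
    # 6 blocks × 256 channels for 500 epochs at batch 4)
    pretrain_epochs: int = 40
    pretrain_batch: int = 4
    pretrain_lr: float = 2e-3
    feature_blocks: int = 3
    feature_width: int = 64
    feature_out_dim: int = 96
    k_eig: int = 48
    # vae
    vae_epochs: int = 100
    vae_channels: int = 32
    vae_batch: int = 8
    vae_lr: float = 3e-3
    latent_dim: int = 6
    n_samples: int = 10
    refine_steps: int = 60

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["stages"] = tuple(d.get("stages", STAGES))
        return cls(**d)


def _hash_mesh(mesh: TriangleMesh) -> str:
    return mesh.content_hash()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    from .correspondence import RefinementConfig, register_template
    from .feature_net import FeatureExtractorConfig, build_feature_extractor
    from .morphometrics import traversal_report
    from .spiral_vae import VaeConfig, latent_traverse, synthesize, train_vae
    from .ssl_pretrain import train_pretext
    from .synthetic_anatomy import CohortSpec, generate_cohort, generate_template
    from . import fe_mapping

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    state: dict = {}

    def record(stage: str, status: str, **info):
        manifest["stages"][stage] = {"status": status, **info}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    enabled = set(config.stages)
    failed = False
    for stage in STAGES:
        if stage not in enabled or failed:
            if stage in enabled and failed:
                record(stage, "skipped_after_failure")
            continue
        t0 = time.time()
        try:
            if stage == "cohort":
                spec = CohortSpec(n_subjects=config.n_subjects,
                                  retessellate=config.retessellate,
                                  resolution=config.cohort_resolution,
                                  seed=stage_seed(config.seed, "cohort"))
                cohort = generate_cohort(spec)
                state["cohort"] = [m for m, _ in cohort]
                state["params"] = [p for _, p in cohort]
                state["template"] = generate_template(config.template_vertices)
                record(stage, "ok", n=len(cohort),
                       hashes=[_hash_mesh(m) for m in state["cohort"]],
                       template_hash=_hash_mesh(state["template"]),
                       seconds=round(time.time() - t0, 2))
            elif stage == "align":
                aligned, al = gpa_align(state["cohort"])
                state["cohort"] = aligned
                record(stage, "ok", reflections=int(al.reflection_flagged.sum()),
                       seconds=round(time.time() - t0, 2))
            elif stage == "pretrain":
                net = build_feature_extractor(FeatureExtractorConfig(
                    n_blocks=config.feature_blocks, width=config.feature_width,
                    out_dim=config.feature_out_dim, k_eig=config.k_eig),
                    seed=stage_seed(config.seed, "pretrain"))
                net, log = train_pretext(
                    state["cohort"], net, epochs=config.pretrain_epochs,
                    batch_size=config.pretrain_batch, lr=config.pretrain_lr,
                    seed=stage_seed(config.seed, "pretrain"))
                state["net"] = net
                net.save(out / "feature_net.pkl")
                record(stage, "ok",
                       loss_first=round(log.epochs[0]["total"], 4),
                       loss_last=round(log.epochs[-1]["total"], 4),
                       seconds=round(time.time() - t0, 2))
            elif stage == "register":
                refine = RefinementConfig(steps=config.refine_steps)
                registered = []
                for mesh in state["cohort"]:
                    reg, _ = register_template(state["template"], mesh,
                                               state["net"], k=config.k_eig,
                                               refine=refine)
                    registered.append(reg)
                state["registered"] = registered
                record(stage, "ok", n=len(registered),
                       connectivity_shared=len({m.faces.tobytes() for m in registered}) == 1,
                       seconds=round(time.time() - t0, 2))
            elif stage == "vae":
                if "registered" not in state:
                    counts = {m.n_vertices for m in state["cohort"]}
                    if len(counts) != 1:
                        raise ValueError(
                            "VAE stage requires a registered (topology-aligned) "
                            "cohort; enable the register stage")
                    state["registered"] = state["cohort"]
                cfg = VaeConfig(channels=config.vae_channels,
                                epochs=config.vae_epochs, batch=config.vae_batch,
                                lr=config.vae_lr, latent_dim=config.latent_dim,
                                seed=stage_seed(config.seed, "vae"))
                weights, topo, log = train_vae(state["registered"], cfg)
                state["vae"] = (weights, topo)
                weights.save(out / "vae_weights.pkl")
                record(stage, "ok",
                       recon_first=round(log.epochs[0]["recon"], 3),
                       recon_last=round(log.epochs[-1]["recon"], 3),
                       seconds=round(time.time() - t0, 2))
            elif stage == "synthesize":
                weights, topo = state["vae"]
                samples = synthesize(weights, topo, config.n_samples,
                                     seed=stage_seed(config.seed, "synthesize"))
                state["samples"] = samples
                sdir = out / "samples"
                for s in samples:
                    write_mesh(s, sdir / f"{s.name}.ply")
                valid = sum(validate_mesh(s, True).watertight for s in samples)
                record(stage, "ok", n=len(samples), valid=valid,
                       hashes=[_hash_mesh(s) for s in samples],
                       seconds=round(time.time() - t0, 2))
            elif stage == "measure":
                weights, topo = state["vae"]
                tables = {}
                for dim in range(config.latent_dim):
                    meshes = latent_traverse(weights, topo, dim,
                                             np.linspace(-3, 3, 7))
                    tables[f"z{dim + 1}"] = traversal_report(meshes, f"z{dim + 1}")
                state["traversals"] = tables
                (out / "traversals.json").write_text(
                    json.dumps(tables, indent=2, default=float))
                record(stage, "ok", dims=config.latent_dim,
                       seconds=round(time.time() - t0, 2))
            elif stage == "morph":
                baseline = fe_mapping.synthetic_baseline(resolution=700)
                target = state["samples"][0]
                morphed, rep = fe_mapping.map_baseline(
                    baseline, target, state["net"],
                    refine=RefinementConfig(steps=config.refine_steps))
                deck = fe_mapping.export_deck(morphed, out / "morphed_000.k",
                                              dialect="keyword")
                record(stage, "ok", deck=str(deck), **rep,
                       seconds=round(time.time() - t0, 2))
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            record(stage, "failed", error=f"{type(exc).__name__}: {exc}",
                   seconds=round(time.time() - t0, 2))
            failed = True
    manifest["ok"] = not failed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable per-stage summary (Markdown) of a run manifest."""
    lines = ["| stage | status | metrics |", "|---|---|---|"]
    for stage, info in manifest.get("stages", {}).items():
        metrics = {k: v for k, v in info.items()
                   if k not in ("status", "hashes") and not isinstance(v, (list, dict))}
        lines.append(f"| {stage} | {info['status']} | "
                     f"{', '.join(f'{k}={v}' for k, v in metrics.items())} |")
    return "\n".join(lines) + "\n"
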