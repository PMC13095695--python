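"""Fixed-topology generative shape model: spiral convolutions + β-weighted VAE.

Once a cohort is registered to a shared triangle template, every subject is
an ordered (n, 3) coordinate array on identical connectivity, and a
spiral-convolution autoencoder applies: each vertex aggregates a
fixed-length, deterministically ordered spiral of its neighbors (itself,
then the 1-ring counterclockwise, then outward ring by ring). The encoder
maps coordinates to a low-dimensional Gaussian posterior (μ, log σ²); the
decoder mirrors it back to coordinates which, concatenated with the constant
template face list, form a valid watertight mesh for any finite latent code.

Training maximizes the evidence lower bound with an L1 reconstruction term
and the closed-form Gaussian KL divergence, weighted β·recon + λ_KL·KL
(defaults 0.9 / 0.1). Sampling z ~ N(0, I) synthesizes novel shapes; sweeping
one latent coordinate with the rest at 0 reads out the semantic factor that
dimension encodes.
"""

from __future__ import annotations

import dataclasses
import pickle

import numpy as np

from .autodiff import Adam, Parameter, Tensor
from .mesh_core import MeshValidationError, TriangleMesh, validate_mesh

__all__ = ["SpiralTopology", "VaeConfig", "VaeWeights", "build_spirals",
           "encode", "decode", "elbo_loss", "train_vae", "synthesize",
           "latent_traverse", "VaeLog"]


# ---------------------------------------------------------------------------
# Spiral construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpiralTopology:
    """Per-vertex spiral index sequences plus the template connectivity."""

    spirals: np.ndarray        # (n, length) int; spirals[i, 0] == i
    template_faces: np.ndarray
    length: int

    @property
    def n(self) -> int:
        return self.spirals.shape[0]


def _one_ring_cycles(n: int, faces: np.ndarray) -> list[list[int]]:
    """Ordered 1-ring of each vertex, counterclockwise w.r.t. outward normal.

    Faces (i, j, k) contribute the directed edge j→k to vertex i's ring;
    on a closed oriented manifold these directed edges chain into a single
    cycle per vertex. The cycle is started at the lowest-index neighbor.
    """
    nxt: list[dict[int, int]] = [dict() for _ in range(n)]
    for a, b, c in faces:
        nxt[a][b] = c
        nxt[b][c] = a
        nxt[c][a] = b
    rings = []
    for i in range(n):
        step = nxt[i]
        if not step:
            raise MeshValidationError(f"isolated vertex {i}")
        start = min(step.keys())
        ring = [start]
        cur = step[start]
        while cur != start:
            if cur in ring or len(ring) > len(step):
                raise MeshValidationError(
                    f"open or non-manifold 1-ring at vertex {i}")
            ring.append(cur)
            cur = step[cur]
        rings.append(ring)
    return rings


def build_spirals(template: TriangleMesh, length: int = 10) -> SpiralTopology:
    """Deterministic spiral sequences: self, CCW 1-ring, then outward rings.

    Ring r+1 vertices are appended in the order their ring-r parents are
    visited (each parent contributing its own CCW-ordered unseen neighbors);
    when the neighborhood is exhausted before `length`, the sequence is
    padded by repeating the center index.
    """
    if length < 1:
        raise ValueError("spiral length must be >= 1")
    rep = validate_mesh(template, require_watertight=False)
    if rep.boundary_edges > 0:
        raise MeshValidationError("build_spirals requires a closed template")
    n = template.n_vertices
    rings1 = _one_ring_cycles(n, template.faces)

    spirals = np.empty((n, length), dtype=np.int64)
    for i in range(n):
        seq = [i]
        seen = {i}
        frontier = [v for v in rings1[i] if v not in seen]
        while len(seq) < length and frontier:
            for v in frontier:
                if len(seq) >= length:
                    break
                if v not in seen:
                    seq.append(v)
                    seen.add(v)
            nxt_frontier: list[int] = []
            for parent in frontier:
                for v in rings1[parent]:
                    if v not in seen and v not in nxt_frontier:
                        nxt_frontier.append(v)
            frontier = nxt_frontier
        while len(seq) < length:
            seq.append(i)               # pad with the center index
        spirals[i] = seq[:length]
    return SpiralTopology(spirals=spirals, template_faces=template.faces.copy(),
                          length=length)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VaeConfig:
    layers: int = 3
    channels: int = 128
    spiral_length: int = 10
    latent_dim: int = 6
    beta: float = 0.9
    lambda_kl: float = 0.1
    lr: float = 3e-4
    batch: int = 8
    epochs: int = 800
    decoder_seed_channels: int = 16
    kl_warmup_frac: float = 0.15  # λ_KL ramps linearly over this epoch fraction
    seed: int = 0

    def validate(self):
        if self.beta < 0 or self.lambda_kl < 0:
            raise ValueError("beta and lambda_kl must be >= 0")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        return self


class VaeWeights:
    """Encoder/decoder parameters plus the cohort normalization constants.

    Coordinates are standardized (cohort mean shape subtracted, global
    standard deviation divided out) before entering the encoder; the decoder
    predicts standardized coordinates and `decode` undoes the transform, so
    the public API always speaks mm.
    """

    def __init__(self, config: VaeConfig, n_vertices: int, seed: int | None = None):
        self.config = config.validate()
        self.n_vertices = n_vertices
        rng = np.random.default_rng(config.seed if seed is None else seed)
        C, L, D = config.channels, config.spiral_length, config.latent_dim

        def lin(n_in, n_out, scale=1.0):
            return Parameter(rng.normal(0, scale * np.sqrt(2.0 / n_in), (n_in, n_out)))

        dims = [3] + [C] * config.layers
        self.enc = []
        for lyr in range(config.layers):
            self.enc.append({"W": lin(L * dims[lyr], dims[lyr + 1]),
                             "b": Parameter(np.zeros(dims[lyr + 1]))})
        self.mu_head_W = lin(C, D)
        self.mu_head_b = Parameter(np.zeros(D))
        self.lv_head_W = lin(C, D)
        self.lv_head_b = Parameter(np.zeros(D))

        S = config.decoder_seed_channels
        self.dec_seed_W = lin(D, n_vertices * S)
        self.dec_seed_b = Parameter(np.zeros(n_vertices * S))
        ddims = [S] + [C] * (config.layers - 1) + [3]
        self.dec = []
        for lyr in range(config.layers):
            scale = 0.1 if lyr == config.layers - 1 else 1.0
            self.dec.append({"W": lin(L * ddims[lyr], ddims[lyr + 1], scale),
                             "b": Parameter(np.zeros(ddims[lyr + 1]))})
        # normalization constants (set by train_vae)
        self.mean_shape = np.zeros((n_vertices, 3))
        self.coord_std = 1.0

    def parameters(self) -> list[Parameter]:
        ps = [self.mu_head_W, self.mu_head_b, self.lv_head_W, self.lv_head_b,
              self.dec_seed_W, self.dec_seed_b]
        for blk in self.enc + self.dec:
            ps.extend(blk.values())
        return ps

    def save(self, path):
        state = {"config": dataclasses.asdict(self.config),
                 "n_vertices": self.n_vertices,
                 "weights": [p.data.copy() for p in self.parameters()],
                 "mean_shape": self.mean_shape, "coord_std": self.coord_std}
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path) -> "VaeWeights":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        w = cls(VaeConfig(**state["config"]), state["n_vertices"])
        for p, arr in zip(w.parameters(), state["weights"]):
            p.data = np.asarray(arr, dtype=np.float64)
        w.mean_shape = state["mean_shape"]
        w.coord_std = float(state["coord_std"])
        return w


def _spiral_conv(x: Tensor, spirals: np.ndarray, W: Parameter, b: Parameter,
                 activate: bool) -> Tensor:
    n, L = spirals.shape
    gathered = x.take_rows(spirals)              # (n, L, C)
    flat = gathered.reshape(n, -1)
    out = flat @ W + b
    return out.elu() if activate else out


def _encode_tensor(coords: Tensor, topo: SpiralTopology, w: VaeWeights
                   ) -> tuple[Tensor, Tensor]:
    x = coords
    for blk in w.enc:
        x = _spiral_conv(x, topo.spirals, blk["W"], blk["b"], activate=True)
    pooled = x.mean(axis=0, keepdims=True)       # global readout
    mu = pooled @ w.mu_head_W + w.mu_head_b
    lv = pooled @ w.lv_head_W + w.lv_head_b
    return mu.reshape(-1), lv.reshape(-1)


def _decode_tensor(z: Tensor, topo: SpiralTopology, w: VaeWeights) -> Tensor:
    S = w.config.decoder_seed_channels
    x = (z.reshape(1, -1) @ w.dec_seed_W + w.dec_seed_b).elu()
    x = x.reshape(w.n_vertices, S)
    for lyr, blk in enumerate(w.dec):
        last = lyr == len(w.dec) - 1
        x = _spiral_conv(x, topo.spirals, blk["W"], blk["b"], activate=not last)
    return x


def encode(coords: np.ndarray, topo: SpiralTopology, weights: VaeWeights
           ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior parameters (μ, log σ²) of a coordinate array (mm)."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (topo.n, 3):
        raise ValueError(f"coords must be ({topo.n}, 3)")
    normed = (coords - weights.mean_shape) / weights.coord_std
    mu, lv = _encode_tensor(Tensor(normed), topo, weights)
    return mu.data.copy(), lv.data.copy()


def decode(z: np.ndarray, topo: SpiralTopology, weights: VaeWeights) -> np.ndarray:
    """Coordinates (mm) decoded from a latent vector."""
    z = np.asarray(z, dtype=np.float64).reshape(-1)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent vector must be finite")
    out = _decode_tensor(Tensor(z), topo, weights)
    return out.data * weights.coord_std + weights.mean_shape


def elbo_loss(coords_in: np.ndarray, coords_out: np.ndarray, mu: np.ndarray,
              log_var: np.ndarray, beta: float = 0.9, lambda_kl: float = 0.1
              ) -> tuple[float, float, float]:
    """(total, recon, kl): β·L1 + λ_KL·KL for a Gaussian posterior.

    recon is the mean absolute error over all vertex-coordinate entries;
    kl = ½ Σᵢ (μᵢ² + σᵢ² − log σᵢ² − 1), exactly zero iff (μ, σ²) = (0, 1).
    """
    a = np.asarray(coords_in, dtype=np.float64)
    b = np.asarray(coords_out, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    lv = np.asarray(log_var, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must share shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))
            and np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))):
        raise ValueError("non-finite inputs to elbo_loss")
    recon = float(np.mean(np.abs(a - b)))
    kl = float(0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0))
    return beta * recon + lambda_kl * kl, recon, kl


@dataclasses.dataclass
class VaeLog:
    epochs: list[dict] = dataclasses.field(default_factory=list)


def train_vae(cohort: list[TriangleMesh], config: VaeConfig | None = None,
              topo: SpiralTopology | None = None, test_fraction: float = 1 / 9,
              ) -> tuple[VaeWeights, SpiralTopology, VaeLog]:
    """Train on a topology-aligned cohort; seeded train/test split (80/10 style).

    All cohort meshes must share the template connectivity. The epoch log
    records reconstruction and KL terms plus held-out reconstruction.
    """
    config = (config or VaeConfig()).validate()
    if not cohort:
        raise ValueError("empty cohort")
    faces0 = cohort[0].faces
    for m in cohort[1:]:
        if m.n_vertices != cohort[0].n_vertices or not np.array_equal(m.faces, faces0):
            raise MeshValidationError(
                "train_vae requires identical template connectivity across the cohort")
    if topo is None:
        topo = build_spirals(cohort[0], config.spiral_length)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(cohort))
    n_test = max(1, int(round(test_fraction * len(cohort)))) if len(cohort) > 2 else 0
    test_idx = order[:n_test]
    train_idx = order[n_test:]

    coords = np.stack([m.vertices for m in cohort])
    w = VaeWeights(config, cohort[0].n_vertices)
    w.mean_shape = coords[train_idx].mean(axis=0)
    # standardize by the residual spread about the mean shape so the
    # reconstruction term is order one and balances the KL term
    w.coord_std = float((coords[train_idx] - w.mean_shape).std()) or 1.0
    normed = (coords - w.mean_shape) / w.coord_std

    opt = Adam(w.parameters(), lr=config.lr)
    log = VaeLog()
    D = config.latent_dim

    def heldout_recon() -> float:
        errs = []
        for i in test_idx:
            mu, _ = _encode_tensor(Tensor(normed[i]), topo, w)
            out = _decode_tensor(Tensor(mu.data), topo, w)
            errs.append(np.mean(np.abs(out.data - normed[i])) * w.coord_std)
        return float(np.mean(errs)) if errs else np.nan

    warmup = max(1, int(round(config.kl_warmup_frac * config.epochs)))
    for epoch in range(config.epochs):
        lam = config.lambda_kl * min(1.0, (epoch + 1) / warmup)
        perm = rng.permutation(train_idx)
        ep = {"recon": 0.0, "kl": 0.0, "total": 0.0}
        for start in range(0, len(perm), config.batch):
            idx = perm[start:start + config.batch]
            opt.zero_grad()
            batch_loss = Tensor(0.0)
            for i in idx:
                x = Tensor(normed[i])
                mu, lv = _encode_tensor(x, topo, w)
                eps = rng.standard_normal(D)
                z = mu + (lv * 0.5).exp() * Tensor(eps)
                out = _decode_tensor(z, topo, w)
                recon = (out - x).abs().mean()
                kl = 0.5 * (mu.square() + lv.exp() - lv - 1.0).sum()
                loss = config.beta * recon + lam * kl
                batch_loss = batch_loss + loss
                ep["recon"] += recon.item() * w.coord_std
                ep["kl"] += kl.item()
                ep["total"] += loss.item()
            if not np.isfinite(batch_loss.item()):
                raise RuntimeError(f"non-finite VAE loss at epoch {epoch}")
            (batch_loss / float(len(idx))).backward()
            opt.step()
        for key in ep:
            ep[key] /= len(perm)
        ep["epoch"] = epoch
        if epoch == 0 or epoch == config.epochs - 1 or (epoch + 1) % 10 == 0:
            ep["heldout_recon"] = heldout_recon()
        log.epochs.append(ep)
    return w, topo, log


def synthesize(weights: VaeWeights, topo: SpiralTopology, n_samples: int,
               seed: int = 0) -> list[TriangleMesh]:
    """Draw z ~ N(0, I) and decode to watertight template-topology meshes."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_samples):
        z = rng.standard_normal(weights.config.latent_dim)
        coords = decode(z, topo, weights)
        out.append(TriangleMesh(coords, topo.template_faces.copy(),
                                name=f"synthesized_{i:03d}"))
    return out


def latent_traverse(weights: VaeWeights, topo: SpiralTopology, dim: int,
                    values) -> list[TriangleMesh]:
    """Decode a sweep of one latent coordinate with the others held at 0."""
    D = weights.config.latent_dim
    if not 0 <= dim < D:
        raise ValueError(f"dim must be in [0, {D})")
    out = []
    for v in values:
        z = np.zeros(D)
        z[dim] = v
        coords = decode(z, topo, weights)
        out.append(TriangleMesh(coords, topo.template_faces.copy(),
                                name=f"traverse_d{dim}_{v:+.2f}"))
    return out
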