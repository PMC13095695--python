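"""Siamese self-supervised pretraining of the feature extractor.

Each training example is one cohort mesh expanded into two randomly
perturbed copies (uniform SO(3) rotation, isotropic scale ~ U(0.9, 1.1));
the two branches share weights. Features of both copies are projected into
their truncated Laplace–Beltrami bases, functional maps are estimated
between the spectral embeddings in both directions, and three losses are
minimised jointly:

* identity loss  ‖C₁₂ − I‖²_F + ‖C₂₁ − I‖²_F  — perturbation invariance;
* regularization loss  Σ‖E − Ē‖₁ on the absolute spectral coefficients —
  uniform spectral energy distribution across frequencies;
* normalization loss  Σ‖E² − 1‖₁ — drives energies toward unit magnitude
  for numerical stability.

Rotation leaves the Laplace–Beltrami eigenbasis untouched and isotropic
scaling transforms it in closed form, so perturbed-copy bases are obtained
exactly from the cached basis of the unperturbed mesh.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from .autodiff import Adam, Tensor
from .feature_net import FeatureExtractor, MeshOperators, build_gradient_operators, mesh_operators
from .mesh_core import TriangleMesh
from .spectral_geometry import SpectralBasis

__all__ = ["PerturbationSpec", "SpectralEmbedding", "FunctionalMap",
           "perturb_pair", "compute_fmap", "loss_identity", "loss_reg",
           "loss_norm", "train_pretext", "PretrainLog"]

RIDGE_DEFAULT = 1e-6


@dataclasses.dataclass
class PerturbationSpec:
    rotation: np.ndarray    # 3×3, det +1
    scale: float            # ~ U(0.9, 1.1)
    seed: int


@dataclasses.dataclass
class SpectralEmbedding:
    """Spectral coefficients Z = Φ⁺ T(X) and their absolute form E = |Z|."""

    Z: np.ndarray           # (k, d)

    @property
    def E(self) -> np.ndarray:
        return np.abs(self.Z)


@dataclasses.dataclass
class FunctionalMap:
    C: np.ndarray           # (k, k)
    direction: tuple[str, str] = ("src", "tgt")

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("functional map must be square k×k")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("non-finite functional map")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) rotation matrix."""
    return Rotation.random(random_state=rng).as_matrix()


def perturb_pair(mesh: TriangleMesh, seed: int
                 ) -> tuple[TriangleMesh, TriangleMesh, PerturbationSpec, PerturbationSpec]:
    """Two independently rotated + scaled copies of one mesh (faces unchanged)."""
    rng = np.random.default_rng(seed)
    out_meshes, specs = [], []
    for branch in range(2):
        R = random_rotation(rng)
        s = float(rng.uniform(0.9, 1.1))
        v = s * (mesh.vertices @ R.T)
        out_meshes.append(TriangleMesh(v, mesh.faces.copy(),
                                       f"{mesh.name}_pert{branch}"))
        specs.append(PerturbationSpec(rotation=R, scale=s, seed=seed))
    return out_meshes[0], out_meshes[1], specs[0], specs[1]


def normalize_channels(Z: np.ndarray) -> np.ndarray:
    """Unit-L2 normalization of each feature channel (column) of Z.

    The raw spectral embedding scales linearly with the shape's isotropic
    scale; normalizing channels before solving for a functional map removes
    that structural factor (standard practice in spectral correspondence).
    """
    norms = np.linalg.norm(Z, axis=0, keepdims=True)
    return Z / np.maximum(norms, 1e-30)


def spectral_embedding(net: FeatureExtractor, mesh: TriangleMesh,
                       k: int | None = None, align: bool = True,
                       normalize: bool = True) -> SpectralEmbedding:
    """Z = Φ⁺ T(X) through the standard inference path.

    ``align`` (default) first puts the mesh into its canonical anatomical
    frame — the pipeline's rigid pre-alignment stage — so embeddings of
    arbitrarily posed inputs are comparable; ``normalize`` applies
    per-channel unit normalization for scale-free functional-map solves.
    """
    k = k if k is not None else net.config.k_eig
    work = mesh
    if align:
        from .mesh_core import _principal_frame

        R, c, _ = _principal_frame(mesh)
        work = TriangleMesh((mesh.vertices - c) @ R.T, mesh.faces, mesh.name)
    ops = mesh_operators(work, k)
    from .feature_net import extract_features

    F = extract_features(net, work, ops=ops).values
    from .spectral_geometry import spectral_project

    Z = spectral_project(ops.basis, F)
    return SpectralEmbedding(Z=normalize_channels(Z) if normalize else Z)


# ---------------------------------------------------------------------------
# Functional maps and losses (numpy API + differentiable tensor kernels)
# ---------------------------------------------------------------------------

def _fmap_tensor(Z_src: Tensor, Z_tgt: Tensor, ridge: float) -> Tensor:
    """Differentiable ridge least squares: argmin_C ‖C Z_src − Z_tgt‖²_F.

    The ridge is scaled by trace(Z Zᵀ)/k so conditioning is independent of
    the overall feature magnitude (untrained features are low-rank: the raw
    inputs span only three channels).
    """
    k = Z_src.shape[0]
    lam = ridge * float(np.trace(Z_src.data @ Z_src.data.T)) / k + 1e-30
    G = Z_src @ Z_src.T + Tensor(lam * np.eye(k))
    return (Z_tgt @ Z_src.T) @ G.inv()


def compute_fmap(Z_src, Z_tgt, ridge: float = 0.0,
                 evals_src: np.ndarray | None = None,
                 evals_tgt: np.ndarray | None = None,
                 mu_commute: float = 0.0,
                 direction: tuple[str, str] = ("src", "tgt")) -> FunctionalMap:
    """Least-squares functional map C with C Z_src ≈ Z_tgt.

    With ridge=0 the minimum-Frobenius-norm solution is returned on rank
    deficiency (via the pseudoinverse). When the number of feature channels
    d is below k the problem is ill-posed; it is still solved, with ridge
    regularization if requested.

    With ``mu_commute > 0`` (and both eigenvalue vectors given) the solve
    adds the Laplacian commutativity term μ‖C Λ_src − Λ_tgt C‖²_F, the
    standard near-isometry prior of the functional-map framework; the
    problem stays row-separable and is solved in closed form per row.
    """
    Zs = Z_src.Z if isinstance(Z_src, SpectralEmbedding) else np.asarray(Z_src)
    Zt = Z_tgt.Z if isinstance(Z_tgt, SpectralEmbedding) else np.asarray(Z_tgt)
    if Zs.shape != Zt.shape:
        raise ValueError("spectral embeddings must share shape (k, d)")
    k, d = Zs.shape
    if d < k and ridge <= 0:
        ridge = RIDGE_DEFAULT
    if mu_commute > 0 and evals_src is not None and evals_tgt is not None:
        scale = np.trace(Zs @ Zs.T) / k
        lam = ridge * scale + 1e-30
        G = Zs @ Zs.T
        B = Zt @ Zs.T
        # eigenvalues normalized to O(1) so μ is unit-free
        ls = np.asarray(evals_src) / max(evals_src[-1], 1e-30)
        lt = np.asarray(evals_tgt) / max(evals_tgt[-1], 1e-30)
        C = np.empty((k, k))
        mu = mu_commute * scale
        for i in range(k):
            D = mu * (ls - lt[i]) ** 2
            C[i] = np.linalg.solve(G + np.diag(D + lam), B[i])
    elif ridge > 0:
        lam = ridge * np.trace(Zs @ Zs.T) / k + 1e-30   # magnitude-relative
        G = Zs @ Zs.T + lam * np.eye(k)
        C = (Zt @ Zs.T) @ np.linalg.inv(G)
    else:
        C = Zt @ np.linalg.pinv(Zs)
    return FunctionalMap(C=C, direction=direction)


def _as_array(x, name: str) -> np.ndarray:
    a = x.E if isinstance(x, SpectralEmbedding) else np.asarray(x, dtype=np.float64)
    if np.any(a < 0):
        raise ValueError(f"{name} must be the absolute spectral form (E ≥ 0)")
    return a


def loss_identity(C12, C21) -> float:
    """‖C₁₂ − I‖²_F + ‖C₂₁ − I‖²_F."""
    A = C12.C if isinstance(C12, FunctionalMap) else np.asarray(C12)
    B = C21.C if isinstance(C21, FunctionalMap) else np.asarray(C21)
    if A.shape != B.shape:
        raise ValueError("functional maps must share k")
    I = np.eye(A.shape[0])
    return float(np.sum((A - I) ** 2) + np.sum((B - I) ** 2))


def loss_reg(E1, E2) -> float:
    """Σ_shapes Σ_channels ‖E_d − Ē_d‖₁, Ē_d the within-channel spectral mean."""
    total = 0.0
    for E in (_as_array(E1, "E1"), _as_array(E2, "E2")):
        mean = E.mean(axis=0, keepdims=True)
        total += float(np.abs(E - mean).sum())
    return total


def loss_norm(E1, E2) -> float:
    """Σ_shapes Σ_channels ‖E_d² − 1‖₁."""
    total = 0.0
    for E in (_as_array(E1, "E1"), _as_array(E2, "E2")):
        total += float(np.abs(E**2 - 1.0).sum())
    return total


def _losses_tensor(Z1: Tensor, Z2: Tensor, ridge: float
                   ) -> tuple[Tensor, Tensor, Tensor]:
    k = Z1.shape[0]
    I = Tensor(np.eye(k))
    # functional maps are solved on channel-normalized embeddings (the raw
    # embedding scales with the shape; see normalize_channels)
    N1 = Z1 / (Z1.square().sum(axis=0, keepdims=True) + 1e-30).sqrt()
    N2 = Z2 / (Z2.square().sum(axis=0, keepdims=True) + 1e-30).sqrt()
    C12 = _fmap_tensor(N1, N2, ridge)
    C21 = _fmap_tensor(N2, N1, ridge)
    l_id = (C12 - I).square().sum() + (C21 - I).square().sum()
    l_reg = Tensor(0.0)
    l_norm = Tensor(0.0)
    for Z in (Z1, Z2):
        E = Z.abs()
        l_reg = l_reg + (E - E.mean(axis=0, keepdims=True)).abs().sum()
        l_norm = l_norm + (E.square() - 1.0).abs().sum()
    return l_id, l_reg, l_norm


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PretrainLog:
    epochs: list[dict] = dataclasses.field(default_factory=list)

    def totals(self) -> np.ndarray:
        return np.array([e["total"] for e in self.epochs])


def _perturbed_ops(base_ops: MeshOperators, mesh: TriangleMesh,
                   spec: PerturbationSpec, align: bool) -> tuple[TriangleMesh, MeshOperators]:
    v = spec.scale * (mesh.vertices @ spec.rotation.T)
    pmesh = TriangleMesh(v, mesh.faces, mesh.name)
    if align:
        from .mesh_core import _principal_frame

        R, c, _ = _principal_frame(pmesh)
        pmesh = TriangleMesh((pmesh.vertices - c) @ R.T, mesh.faces, mesh.name)
    basis = base_ops.basis.scaled(spec.scale)
    Gx, Gy = build_gradient_operators(pmesh)
    return pmesh, MeshOperators(basis, Gx, Gy)


def train_pretext(cohort: list[TriangleMesh], net: FeatureExtractor,
                  weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                  epochs: int = 500, batch_size: int = 4, lr: float = 1e-3,
                  seed: int = 0,
                  bases: list[SpectralBasis] | None = None,
                  normalize_reg: bool = True,
                  ridge: float = 1e-4,
                  lr_decay: bool = True,
                  align_pairs: bool = True,
                  ) -> tuple[FeatureExtractor, PretrainLog]:
    """Adam-train the extractor on perturbed pairs; returns (net, loss log).

    `weights` are (α_id, α_reg, α_norm). The L1-style regularization and
    normalization losses scale with k·d; with ``normalize_reg`` they are
    averaged per entry so the balance with the identity loss is architecture
    independent (α defaults stay (1, 1, 1)).

    With ``align_pairs`` (default) each perturbed copy is put into its
    canonical anatomical frame before feature extraction, mirroring the
    cohort-level rigid alignment that precedes representation learning in
    the pipeline; the rotation draw then exercises the stability of that
    alignment while the identity loss concentrates on scale robustness and
    spectral richness. Set False for raw-pose Siamese branches.
    """
    if not cohort:
        raise ValueError("empty cohort")
    k = net.config.k_eig
    base_ops = []
    for i, mesh in enumerate(cohort):
        basis = bases[i] if bases is not None else None
        base_ops.append(mesh_operators(mesh, k, basis=basis))

    params = net.parameters()
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed)
    log = PretrainLog()
    alpha = np.asarray(weights, dtype=np.float64)
    kd = k * net.config.out_dim

    step_seed = 0
    for epoch in range(epochs):
        if lr_decay:   # cosine decay to 5% of the initial rate
            opt.lr = lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * epoch / max(epochs - 1, 1))))
        order = rng.permutation(len(cohort))
        ep = {"identity": 0.0, "reg": 0.0, "norm": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            batch_total = Tensor(0.0)
            for i in idx:
                step_seed += 1
                m1, m2, s1, s2 = perturb_pair(cohort[i], seed=int(
                    np.random.default_rng((seed, epoch, step_seed)).integers(2**31)))
                pm1, ops1 = _perturbed_ops(base_ops[i], cohort[i], s1, align_pairs)
                pm2, ops2 = _perturbed_ops(base_ops[i], cohort[i], s2, align_pairs)
                F1 = net.forward(pm1.vertices, ops1)
                F2 = net.forward(pm2.vertices, ops2)
                Z1 = Tensor(ops1.basis.pinv()) @ F1
                Z2 = Tensor(ops2.basis.pinv()) @ F2
                l_id, l_reg, l_norm = _losses_tensor(Z1, Z2, ridge)
                if normalize_reg:
                    l_reg = l_reg / float(kd)
                    l_norm = l_norm / float(kd)
                total = alpha[0] * l_id + alpha[1] * l_reg + alpha[2] * l_norm
                batch_total = batch_total + total
                ep["identity"] += l_id.item()
                ep["reg"] += l_reg.item()
                ep["norm"] += l_norm.item()
                ep["total"] += total.item()
            if not np.isfinite(batch_total.item()):
                raise RuntimeError(
                    f"NaN/Inf loss at epoch {epoch}: {ep}")
            if np.any(alpha != 0):
                (batch_total / float(len(idx))).backward()
                opt.step()
            n_batches += 1
        for key in ep:
            ep[key] /= len(order)
        ep["epoch"] = epoch
        log.epochs.append(ep)
    return net, log
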