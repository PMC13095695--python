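"""Laplace–Beltrami spectral substrate: cotangent stiffness, lumped mass,
truncated eigenbasis, mass-weighted spectral projection, and heat diffusion.

Conventions: the stiffness matrix ``L`` is the positive semi-definite
cotangent FEM matrix (zero row sums, constants in the kernel); the mass
matrix ``M`` is diagonal (one-third triangle-area lumping, mm²), which makes
the Moore–Penrose pseudoinverse of the truncated basis exact and cheap:
``Φ⁺ = Φᵀ M``. Eigenpairs solve the generalized problem ``L φ = λ M φ`` with
``0 = λ₁ ≤ λ₂ ≤ …``; eigenvalues carry units 1/mm², so isotropic scaling by
``s`` multiplies them by ``1/s²`` and leaves the stiffness untouched.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_core import MeshValidationError, TriangleMesh

__all__ = ["SpectralBasis", "cotan_laplacian", "eigenbasis", "spectral_project",
           "reconstruct", "heat_diffuse"]

COT_CLAMP = 1e4   # survive near-degenerate triangles
DEFAULT_K = 48


@dataclasses.dataclass
class SpectralBasis:
    """Truncated LBO eigenpairs plus the operators that generated them."""

    eigenvalues: np.ndarray      # (k,) ascending, λ₁ ≈ 0
    eigenfunctions: np.ndarray   # (n, k), ΦᵀMΦ = I
    mass_diag: np.ndarray        # (n,) lumped vertex areas, mm²
    stiffness: sp.csr_matrix     # (n, n) cotangent matrix
    k: int

    @property
    def n(self) -> int:
        return self.eigenfunctions.shape[0]

    @property
    def mass(self) -> sp.dia_matrix:
        return sp.diags(self.mass_diag)

    def pinv(self) -> np.ndarray:
        """Φ⁺ = ΦᵀM (exact pseudoinverse under the lumped mass inner product)."""
        return self.eigenfunctions.T * self.mass_diag[None, :]

    def scaled(self, s: float) -> "SpectralBasis":
        """Basis of the same mesh isotropically scaled by s (exact identity).

        Under x → s·x: areas scale by s², eigenvalues by 1/s², eigenfunctions
        by 1/s (to stay mass-orthonormal), and the cotangent stiffness is
        scale-invariant.
        """
        return SpectralBasis(
            eigenvalues=self.eigenvalues / s**2,
            eigenfunctions=self.eigenfunctions / s,
            mass_diag=self.mass_diag * s**2,
            stiffness=self.stiffness,
            k=self.k)

    def save(self, path):
        np.savez(path, eigenvalues=self.eigenvalues,
                 eigenfunctions=self.eigenfunctions, mass_diag=self.mass_diag,
                 stiffness_data=self.stiffness.data,
                 stiffness_indices=self.stiffness.indices,
                 stiffness_indptr=self.stiffness.indptr, k=self.k)

    @classmethod
    def load(cls, path) -> "SpectralBasis":
        z = np.load(path)
        n = len(z["mass_diag"])
        L = sp.csr_matrix((z["stiffness_data"], z["stiffness_indices"],
                           z["stiffness_indptr"]), shape=(n, n))
        return cls(z["eigenvalues"], z["eigenfunctions"], z["mass_diag"], L,
                   int(z["k"]))


def _check_edge_manifold(mesh: TriangleMesh):
    und = mesh.edges_undirected()
    _, counts = np.unique(und, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise MeshValidationError("cotan_laplacian requires an edge-manifold mesh")


def cotan_laplacian(mesh: TriangleMesh) -> tuple[sp.csr_matrix, sp.dia_matrix]:
    """Cotangent stiffness (PSD, zero row sums) and lumped diagonal mass.

    trace(M) equals the total surface area; cotangent weights are clamped at
    ±1e4 so near-degenerate triangles cannot blow up the spectrum.
    """
    _check_edge_manifold(mesh)
    v, f = mesh.vertices, mesh.faces
    areas = mesh.face_areas()
    if np.any(areas <= 0):
        raise MeshValidationError("zero-area face in cotan_laplacian")

    I, J, W = [], [], []
    for c in range(3):
        i = f[:, (c + 1) % 3]
        j = f[:, (c + 2) % 3]
        o = f[:, c]
        u = v[i] - v[o]
        w = v[j] - v[o]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        cot = np.einsum("ij,ij->i", u, w) / np.maximum(cross, 1e-300)
        cot = np.clip(cot, -COT_CLAMP, COT_CLAMP)
        I.append(i)
        J.append(j)
        W.append(0.5 * cot)
    I = np.concatenate(I)
    J = np.concatenate(J)
    W = np.concatenate(W)
    n = mesh.n_vertices
    off = sp.coo_matrix((W, (I, J)), shape=(n, n))
    off = off + off.T
    L = sp.diags(np.asarray(off.sum(axis=1)).ravel()) - off

    mass_diag = mesh.vertex_areas()
    return L.tocsr(), sp.diags(mass_diag)


def eigenbasis(mesh: TriangleMesh, k: int = DEFAULT_K) -> SpectralBasis:
    """First k eigenpairs of the LBO with a deterministic sign convention."""
    n = mesh.n_vertices
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    L, M = cotan_laplacian(mesh)
    try:
        # fixed start vector: ARPACK is otherwise randomly initialized and
        # eigenvectors of near-degenerate pairs would differ across runs
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = spla.eigsh(L, k=k, M=M, sigma=-1e-8, which="LM", v0=v0)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"eigensolver failed (n={n}, k={k}): {exc}") from exc
    order = np.argsort(vals)
    vals = np.maximum(vals[order], 0.0)
    vals[0] = 0.0
    vecs = vecs[:, order]
    # deterministic sign: first entry with magnitude above 1e-8 made positive
    for c in range(k):
        col = vecs[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-8)
        if len(nz) and col[nz[0]] < 0:
            vecs[:, c] = -col
    mass_diag = M.diagonal()
    # re-normalize exactly under the lumped mass inner product
    norms = np.sqrt(np.einsum("ik,i,ik->k", vecs, mass_diag, vecs))
    vecs = vecs / norms[None, :]
    return SpectralBasis(vals, vecs, mass_diag, L, k)


def spectral_project(basis: SpectralBasis, signal: np.ndarray) -> np.ndarray:
    """Spectral coefficients Z = Φ⁺ x = ΦᵀM x (L²-optimal rank-k code)."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.shape[0] != basis.n:
        raise ValueError(f"signal rows {signal.shape[0]} != mesh vertices {basis.n}")
    return basis.eigenfunctions.T @ (basis.mass_diag[:, None] * signal
                                     if signal.ndim == 2 else basis.mass_diag * signal)


def reconstruct(basis: SpectralBasis, coeffs: np.ndarray) -> np.ndarray:
    """Lift spectral coefficients back to the vertices: x ≈ Φ Z."""
    return basis.eigenfunctions @ coeffs


def heat_diffuse(basis: SpectralBasis, signal: np.ndarray, t) -> np.ndarray:
    """Spectrally truncated heat diffusion: Φ diag(e^{−λt}) ΦᵀM x.

    ``t`` may be a scalar or one nonnegative diffusion time per channel
    (units mm²). t=0 returns the rank-k projection; t→∞ the mass-weighted
    mean, which is conserved for every t.
    """
    signal = np.asarray(signal, dtype=np.float64)
    squeeze = signal.ndim == 1
    if squeeze:
        signal = signal[:, None]
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    if np.any(t < 0):
        raise ValueError("diffusion times must be >= 0")
    if t.size == 1:
        t = np.full(signal.shape[1], t[0])
    if t.size != signal.shape[1]:
        raise ValueError("need one diffusion time per channel")
    coeffs = spectral_project(basis, signal)
    decay = np.exp(-np.outer(basis.eigenvalues, t))
    out = basis.eigenfunctions @ (decay * coeffs)
    return out[:, 0] if squeeze else out
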