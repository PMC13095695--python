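"""Triangle-mesh data model, I/O, validation, preprocessing, cohort alignment.

The mesh is the universal currency of the pipeline: watertight genus-0
triangle surfaces in millimetres. Anatomical frame convention: x is
medial–lateral, y is anterior–posterior, z is longitudinal. Indices are
0-based internally; OBJ's 1-based convention is converted at the I/O boundary
(trimesh handles this).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import trimesh

from .geom import MeshLocator

__all__ = [
    "TriangleMesh", "ValidationReport", "CohortAlignment",
    "MeshFormatError", "MeshValidationError",
    "read_mesh", "write_mesh", "validate_mesh", "preprocess_mesh", "gpa_align",
]

WELD_TOL_MM = 1e-6
MIN_FACE_AREA_MM2 = 1e-12


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed in the requested format."""


class MeshValidationError(ValueError):
    """Raised when a mesh violates the invariants an operation requires."""


@dataclasses.dataclass
class TriangleMesh:
    """Vertices (n×3, mm) and faces (m×3, 0-based, CCW from outside)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be n×3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be m×3")
        # a bare triangle is readable (open surface); closed-surface
        # operations require ≥4 vertices and check watertightness themselves
        if len(self.vertices) < 3:
            raise MeshValidationError("meshes below 3 vertices are rejected")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshValidationError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            self.name if name is None else name)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        return cross / np.maximum(norm, 1e-300)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals, unit length."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        np.add.at(normals, f[:, 0], cross)
        np.add.at(normals, f[:, 1], cross)
        np.add.at(normals, f[:, 2], cross)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        if np.any(norm < 1e-300):
            raise MeshValidationError("zero vertex normal encountered")
        return normals / norm

    def vertex_areas(self) -> np.ndarray:
        """Lumped (one-third) vertex areas in mm²."""
        areas = self.face_areas()
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.faces.ravel(), np.repeat(areas / 3.0, 3))
        return out

    def edges_undirected(self) -> np.ndarray:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        return np.sort(e, axis=1)

    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def centroid(self) -> np.ndarray:
        w = self.vertex_areas()
        return (self.vertices * w[:, None]).sum(axis=0) / w.sum()

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertices).tobytes())
        h.update(np.ascontiguousarray(self.faces).tobytes())
        return h.hexdigest()

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclasses.dataclass
class ValidationReport:
    n_vertices: int
    n_faces: int
    boundary_edges: int
    nonmanifold_edges: int
    components: int
    genus: int | None
    min_face_area: float
    degenerate_faces: int
    oriented: bool
    watertight: bool
    passed: bool

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


@dataclasses.dataclass
class CohortAlignment:
    """Per-subject rigid transforms: aligned = (v - translation) @ rotation.T ...

    Stored so that ``aligned_i = (vertices_i @ rotations[i].T) + translations[i]``.
    Rigid only — scale is deliberately preserved so absolute size survives
    into the learned shape prior.
    """

    rotations: np.ndarray       # s×3×3
    translations: np.ndarray    # s×3
    mean_shape_proxy: np.ndarray
    reflection_flagged: np.ndarray  # s bools
    n_iterations: int = 1


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL_MM):
    """Merge vertices closer than `tol` (exact grid snap), drop degenerates."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    new_faces = inverse[faces]
    keep = ((new_faces[:, 0] != new_faces[:, 1]) &
            (new_faces[:, 1] != new_faces[:, 2]) &
            (new_faces[:, 0] != new_faces[:, 2]))
    return vertices[first], new_faces[keep]


def read_mesh(path, format: str = "auto") -> TriangleMesh:
    """Read an OBJ/PLY/STL surface. STL facets are vertex-welded at 1e-6 mm."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = path.suffix.lstrip(".").lower() if format == "auto" else format
    if fmt not in ("obj", "ply", "stl"):
        raise MeshFormatError(f"unsupported mesh format: {fmt}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - trimesh raises various types
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.size == 0:
        raise MeshFormatError(f"{path}: no faces")
    if fmt == "stl":
        vertices, faces = _weld(vertices, faces)
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise MeshValidationError(f"{path}: face index out of range")
    return TriangleMesh(vertices, faces, name=path.stem)


def write_mesh(mesh: TriangleMesh, path, format: str | None = None):
    """Write a mesh; round-trips faces exactly and coordinates to 1e-6 mm."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("obj", "ply", "stl"):
        raise MeshFormatError(f"unsupported mesh format: {fmt}")
    path.parent.mkdir(parents=True, exist_ok=True)
    # explicit ASCII writers with fixed precision: binary PLY/STL carry
    # float32 coordinates, which would break the 1e-6 mm round-trip contract
    # at anatomical (hundreds of mm) scales
    if fmt == "obj":
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0]+1} {f[1]+1} {f[2]+1}\n")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n"
                     f"element vertex {mesh.n_vertices}\n"
                     "property double x\nproperty double y\nproperty double z\n"
                     f"element face {mesh.n_faces}\n"
                     "property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:  # stl (ascii)
        normals = mesh.face_normals()
        with open(path, "w") as fh:
            fh.write(f"solid {mesh.name or 'mesh'}\n")
            for f, n in zip(mesh.faces, normals):
                fh.write(f" facet normal {n[0]:.9f} {n[1]:.9f} {n[2]:.9f}\n"
                         "  outer loop\n")
                for vi in f:
                    v = mesh.vertices[vi]
                    fh.write(f"   vertex {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
                fh.write("  endloop\n endfacet\n")
            fh.write(f"endsolid {mesh.name or 'mesh'}\n")
    return path


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_mesh(mesh: TriangleMesh, require_watertight: bool = False) -> ValidationReport:
    """Report boundary/non-manifold edges, components, genus, orientation.

    Report-only: never raises on a bad mesh.
    """
    areas = mesh.face_areas()
    degenerate = int(np.sum(areas <= MIN_FACE_AREA_MM2))
    distinct = ((mesh.faces[:, 0] != mesh.faces[:, 1]) &
                (mesh.faces[:, 1] != mesh.faces[:, 2]) &
                (mesh.faces[:, 0] != mesh.faces[:, 2]))
    degenerate += int(np.sum(~distinct))

    und = mesh.edges_undirected()
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary = int(np.sum(counts == 1))
    nonmanifold = int(np.sum(counts > 2))

    # orientation: each directed edge must appear exactly once
    directed = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                               mesh.faces[:, [2, 0]]])
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    oriented = bool(np.all(dcounts == 1))

    n, m, e = mesh.n_vertices, mesh.n_faces, len(uniq)
    adj = sp.coo_matrix((np.ones(len(und)), (und[:, 0], und[:, 1])), shape=(n, n))
    ncomp = sp.csgraph.connected_components(adj + adj.T, directed=False)[0]

    closed = boundary == 0 and nonmanifold == 0
    genus = None
    if closed and ncomp == 1:
        chi = n - e + m
        if (2 - chi) % 2 == 0:
            genus = (2 - chi) // 2
    watertight = bool(closed and ncomp == 1 and oriented and genus == 0
                      and degenerate == 0)
    passed = watertight if require_watertight else (degenerate == 0 and nonmanifold == 0)
    return ValidationReport(
        n_vertices=n, n_faces=m, boundary_edges=boundary,
        nonmanifold_edges=nonmanifold, components=int(ncomp), genus=genus,
        min_face_area=float(areas.min()) if len(areas) else 0.0,
        degenerate_faces=degenerate, oriented=oriented,
        watertight=watertight, passed=bool(passed))


def require_watertight(mesh: TriangleMesh, what: str = "operation"):
    rep = validate_mesh(mesh, require_watertight=True)
    if not rep.watertight:
        raise MeshValidationError(
            f"{what} requires a watertight genus-0 mesh "
            f"(boundary={rep.boundary_edges}, nonmanifold={rep.nonmanifold_edges}, "
            f"components={rep.components}, genus={rep.genus})")
    return rep


# ---------------------------------------------------------------------------
# Preprocessing: simplification + vertex redistribution
# ---------------------------------------------------------------------------

def tangential_smooth(mesh: TriangleMesh, iterations: int = 10,
                      step: float = 0.5,
                      reference: TriangleMesh | None = None) -> TriangleMesh:
    """Tangential Laplacian smoothing with back-projection to a reference.

    Moves every vertex toward its one-ring barycentre, keeps only the
    component tangent to the surface, then snaps back onto `reference`
    (defaults to the input) so surface deviation stays small.
    """
    ref = reference if reference is not None else mesh
    locator = MeshLocator(ref.vertices, ref.faces)
    und = mesh.edges_undirected()
    uniq = np.unique(und, axis=0)
    n = mesh.n_vertices
    deg = np.zeros(n)
    np.add.at(deg, uniq.ravel(), 1.0)
    v = mesh.vertices.copy()
    for _ in range(iterations):
        nbr_sum = np.zeros_like(v)
        np.add.at(nbr_sum, uniq[:, 0], v[uniq[:, 1]])
        np.add.at(nbr_sum, uniq[:, 1], v[uniq[:, 0]])
        lap = nbr_sum / deg[:, None] - v
        normals = TriangleMesh(v, mesh.faces, mesh.name).vertex_normals()
        lap -= np.einsum("ij,ij->i", lap, normals)[:, None] * normals
        v = v + step * lap
        v, _, _ = locator.query(v)
    return TriangleMesh(v, mesh.faces.copy(), mesh.name)


def preprocess_mesh(mesh: TriangleMesh, target_vertex_count: int,
                    redistribution_iters: int = 10) -> TriangleMesh:
    """Simplify to ~target vertex count and redistribute vertices.

    Quadric edge collapse to the exact target, then tangential smoothing with
    back-projection onto the input surface. Output stays watertight genus-0.
    """
    from .decimate import quadric_decimate

    if target_vertex_count < 4:
        raise MeshValidationError("target_vertex_count must be ≥ 4")
    require_watertight(mesh, "preprocess_mesh")
    work = mesh
    if target_vertex_count > work.n_vertices:
        tm = work.to_trimesh()
        while len(tm.vertices) < target_vertex_count:
            tm = tm.subdivide()
        work = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), mesh.name)
    out = quadric_decimate(work, target_vertex_count)
    if redistribution_iters > 0:
        out = tangential_smooth(out, redistribution_iters, reference=mesh)
    rep = validate_mesh(out, require_watertight=True)
    if not rep.watertight:
        raise MeshValidationError("simplification destroyed watertightness/genus")
    if abs(out.n_vertices - target_vertex_count) > max(1, round(0.02 * target_vertex_count)):
        raise MeshValidationError(
            f"could not reach target vertex count {target_vertex_count} "
            f"(got {out.n_vertices})")
    return out


# ---------------------------------------------------------------------------
# Generalized Procrustes Alignment (rigid)
# ---------------------------------------------------------------------------

def _principal_frame(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, bool]:
    """Deterministic anatomical frame from area-weighted vertex moments.

    Longest principal axis → z (longitudinal), second → x (medial–lateral),
    third → y (anterior–posterior). Axis signs are fixed by third central
    moments (skewness) so the frame is stable across rigid motions; if sign
    disambiguation forces a flip against a significant skewness a reflection
    is flagged.
    """
    w = mesh.vertex_areas()
    w = w / w.sum()
    c = (mesh.vertices * w[:, None]).sum(axis=0)
    x = mesh.vertices - c
    cov = (x * w[:, None]).T @ x
    evals, evecs = np.linalg.eigh(cov)           # ascending
    ax_z = evecs[:, 2]                           # longest axis → z
    # longitudinal sign from the third moment (consistent within a family)
    skew_z = float((w * (x @ ax_z) ** 3).sum())
    if skew_z < 0:
        ax_z = -ax_z
    zc = x @ ax_z
    z_lo, z_hi = np.quantile(zc, [0.2, 0.8])
    length = float(zc.max() - zc.min())

    def cap_offset(mask):
        ww = w[mask] / w[mask].sum()
        p = (x[mask] * ww[:, None]).sum(axis=0)
        return p - np.dot(p, ax_z) * ax_z        # transverse component

    # azimuth from the transverse offset of an end cap relative to the
    # shaft axis (the neck-direction analogue on long bones): far more
    # stable than the middle/short covariance eigenvectors, whose
    # eigenvalues are nearly degenerate for near-elliptic cross-sections
    off = cap_offset(zc < z_lo)
    if np.linalg.norm(off) < 0.005 * length:
        off = cap_offset(zc > z_hi)
    if np.linalg.norm(off) >= 0.005 * length:
        ax_x = off / np.linalg.norm(off)
    else:
        # transversely symmetric shape: fall back to the middle eigenvector
        # with a skewness-fixed sign
        ax_x = evecs[:, 1]
        if float((w * (x @ ax_x) ** 3).sum()) < 0:
            ax_x = -ax_x
        ax_x = ax_x - np.dot(ax_x, ax_z) * ax_z
        ax_x /= np.linalg.norm(ax_x)
    ax_y = np.cross(ax_z, ax_x)                  # right-handed by construction
    skew_y = float((w * (x @ ax_y) ** 3).sum())
    scale = float(np.trace(cov)) ** 1.5
    reflection = skew_y < -1e-4 * scale          # significant mirror asymmetry
    R = np.stack([ax_x, ax_y, ax_z], axis=0)     # rows: new x, y, z in old coords
    return R, c, reflection


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, bool]:
    """Optimal rotation R with dst ≈ src @ R.T (centered inputs)."""
    H = src.T @ dst
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, d < 0


def gpa_align(cohort: list[TriangleMesh], max_iters: int = 20, tol: float = 1e-9,
              method: str = "axes") -> tuple[list[TriangleMesh], CohortAlignment]:
    """Rigidly align a cohort into a shared anatomical frame (no scaling).

    method="axes" (default): correspondence-free, each mesh is put into its
    deterministic principal frame — suitable for heterogeneous tessellations.
    method="landmarks": classic iterative GPA with Kabsch against an evolving
    consensus; requires all meshes to share vertex count and correspondence.
    """
    if len(cohort) < 2:
        raise MeshValidationError("gpa_align needs at least 2 meshes")
    s = len(cohort)
    rotations = np.zeros((s, 3, 3))
    translations = np.zeros((s, 3))
    flags = np.zeros(s, dtype=bool)

    if method == "axes":
        aligned = []
        for i, mesh in enumerate(cohort):
            R, c, refl = _principal_frame(mesh)
            v = (mesh.vertices - c) @ R.T
            aligned.append(TriangleMesh(v, mesh.faces.copy(), mesh.name))
            rotations[i] = R
            translations[i] = -R @ c
            flags[i] = refl
        proxy = np.stack([m.vertices.max(axis=0) - m.vertices.min(axis=0)
                          for m in aligned]).mean(axis=0)
        return aligned, CohortAlignment(rotations, translations, proxy, flags, 1)

    if method != "landmarks":
        raise ValueError(f"unknown GPA method: {method}")
    counts = {m.n_vertices for m in cohort}
    if len(counts) != 1:
        raise MeshValidationError("landmark GPA requires matched vertex counts")
    centered = []
    for i, mesh in enumerate(cohort):
        c = mesh.vertices.mean(axis=0)
        centered.append(mesh.vertices - c)
        translations[i] = -c
        rotations[i] = np.eye(3)
    consensus = centered[0].copy()
    n_it = 0
    for n_it in range(1, max_iters + 1):
        for i, v in enumerate(centered):
            R, refl = _kabsch(v, consensus)
            flags[i] |= refl
            rotations[i] = R
        aligned_v = [v @ rotations[i].T for i, v in enumerate(centered)]
        new_consensus = np.mean(aligned_v, axis=0)
        change = float(np.linalg.norm(new_consensus - consensus) /
                       max(np.linalg.norm(consensus), 1e-300))
        consensus = new_consensus
        if change < tol:
            break
    aligned = [TriangleMesh(v @ rotations[i].T, cohort[i].faces.copy(), cohort[i].name)
               for i, v in enumerate(centered)]
    # fold the pre-centering into the stored translation: aligned = (x + t) @ R.T
    translations = translations.copy()
    return aligned, CohortAlignment(rotations, translations, consensus, flags, n_it)
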