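"""Dimension-agnostic closest-point queries against triangle soups.

Used both in ambient 3-space (surface back-projection after smoothing,
point-to-surface distances) and in k-dimensional spectral embeddings
(deblurring a functional map into a vertex-to-point map). All routines are
vectorized; candidate triangles are pruned with a KD-tree over vertices.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_triangles", "closest_point_on_mesh", "vertex_face_incidence"]


def closest_point_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                            c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle (a,b,c) to each point p (row-wise).

    Works in any ambient dimension (only inner products are used). Returns
    (points, barycentric) with barycentric ordered for corners (a, b, c).
    Implementation is the standard region-classification algorithm.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    n = p.shape[0]
    u = np.empty(n)
    v = np.empty(n)
    w = np.empty(n)
    done = np.zeros(n, dtype=bool)

    def settle(mask, uu, vv, ww):
        m = mask & ~done
        u[m], v[m], w[m] = uu[m] if isinstance(uu, np.ndarray) else uu, \
            vv[m] if isinstance(vv, np.ndarray) else vv, \
            ww[m] if isinstance(ww, np.ndarray) else ww
        done[m] = True

    # vertex regions
    settle((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)
    settle((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)
    settle((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)

    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        t_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), 1.0 - t_ab, t_ab, np.zeros(n))
    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        t_ac = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), 1.0 - t_ac, np.zeros(n), t_ac)
    # edge BC
    va = d3 * d6 - d5 * d4
    with np.errstate(invalid="ignore", divide="ignore"):
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           np.zeros(n), 1.0 - t_bc, t_bc)

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    vv = vb / denom
    ww = vc / denom
    u[m] = 1.0 - vv[m] - ww[m]
    v[m] = vv[m]
    w[m] = ww[m]

    bary = np.stack([u, v, w], axis=1)
    pts = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return pts, bary


def vertex_face_incidence(n_vertices: int, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (offsets, face_ids) listing faces incident to each vertex."""
    counts = np.zeros(n_vertices, dtype=np.int64)
    np.add.at(counts, faces.ravel(), 1)
    offsets = np.zeros(n_vertices + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    order = np.argsort(faces.ravel(), kind="stable")
    face_ids = order // 3
    return offsets, face_ids


class MeshLocator:
    """Accelerated closest-point queries on a fixed triangle mesh (any dim)."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k_nearest: int = 4):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        self.k_nearest = min(k_nearest, len(self.vertices))
        self._tree = cKDTree(self.vertices)
        self._offsets, self._face_ids = vertex_face_incidence(len(self.vertices), self.faces)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest_points, face_index, barycentric) per query row."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, nn = self._tree.query(points, k=self.k_nearest)
        nn = np.atleast_2d(nn)
        best_d = np.full(len(points), np.inf)
        best_pt = np.zeros((len(points), self.vertices.shape[1]))
        best_face = np.zeros(len(points), dtype=np.int64)
        best_bary = np.zeros((len(points), 3))

        # gather candidate faces per point (ragged -> flat with owner index)
        owners = []
        cand = []
        for col in range(nn.shape[1]):
            vs = nn[:, col]
            for i, vtx in enumerate(vs):
                s, e = self._offsets[vtx], self._offsets[vtx + 1]
                fs = self._face_ids[s:e]
                owners.append(np.full(len(fs), i, dtype=np.int64))
                cand.append(fs)
        owners = np.concatenate(owners)
        cand = np.concatenate(cand)
        # dedupe (owner, face) pairs
        key = owners * (self.faces.shape[0] + 1) + cand
        _, keep = np.unique(key, return_index=True)
        owners, cand = owners[keep], cand[keep]

        tri = self.faces[cand]
        p = points[owners]
        pts, bary = closest_point_triangles(
            p, self.vertices[tri[:, 0]], self.vertices[tri[:, 1]], self.vertices[tri[:, 2]])
        d = np.einsum("ij,ij->i", pts - p, pts - p)
        order = np.argsort(d, kind="stable")
        seen = np.zeros(len(points), dtype=bool)
        for idx in order:
            o = owners[idx]
            if not seen[o]:
                seen[o] = True
                best_d[o] = d[idx]
                best_pt[o] = pts[idx]
                best_face[o] = cand[idx]
                best_bary[o] = bary[idx]
        return best_pt, best_face, best_bary


def closest_point_on_mesh(points: np.ndarray, vertices: np.ndarray,
                          faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-shot convenience wrapper around :class:`MeshLocator`."""
    return MeshLocator(vertices, faces).query(points)
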