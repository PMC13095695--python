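"""Quadric edge-collapse simplification for closed manifold triangle meshes.

Standard QEM: each vertex carries the sum of its incident faces' plane
quadrics; an edge collapse is placed at the point minimising the combined
quadric and costed by the residual. Collapses that would break the manifold
structure (link condition), flip face normals, or create degenerate faces are
rejected. Collapsing proceeds until the requested vertex count is reached,
which keeps genus and watertightness intact on genus-0 inputs.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["quadric_decimate"]


def _face_quadric(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    area = 0.5 * np.linalg.norm(n)
    if area < 1e-300:
        return np.zeros((4, 4))
    n = n / (2.0 * area)
    d = -np.dot(n, p0)
    plane = np.array([n[0], n[1], n[2], d])
    return area * np.outer(plane, plane)


def _optimal_placement(Q, pu, pv):
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        if np.linalg.cond(A) < 1e7:
            pos = np.linalg.solve(A, b)
            return pos, float(_cost(Q, pos))
    except np.linalg.LinAlgError:
        pass
    cands = [0.5 * (pu + pv), pu, pv]
    costs = [float(_cost(Q, p)) for p in cands]
    i = int(np.argmin(costs))
    return cands[i], costs[i]


def _cost(Q, p):
    ph = np.array([p[0], p[1], p[2], 1.0])
    return ph @ Q @ ph


def quadric_decimate(mesh, target_vertices: int):
    """Collapse edges of a watertight mesh down to exactly `target_vertices`."""
    from .mesh_core import MeshValidationError, TriangleMesh

    V = mesh.vertices.copy()
    F = mesh.faces.copy()
    n = len(V)
    if target_vertices >= n:
        return mesh.copy()
    if target_vertices < 4:
        raise MeshValidationError("cannot decimate below 4 vertices")

    quadrics = np.zeros((n, 4, 4))
    vertex_faces: list[set[int]] = [set() for _ in range(n)]
    for fi, (a, b, c) in enumerate(F):
        K = _face_quadric(V[a], V[b], V[c])
        for vtx in (a, b, c):
            quadrics[vtx] += K
            vertex_faces[vtx].add(fi)

    face_alive = np.ones(len(F), dtype=bool)
    vert_alive = np.ones(n, dtype=bool)
    version = np.zeros(n, dtype=np.int64)

    def neighbors(u):
        out = set()
        for fi in vertex_faces[u]:
            if face_alive[fi]:
                out.update(F[fi])
        out.discard(u)
        return out

    heap: list = []

    def push_edge(u, v):
        if u > v:
            u, v = v, u
        Q = quadrics[u] + quadrics[v]
        pos, cost = _optimal_placement(Q, V[u], V[v])
        heapq.heappush(heap, (cost, int(version[u]), int(version[v]), u, v,
                              pos.tolist()))

    edges = {tuple(sorted(e)) for f in F for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))}
    for u, v in edges:
        push_edge(u, v)

    alive_count = n
    while alive_count > target_vertices and heap:
        cost, vu, vv, u, v, pos = heapq.heappop(heap)
        if not (vert_alive[u] and vert_alive[v]):
            continue
        if vu != version[u] or vv != version[v]:
            continue
        nu, nv = neighbors(u), neighbors(v)
        if v not in nu:
            continue
        common = nu & nv
        if len(common) != 2:          # link condition (closed manifold)
            continue
        pos = np.asarray(pos)
        # normal-flip / degeneracy check on surviving faces of u and v
        ok = True
        touched = [fi for fi in (vertex_faces[u] | vertex_faces[v]) if face_alive[fi]]
        dying = [fi for fi in touched if u in F[fi] and v in F[fi]]
        for fi in touched:
            if fi in dying:
                continue
            tri = F[fi]
            p_old = [V[t] for t in tri]
            p_new = [pos if t in (u, v) else V[t] for t in tri]
            n_old = np.cross(p_old[1] - p_old[0], p_old[2] - p_old[0])
            n_new = np.cross(p_new[1] - p_new[0], p_new[2] - p_new[0])
            if np.linalg.norm(n_new) < 1e-14 or np.dot(n_old, n_new) <= 0:
                ok = False
                break
        if not ok:
            continue

        # commit: v survives at pos, u dies
        V[v] = pos
        quadrics[v] = quadrics[u] + quadrics[v]
        for fi in dying:
            face_alive[fi] = False
        for fi in list(vertex_faces[u]):
            if not face_alive[fi]:
                continue
            F[fi][F[fi] == u] = v
            vertex_faces[v].add(fi)
        vertex_faces[u].clear()
        vert_alive[u] = False
        version[u] += 1
        version[v] += 1
        alive_count -= 1
        for w in neighbors(v):
            version[w] += 0  # versions unchanged; re-push edges with v
            push_edge(v, w)

    if alive_count > target_vertices:
        raise MeshValidationError(
            f"decimation stalled at {alive_count} vertices (target {target_vertices})")

    new_index = -np.ones(n, dtype=np.int64)
    new_index[vert_alive] = np.arange(alive_count)
    out_faces = new_index[F[face_alive]]
    return TriangleMesh(V[vert_alive], out_faces, mesh.name)
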