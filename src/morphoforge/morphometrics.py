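"""Morphometrics of bone-like shapes: directional extents, shaft centerline,
fitted curvature / equivalent radius, slenderness.

These quantify the semantic factors a trained shape prior's latent
dimensions control (overall size, slenderness, shaft length, bending
curvature). All measures assume the canonical anatomical frame
(x medial–lateral, y anterior–posterior, z longitudinal), i.e. meshes
aligned by the cohort alignment stage; extents are deliberately
frame-dependent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh

from .mesh_core import TriangleMesh

__all__ = ["MorphometricReport", "directional_extents", "shaft_centerline",
           "fit_curvature", "measure", "traversal_report"]

INFINITE_RADIUS = float("inf")
_CURVATURE_EPS = 1e-9


@dataclasses.dataclass
class MorphometricReport:
    extent_ml: float        # mm, x
    extent_ap: float        # mm, y
    extent_long: float      # mm, z
    shaft_curvature: float  # 1/mm
    equivalent_radius: float  # mm; inf when the centerline is straight
    slenderness: float      # extent_long / mean shaft diameter

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def directional_extents(mesh: TriangleMesh) -> tuple[float, float, float]:
    """Axis-aligned extents (ML, AP, longitudinal) in the canonical frame."""
    span = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    return float(span[0]), float(span[1]), float(span[2])


def _section_centroid_area(mesh: trimesh.Trimesh, z: float) -> tuple[np.ndarray, float]:
    """Area-weighted centroid of the planar cross-section at height z."""
    section = mesh.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if section is None:
        raise ValueError(f"empty cross-section at z={z:.3f}")
    centroid = np.zeros(2)
    area = 0.0
    for loop in section.discrete:          # closed 3D polylines
        pts = np.asarray(loop)[:, :2]
        x, y = pts[:, 0], pts[:, 1]
        cross = x[:-1] * y[1:] - x[1:] * y[:-1]
        a = 0.5 * cross.sum()
        if abs(a) < 1e-12:
            continue
        cx = np.sum((x[:-1] + x[1:]) * cross) / (6.0 * a)
        cy = np.sum((y[:-1] + y[1:]) * cross) / (6.0 * a)
        centroid += abs(a) * np.array([cx, cy])
        area += abs(a)
    if area <= 0:
        raise ValueError(f"degenerate cross-section at z={z:.3f}")
    return np.array([centroid[0] / area, centroid[1] / area, z]), area


def shaft_centerline(mesh: TriangleMesh, z_lo_frac: float = 0.25,
                     z_hi_frac: float = 0.75, n_slices: int = 20) -> np.ndarray:
    """Cross-section centroids of the mid-shaft, ordered by z (n_slices × 3).

    The shaft window is a fraction of the longitudinal extent (defaults to
    the central half, the geometric analogue of the section between the
    proximal and distal metaphyses).
    """
    if not (0.0 <= z_lo_frac < z_hi_frac <= 1.0):
        raise ValueError("need 0 <= z_lo_frac < z_hi_frac <= 1")
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    tm = mesh.to_trimesh()
    z0, z1 = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    zs = z0 + (z1 - z0) * np.linspace(z_lo_frac, z_hi_frac, n_slices)
    return np.stack([_section_centroid_area(tm, z)[0] for z in zs])


def _mean_shaft_diameter(mesh: TriangleMesh, z_lo_frac: float = 0.25,
                         z_hi_frac: float = 0.75, n_slices: int = 9) -> float:
    tm = mesh.to_trimesh()
    z0, z1 = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    zs = z0 + (z1 - z0) * np.linspace(z_lo_frac, z_hi_frac, n_slices)
    areas = [_section_centroid_area(tm, z)[1] for z in zs]
    # diameter of the circle with the mean cross-section area
    return float(2.0 * np.sqrt(np.mean(areas) / np.pi))


def fit_curvature(centerline: np.ndarray) -> tuple[float, float]:
    """Total-least-squares circle fit of a polyline: (curvature, radius).

    Points are reduced to their best-fit plane (principal components) and an
    algebraic circle fit is solved there. Collinear input returns curvature
    0 with an infinite equivalent radius.
    """
    pts = np.asarray(centerline, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("centerline must be at least 3 points in 3D")
    c = pts.mean(axis=0)
    X = pts - c
    _, svals, Vt = np.linalg.svd(X, full_matrices=False)
    # collinearity: second singular value negligible vs first
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        return 0.0, INFINITE_RADIUS
    uv = X @ Vt[:2].T                      # in-plane coordinates
    u, v = uv[:, 0], uv[:, 1]
    A = np.column_stack([u, v, np.ones(len(u))])
    b = u**2 + v**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cu, cv = 0.5 * sol[0], 0.5 * sol[1]
    r2 = sol[2] + cu**2 + cv**2
    if r2 <= 0:
        return 0.0, INFINITE_RADIUS
    radius = float(np.sqrt(r2))
    curvature = 1.0 / radius
    if curvature < _CURVATURE_EPS:
        return 0.0, INFINITE_RADIUS
    return curvature, radius


def measure(mesh: TriangleMesh, z_lo_frac: float = 0.25, z_hi_frac: float = 0.75,
            n_slices: int = 20) -> MorphometricReport:
    """Full morphometric report for one mesh in the canonical frame."""
    ml, ap, lg = directional_extents(mesh)
    center = shaft_centerline(mesh, z_lo_frac, z_hi_frac, n_slices)
    curvature, radius = fit_curvature(center)
    diam = _mean_shaft_diameter(mesh, z_lo_frac, z_hi_frac)
    return MorphometricReport(
        extent_ml=ml, extent_ap=ap, extent_long=lg,
        shaft_curvature=curvature, equivalent_radius=radius,
        slenderness=lg / diam)


def traversal_report(meshes: list[TriangleMesh], dim_label: str = "",
                     **measure_kwargs) -> dict:
    """Per-mesh metrics for a latent traversal plus min→max deltas.

    Percent changes are reported relative to the traversal midpoint mesh
    (the latent-mean decode).
    """
    reports = [measure(m, **measure_kwargs) for m in meshes]
    mid = reports[len(reports) // 2]
    fields = ["extent_ml", "extent_ap", "extent_long", "shaft_curvature",
              "slenderness"]
    deltas = {}
    for f in fields:
        vals = np.array([getattr(r, f) for r in reports])
        base = getattr(mid, f)
        deltas[f] = {
            "min": float(vals.min()), "max": float(vals.max()),
            "delta": float(vals.max() - vals.min()),
            "percent": float(100.0 * (vals.max() - vals.min()) / base) if base else np.nan,
        }
    radii = [r.equivalent_radius for r in reports]
    return {"dim": dim_label, "reports": [r.as_dict() for r in reports],
            "deltas": deltas,
            "equivalent_radius_range": (float(np.min(radii)), float(np.max(radii)))}
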