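"""Parametric generator of bone-like watertight surfaces with analytic ground truth.

Clinical bone cohorts are access-restricted, so the pipeline is exercised on
a synthetic stand-in: an elliptical cross-section swept along a circular-arc
centerline, blended into bulged, smoothly-closed end caps (the geometric
analogue of epiphyses). The sweep is translate-only — every cross-section
plane stays normal to the longitudinal z axis and the arc offsets ring
centers in the anterior–posterior (y) direction — so

* the longitudinal extent equals ``length`` exactly,
* mid-shaft cross-sections are exact ellipses with the requested half-axes,
* cross-section centroids lie on an exact circle of curvature
  ``bend_curvature`` in the y–z plane,

giving closed-form ground truth for every morphometric the pipeline reports.
Random re-tessellation (decimation to a random target plus tangential
remeshing) produces discretization-heterogeneous cohorts so registration is
genuinely exercised.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mesh_core import MeshValidationError, TriangleMesh, tangential_smooth, validate_mesh

__all__ = [
    "BoneParams", "CohortSpec", "DEFAULT_PARAM_DISTRIBUTIONS",
    "generate_bone", "generate_bone_parameterized", "generate_cohort",
    "generate_template", "bone_surface_points", "retessellate_mesh",
]


@dataclasses.dataclass
class BoneParams:
    """Ground-truth morphological parameters of one synthetic bone.

    Units: mm for lengths/radii, 1/mm for curvature. ``bend_curvature`` is
    signed (bowing direction along ±y); ``shaft_fraction`` is the fraction of
    total length occupied by the prismatic shaft; ``epiphysis_scale`` is the
    end-cap bulge factor relative to the shaft cross-section.
    """

    length: float = 420.0
    shaft_radius_ml: float = 14.0
    shaft_radius_ap: float = 12.0
    bend_curvature: float = 1.2e-3
    shaft_fraction: float = 0.5
    epiphysis_scale: float = 1.8
    taper: float = 0.1
    head_offset: float = 8.0
    seed: int = 0

    def validate(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.shaft_radius_ml <= 0 or self.shaft_radius_ap <= 0:
            raise ValueError("shaft radii must be positive")
        if abs(self.bend_curvature) * self.length >= 1.0:
            raise ValueError("self-intersecting parameters: |bend_curvature|*length >= 1")
        if not (0.0 < self.shaft_fraction < 1.0):
            raise ValueError("shaft_fraction must lie in (0, 1)")
        if not (1.0 <= self.epiphysis_scale <= 3.0):
            raise ValueError("epiphysis_scale must lie in [1, 3]")
        if self.head_offset < 0:
            raise ValueError("head_offset must be >= 0")
        return self


# per-field (mean, spread) of the emulated cohort
DEFAULT_PARAM_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "length": (420.0, 25.0),
    "shaft_radius_ml": (14.0, 1.5),
    "shaft_radius_ap": (12.0, 1.2),
    "bend_curvature": (1.2e-3, 4.0e-4),
    "shaft_fraction": (0.5, 0.04),
    "epiphysis_scale": (1.8, 0.25),
    "taper": (0.1, 0.03),
    "head_offset": (8.0, 1.5),
}

_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "length": (100.0, 1000.0),
    "shaft_radius_ml": (4.0, 40.0),
    "shaft_radius_ap": (4.0, 40.0),
    "bend_curvature": (-2.0e-3, 2.0e-3),
    "shaft_fraction": (0.2, 0.8),
    "epiphysis_scale": (1.0, 3.0),
    "taper": (-0.3, 0.3),
    "head_offset": (0.0, 20.0),
}


@dataclasses.dataclass
class CohortSpec:
    """Recipe for an emulated cohort with known per-subject ground truth."""

    n_subjects: int = 90
    param_distributions: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PARAM_DISTRIBUTIONS))
    retessellate: bool = True
    seed: int = 0
    resolution: int = 1500

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for k, (_, sd) in self.param_distributions.items():
            if sd < 0:
                raise ValueError(f"spread of {k} must be >= 0")
        return self


# ---------------------------------------------------------------------------
# Analytic surface
# ---------------------------------------------------------------------------

def _radial_envelope(params: BoneParams, t: np.ndarray) -> np.ndarray:
    """Dimensionless radius multiplier g(t); g=1 in the shaft, 0 at the poles."""
    t = np.asarray(t, dtype=np.float64)
    t0 = 0.5 * (1.0 - params.shaft_fraction)
    t1 = 1.0 - t0
    e = params.epiphysis_scale
    g = np.ones_like(t)

    prox = t < t0
    u = np.clip(t[prox] / t0, 0.0, 1.0)
    g[prox] = (1.0 + (e - 1.0) * np.sin(np.pi * u)) * np.sqrt(u * (2.0 - u))

    dist = t > t1
    u = np.clip((1.0 - t[dist]) / t0, 0.0, 1.0)
    g[dist] = (1.0 + (e - 1.0) * np.sin(np.pi * u)) * np.sqrt(u * (2.0 - u))
    return g


def _centerline_offset(params: BoneParams, z: np.ndarray) -> np.ndarray:
    """y offset of the cross-section center at height z (exact circular arc)."""
    z = np.asarray(z, dtype=np.float64)
    k = params.bend_curvature
    if abs(k) < 1e-12:
        return np.zeros_like(z)
    R = 1.0 / abs(k)
    L = params.length
    y = np.sqrt(R**2 - (z - L / 2.0) ** 2) - np.sqrt(R**2 - (L / 2.0) ** 2)
    return np.sign(k) * y


def bone_surface_points(params: BoneParams, t, theta) -> np.ndarray:
    """Exact surface point at parameters (t along axis in [0,1], theta around)."""
    t = np.asarray(t, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    g = _radial_envelope(params, t)
    m = 1.0 - params.taper * (t - 0.5)
    a = params.shaft_radius_ml * g * m
    b = params.shaft_radius_ap * g * m
    z = t * params.length
    y0 = _centerline_offset(params, z)
    # femoral-head-like medial offset of the proximal cap: breaks the
    # medial-lateral mirror symmetry and the proximal/distal interchange
    # symmetry exactly as real long bones do, while vanishing in the shaft
    # so every shaft-based ground truth stays closed-form
    t0 = 0.5 * (1.0 - params.shaft_fraction)
    u = np.clip(t / t0, 0.0, 1.0)
    x0 = params.head_offset * np.sin(np.pi * np.minimum(u, 1.0)) * (t < t0)
    return np.stack([a * np.cos(theta) + x0, b * np.sin(theta) + y0, z], axis=-1)


# ---------------------------------------------------------------------------
# Structured meshing
# ---------------------------------------------------------------------------

def _grid_shape(params: BoneParams, resolution: int) -> tuple[int, int]:
    """Pick rings R and segments S with R*S + 2 ≈ resolution, near-isotropic."""
    r_mean = 0.5 * (params.shaft_radius_ml + params.shaft_radius_ap)
    # balance ring spacing L/R against circumferential spacing 2*pi*r/S
    ratio = params.length / (2.0 * np.pi * r_mean * 1.4)   # caps are fatter
    R = max(3, int(round(np.sqrt((resolution - 2) * ratio))))
    S = max(3, int(round((resolution - 2) / R)))
    return R, S


def _structured_bone(params: BoneParams, rings: int, segments: int):
    """Vertices/faces plus the (t, theta) parameter grid behind each vertex."""
    R, S = rings, segments
    t_rings = np.arange(1, R + 1) / (R + 1.0)
    theta = 2.0 * np.pi * np.arange(S) / S

    tt, th = np.meshgrid(t_rings, theta, indexing="ij")
    ring_pts = bone_surface_points(params, tt.ravel(), th.ravel())
    pole0 = bone_surface_points(params, np.array([0.0]), np.array([0.0]))
    pole1 = bone_surface_points(params, np.array([1.0]), np.array([0.0]))
    V = np.concatenate([pole0, ring_pts, pole1])
    t_param = np.concatenate([[0.0], tt.ravel(), [1.0]])
    th_param = np.concatenate([[np.nan], th.ravel(), [np.nan]])

    def vid(i, j):   # ring i in [0, R), segment j mod S
        return 1 + i * S + (j % S)

    faces = []
    top = R * S + 1
    for j in range(S):               # bottom cap: outward normal points -z
        faces.append([0, vid(0, j + 1), vid(0, j)])
    for i in range(R - 1):
        for j in range(S):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j + 1), vid(i + 1, j)
            faces.append([a, b, c])
            faces.append([a, c, d])
    for j in range(S):               # top cap: outward normal points +z
        faces.append([top, vid(R - 1, j), vid(R - 1, j + 1)])
    F = np.asarray(faces, dtype=np.int64)

    # enforce outward orientation via signed volume
    vol = np.einsum("ij,ij->i", V[F[:, 0]],
                    np.cross(V[F[:, 1]], V[F[:, 2]])).sum() / 6.0
    if vol < 0:
        F = F[:, [0, 2, 1]]
    return V, F, t_param, th_param


def generate_bone_parameterized(params: BoneParams, resolution: int = 1500):
    """Generate a bone plus the (t, theta) surface parameters of each vertex.

    The parameter grid is the analytic ground truth used by correspondence
    tests: matched points across tessellations share (t, theta).
    """
    params.validate()
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    R, S = _grid_shape(params, resolution)
    V, F, t, th = _structured_bone(params, R, S)
    mesh = TriangleMesh(V, F, name=f"bone_seed{params.seed}")
    return mesh, t, th


def generate_bone(params: BoneParams, resolution: int = 1500) -> TriangleMesh:
    """Watertight genus-0 bone-like mesh with the requested morphology."""
    mesh, _, _ = generate_bone_parameterized(params, resolution)
    return mesh


def retessellate_mesh(mesh: TriangleMesh, rng: np.random.Generator,
                      target_range: tuple[int, int] = (800, 3000)) -> TriangleMesh:
    """Random re-tessellation: decimate to a random target, then remesh.

    Decimation target drawn uniformly from ``target_range``; three tangential
    smoothing iterations with back-projection onto the input surface jitter
    the vertex distribution without leaving the shape.
    """
    from .decimate import quadric_decimate

    lo, hi = target_range
    hi = min(hi, mesh.n_vertices - 1)
    if hi <= lo:
        target = max(4, min(lo, mesh.n_vertices - 1))
    else:
        target = int(rng.integers(lo, hi + 1))
    out = quadric_decimate(mesh, target)
    out = tangential_smooth(out, iterations=3, step=float(rng.uniform(0.3, 0.7)),
                            reference=mesh)
    return out


def generate_cohort(spec: CohortSpec) -> list[tuple[TriangleMesh, BoneParams]]:
    """Deterministic (per seed) cohort with per-subject ground-truth params."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    # shared structured grid for topology-aligned cohorts: with
    # retessellate=False all subjects get identical connectivity
    mean_kwargs = {k: m for k, (m, _) in spec.param_distributions.items()}
    shared_grid = _grid_shape(BoneParams(**mean_kwargs), spec.resolution)
    out = []
    for i in range(spec.n_subjects):
        kwargs = {}
        for field, (mean, sd) in spec.param_distributions.items():
            lo, hi = _PARAM_BOUNDS[field]
            val = float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, lo, hi))
            kwargs[field] = val
        # keep the arc non-degenerate under extreme joint draws
        if abs(kwargs.get("bend_curvature", 0.0)) * kwargs.get("length", 420.0) >= 0.95:
            kwargs["bend_curvature"] = np.sign(kwargs["bend_curvature"]) * 0.95 / kwargs["length"]
        params = BoneParams(seed=int(spec.seed * 100003 + i), **kwargs)
        if spec.retessellate:
            base = generate_bone(params, resolution=int(rng.integers(2400, 4000)))
            mesh = retessellate_mesh(base, rng)
        else:
            V, F, _, _ = _structured_bone(params, *shared_grid)
            mesh = TriangleMesh(V, F)
        mesh.name = f"subject_{i:03d}"
        out.append((mesh, params))
    return out


def generate_template(resolution_target: int = 1083,
                      params: BoneParams | None = None,
                      max_retries: int = 5) -> TriangleMesh:
    """Bone template with *exactly* ``resolution_target`` vertices.

    A genus-0 closed surface with n vertices has 2n−4 faces, so the default
    1,083-vertex template carries 2,162 faces. When ``resolution_target − 2``
    factors into a reasonable rings×segments grid the structured sweep hits
    the count directly; otherwise the mesh is generated slightly finer and
    quadric-decimated to the exact count.
    """
    if resolution_target < 4:
        raise ValueError("resolution_target must be >= 4")
    params = (params or BoneParams()).validate()
    if resolution_target == 4:
        # degenerate limit: regular tetrahedron scaled to the bone's length
        s = params.length / 2.0
        V = s * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        F = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]], dtype=np.int64)
        return TriangleMesh(V, F, name="template")

    n = resolution_target - 2
    R_ideal, _ = _grid_shape(params, resolution_target)
    best = None
    for R in range(3, n // 3 + 1):
        if n % R == 0:
            S = n // R
            if S < 3:
                continue
            score = abs(np.log(R / max(R_ideal, 1)))
            if best is None or score < best[0]:
                best = (score, R, S)
    if best is not None and best[0] < np.log(2.5):
        _, R, S = best
        V, F, t, th = _structured_bone(params, R, S)
        mesh = TriangleMesh(V, F, name="template")
    else:
        from .decimate import quadric_decimate

        mesh = None
        for attempt in range(max_retries):
            fine = generate_bone(params, resolution=int(resolution_target * 1.5) + 40 * attempt)
            try:
                mesh = quadric_decimate(fine, resolution_target)
                break
            except MeshValidationError:
                continue
        if mesh is None or mesh.n_vertices != resolution_target:
            raise MeshValidationError(
                f"cannot reach exact vertex count {resolution_target}")
        mesh.name = "template"
    rep = validate_mesh(mesh, require_watertight=True)
    if not rep.watertight or mesh.n_vertices != resolution_target:
        raise MeshValidationError("template generation failed watertightness")
    return mesh
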