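# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests demonstrate.

## Geometry substrate

**Meshes.** Watertight genus-0 triangle surfaces in millimetres, with the
anatomical frame convention x = medial–lateral, y = anterior–posterior,
z = longitudinal. Watertightness is checked structurally (every edge in
exactly two faces, consistent winding, one component, Euler characteristic
2 ⇒ m = 2n − 4) and degenerate faces (area ≤ 1e-12 mm²) are rejected.
OBJ/PLY/STL are written as ASCII with fixed 1e-9 precision because binary
PLY/STL carry float32 coordinates, which would break the 1e-6 mm
round-trip contract at anatomical scales. STL facet soups are vertex-welded
on read at 1e-6 mm (grid snap).

**Canonical frame.** Cohort alignment is rigid only (no scaling): absolute
size must survive into the learned shape prior, whose first latent factor
is expected to encode overall size. The correspondence-free variant assigns
each mesh a deterministic frame: the longest principal axis of the
area-weighted vertex covariance becomes z (sign fixed by the third moment);
the azimuth is pinned by the transverse offset of an end cap relative to
the shaft axis — the analogue of the femoral-neck direction — because the
middle/short covariance eigenvalues of near-elliptic cross-sections are
nearly degenerate and their eigenvectors are unstable across subjects; y
completes a right-handed frame. A classic iterative Kabsch variant against
an evolving consensus is available for cohorts with matched vertex counts.
Frames are stable to ~1e-12 under rigid motion and consistent across
tessellations and subjects of the same family.

**Spectral operators.** Cotangent stiffness (weights clamped at ±1e4 to
survive near-degenerate triangles) and one-third-area lumped mass, so the
truncated pseudoinverse is exact and cheap: Φ⁺ = ΦᵀM. Eigenpairs come from
shift-invert Lanczos at σ = −1e-8 with a fixed start vector (ARPACK is
otherwise randomly initialized, which would make eigenvectors of
near-degenerate pairs run-dependent) and a deterministic sign convention.
Default truncation k = 48. Heat diffusion is the closed form
Φ e^{−λt} ΦᵀM; on the rank-k subspace it is an exact semigroup. Under
isotropic scaling by s the basis transforms in closed form (λ → λ/s²,
Φ → Φ/s, M → s²M), which the pretraining loop uses instead of re-solving.

**Closest points.** Projection onto triangle soups (used both in ambient
3-space and in k-dimensional spectral embeddings) uses the standard
region-classification algorithm, vectorized, with KD-tree candidate
pruning; it is validated against dense barycentric-grid oracles.

## Synthetic anatomy

Clinical bone cohorts of the kind this pipeline targets are typically
access-restricted, so all experiments run on a parametric stand-in with
analytic ground truth. A bone is an elliptical cross-section swept along a
circular arc, blended into bulged smoothly-closed end caps, plus a
femoral-head-like transverse offset of the proximal cap. The sweep is
translate-only — ring planes stay normal to z and the arc offsets ring
centers in y — which makes the following exact by construction:

* longitudinal extent = `length` (default 420 mm ± 25 cohort spread);
* mid-shaft cross-sections are exact ellipses with half-axes
  `shaft_radius_ml` (14 ± 1.5 mm) × `shaft_radius_ap` (12 ± 1.2 mm);
* shaft cross-section centroids lie on an exact circle of curvature
  `bend_curvature` (1.2e-3 ± 4e-4 mm⁻¹, i.e. equivalent radii of roughly
  0.5–2 m) in the y–z plane;
* cap cross-section areas scale as `epiphysis_scale`² (1.8 ± 0.25).

The head offset (8 ± 1.5 mm) exists because real long bones are not
mirror-symmetric: a perfectly ML-symmetric shape makes both the canonical
azimuth and spectral correspondence ill-posed (the classic bilateral
symmetry ambiguity). It vanishes inside the shaft so every shaft-based
ground truth above is untouched. Default parameter means and spreads are
the emulated cohort's study conditions and are fixed once in
`DEFAULT_PARAM_DISTRIBUTIONS`.

Re-tessellation (for discretization-heterogeneous cohorts) draws a random
decimation target in [800, 3000] vertices, applies in-repo quadric edge
collapse (link-condition and normal-flip guarded, so genus and
watertightness survive), and jitters the vertex distribution with three
tangential smoothing iterations back-projected onto the original surface.

What the generator does **not** emulate: segmentation noise, cortical
thickness, anatomical landmarks (trochanters, condyles), non-genus-0
defects, and intensity data. Passing tests therefore demonstrate the
pipeline's correctness on clean, near-isometric, genus-0 anatomy — not
robustness to scanner artifacts.

## Self-supervised registration

**Feature extractor.** A heat-diffusion network: per block, (i) per-channel
learned-time spectral diffusion (times parameterized softplus to stay
positive, initialized at 100 mm² ≈ 1 cm smoothing), (ii) tangent-plane
gradient features combined through learned complex-linear mixing whose
inner-product readout is invariant to the per-vertex tangent-basis choice,
(iii) a shared per-vertex MLP with a residual connection. Parameters are
independent of tessellation. Inputs are the raw vertex coordinates in
area-relative units: coordinates are divided by √(A/A_ref) and diffusion
times and gradients multiplied by the matching power of the same factor
(A_ref = 4·10⁴ mm², adult-femur scale). This makes the feature map
*exactly* invariant to isotropic scaling — absolute size is carried by the
registered coordinates and the shape prior, not by correspondence features.
The full-scale configuration is 6 blocks × 256 channels; scaled-down
experiments use 3 blocks × 64 channels with 96 output channels.

**Pretraining.** Siamese branches share weights; each cohort mesh becomes a
perturbed pair (uniform SO(3) rotation, scale U(0.9, 1.1)). Both copies are
put into their canonical frames before feature extraction, mirroring the
pipeline's cohort-level rigid pre-alignment, so the rotation draw exercises
the stability of that alignment while the identity loss concentrates on
scale robustness and spectral richness of the features; a raw-pose mode
(`align_pairs=False`) is kept for experimentation. Functional maps inside
the loss are solved by ridge least squares on channel-normalized
embeddings — the raw spectral embedding scales linearly with the shape, so
per-channel unit normalization removes a structural factor no finite
training run could cancel. The ridge is trace-relative
(λ_eff = λ·tr(ZZᵀ)/k): untrained features span only a few directions and
an absolute ridge is meaningless against them. The three losses are
combined with α = (1, 1, 1) after the two L1-style terms are averaged per
entry so the balance is architecture-independent. Adam, cosine-decayed
learning rate, defaults 500 epochs × batch 4 at full scale; the test
fixture trains 40 epochs on 10 shapes (~1 min CPU), after which a held-out
shape under a fresh rotation+scale pair satisfies ‖C−I‖_F/‖I‖_F ≈ 1e-4
(untrained nets fail this at ≈ 0.4 due to rank deficiency).

**Inference.** Template → target correspondence: features on both
canonically aligned shapes → spectral projection → functional map with the
Laplacian-commutativity prior (μ‖CΛ−ΛC‖², row-separable closed form,
μ = 0.1 relative; the standard near-isometry prior, which keeps maps sane
when features extrapolate poorly) → deblurring: rows of Φ_M C are projected
to closest points on the embedded target surface, alternating with C
refits (the residual ‖Φ_M C − PΦ_N‖ is non-increasing) → conformal
refinement: Adam on corner-angle MSE plus an L1 tangential Laplacian
residual (α = 1.0 / 0.1, tangent term averaged per vertex so the weight is
resolution-independent and commensurate with the radians² angle term;
normals are the target's vertex normals barycentrically interpolated at
the mapped points, which makes a congruent map an exact fixed point),
with per-step re-projection onto the target, best-accepted-state tracking,
and divergence abort after 20 consecutive increases. The registered output
carries the template's face list verbatim with vertices on the target
surface.

On a re-tessellated, rigidly moved copy of the template, the scaled-down
pipeline recovers ground-truth correspondence for ≥ 99% of vertices within
2% of the bounding-box diagonal (median error ~3 mm at ~7 mm edge length).

## Shape-prior VAE

Spiral sequences are deterministic: each vertex lists itself, its
counterclockwise 1-ring starting at the lowest-index neighbor, then outward
rings in parent order, padded with the center index (length 10). Encoder:
3 spiral convolutions (gather, concatenate, per-vertex linear, ELU) × 128
channels at full scale, global mean pooling, two 6-D heads (μ, log σ²).
Decoder mirrors it from a per-vertex seed projected from z. Coordinates are
standardized by the cohort mean shape and the residual spread about it
(standardizing by raw coordinate spread — dominated by the shape itself,
not the variation — starves the reconstruction term and collapses the
posterior). Loss: β·(per-entry L1) + λ_KL·KL with β = 0.9, λ_KL = 0.1,
reparameterized sampling, Adam at 3e-4 (full scale) with λ_KL warmed up
linearly over the first 15% of epochs: measured across seeds, the shorter
warm-up concentrates each generative factor in one latent dimension and
improves aggregate-posterior/prior matching at small epoch budgets.
Defaults: 800 epochs × batch 8, 80/10 seeded split.

Scaled-down experiments train 100 epochs × 32 channels on a 90-shape
cohort (~300-vertex template) in which only length and bending curvature
vary. Encoded means recover both factors (|Spearman ρ| ≈ 0.99 / 0.94 at
the fixed experiment seeds); traversing each matched dimension changes the
corresponding morphometric monotonically; 100 bounded prior samples decode
to watertight meshes without degenerate faces. A known limit at this
scale: bending curvature is the geometrically weak factor (its coordinate
displacement is a ~9 mm sagitta versus a 25 mm length spread), and some
training seeds split it across two latent dimensions, in which case no
single-dimension traversal is monotone in curvature. Larger budgets (the
full-scale configuration) are expected to stabilize this; the acceptance
script reports whatever its seed yields.

## Morphometrics

Extents are axis-aligned spans in the canonical frame (deliberately
frame-dependent). The shaft centerline is the sequence of area-weighted
cross-section centroids over the central z-fraction (default 0.25–0.75 —
the geometric analogue of the inter-metaphyseal shaft, since synthetic
bones carry no anatomical landmarks). Curvature is a total-least-squares
circle fit: points are reduced to their principal plane and an algebraic
fit is solved there; it is exact on noiseless circles over radii
10–10⁵ mm, and collinear input (second singular value ≤ 1e-9 of the first)
returns curvature 0 with an infinite-radius sentinel. Equivalent radius ×
curvature = 1 whenever finite. Slenderness = longitudinal extent / mean
shaft equivalent diameter. Traversal tables report min→max deltas with
percent changes relative to the traversal midpoint (latent-mean decode).

## Volumetric morphing

The shipped baseline is a synthetic tetrahedralized bone (labelled
synthetic throughout): surface shell + centerline axis nodes + wedge-cell
centroids, wedges star-split through their centroids with a
min-index-diagonal rule for shared quads so neighboring cells agree, end
caps fanned into the poles; all Jacobians positive by construction.

Morphing: the baseline's boundary surface is registered onto the target;
the registered displacement field is Laplacian-smoothed (default 20
iterations, smoothing displacements rather than positions so the shape does
not shrink) and re-projected — spectral truncation otherwise leaves
mm-scale jitter that flips small elements; a thin-plate spline (3-D kernel
U(r) = r, bordered system with exact affine reproduction, ≤1000
farthest-point-subsampled controls) carries the interior nodes. Element
connectivity, IDs and labels pass through bit-identically. More than 1%
inverted elements aborts with the offending element ids; any smaller count
warns. Identity morphs (target = own surface) keep interior nodes within
1% of the bounding-box diagonal and invert nothing.

Deck dialects: keyword (\*NODE / \*ELEMENT_SOLID with the repeated-node
tetra convention), Abaqus .inp subset (C3D4), legacy ASCII VTK (cell type
10); each round-trips through its own reader to 1e-6 mm and exact
connectivity.

## Reproducibility and problem sizes

Every stochastic component is seeded; the pipeline driver fans one global
seed into per-stage sub-seeds by hashing stage names, so stages can be
rerun in isolation. The eigensolver start vector is pinned (see above), so
end-to-end reruns reproduce synthesized meshes hash-identically.

Scaled-down study conditions used by the test suite and the acceptance
script, chosen as the package's own desk-scale experiment sizes: feature
extractor 3 × 64/96 channels, k = 48, 10-shape pretraining cohort at
~1200 vertices, 40 epochs; registration targets ~2000–3000 vertices; VAE
32 channels on a ~300-vertex template, 90 shapes, 100 epochs; baseline
solid ~1500 nodes / ~5600 tets. The full-scale defaults (6 × 256, 500
epochs; 128 channels, 800 epochs, 1083-vertex template) remain the
package defaults for production use.

## Known limitations

* Correspondence assumes near-isometric, genus-0, complete shapes;
  partial or topology-changing inputs are out of scope.
* The canonical-frame azimuth convention relies on a transversely
  asymmetric end cap; transversely symmetric shapes fall back to the
  (less stable) covariance eigenvector.
* Latent disentanglement of weak generative factors is seed-sensitive at
  desk-scale training budgets (see above).
* The synthetic cohort's cleanliness overstates performance on clinical
  segmentations; no claim is made about scanner noise or pathology.
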