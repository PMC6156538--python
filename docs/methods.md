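# Methods

This note documents the models, numerical choices and limitations behind
`myofe`, in the order the pipeline runs.

## Mosaic assembly and acquisition averaging

A mosaic is a single 2D image tiling all slices of a 3D acquisition in an
N×N grid. The slice index obeys `m = N(l−1) + k` with 1-based tile
coordinates, where `k` counts tile columns (fastest-varying) and `l` tile
rows; this is the only place a 1-based convention appears — storage is
0-based everywhere else. Trailing empty tiles are detected as all-zero
blocks unless the populated count is given explicitly, so a deliberate
all-zero slice must be declared.

Averaging groups volumes by (b-value, gradient direction), pooling all
b = 0 volumes into a single reference; a 4-repeat, 12-direction protocol
with 12 b0 repeats therefore collapses 60 volumes to 13. Acquisitions with
differing direction sets are rejected rather than silently intersected.

## Local-PCA denoising

Magnitude MR noise is Rician. The denoiser slides a cubic patch
(radius 1, i.e. 3³ voxels, by default) over the volume, forms the
patch-by-volume Casorati matrix, and suppresses principal components of
the across-volume covariance whose eigenvalues fall below τ = 2.3 σ²;
overlapping patch estimates are averaged, and the Rician bias is removed
via `Â = sqrt(max(m̂² − 2σ², 0))`. This is a compact sliding-window variant
of overcomplete local-PCA denoising: the same principle (local low-rank
structure across diffusion volumes, hard eigenvalue threshold, bias
correction), sized so phantom studies run in seconds. σ is a required
input, not estimated; the threshold constant and patch size are defaults
chosen for the 13-volume protocol, where the Marchenko-Pastur bulk of a
27×13 noise matrix is mostly below 2.3 σ².

## Tensor fit and tractography

The tensor fit is standard log-linear least squares on
`ln(S/S0) = −b gᵀDg`, requiring ≥ 6 directions spanning the symmetric
tensor space; voxels with non-positive signals are masked out. Tracking is
deterministic bidirectional Euler integration of the principal eigenvector
with nearest-voxel sampling; the eigenvector sign is re-aligned to the
previous step direction at every step (hemisphere continuity), and
propagation stops on mask exit, FA below a floor, or a turning angle above
a cap (default 45°). The minimum strand length is interpreted in mm
(default 10 mm). The tracking step and angle cap are exposed directly
rather than an opaque "smoothness" knob; integrator order is first
(Euler), which is adequate for the smooth phantom fields the package
targets. Bundling keeps a strand iff at least one point lies in the closed
cropping box.

## Mask smoothing

Binary masks are smoothed by morphological dilation followed by a Gaussian
blur of the indicator and a re-threshold. With the default
`threshold=None`, the cut level is chosen by volume matching: exactly the
original number of voxels with the highest blurred values is kept (ties
broken deterministically by voxel index). The smoothing is then
volume-preserving by construction — the measured relative volume change is
zero up to tie effects — which comfortably respects the sub-0.2%
volume-drift budget expected of segmentation-mask cleanup. A fixed float
threshold remains available; note that a fixed 0.5 cut after dilation
shifts the surface outward by the dilation radius and is *not*
volume-preserving.

## Fibre mapping and RBF smoothing

Fibre directions are axial quantities: `f` and `−f` denote the same fibre.
All summations therefore hemisphere-align contributions first (to the
longest run in the per-element combination; to the element's own or the
nearest seeded direction in field smoothing), and all outputs are
normalised to unit length — raw kernel sums would otherwise cancel
antipodal vectors and carry physically meaningless magnitudes. Shepard
normalisation of the kernel weights is omitted for the same reason: the
output is re-normalised anyway.

Per element, maximal runs of consecutively numbered strand points inside
the element (barycentric classification, boundary counts as inside) are
trend-line fitted by total least squares, the line's sign following the
strand's traversal; runs of a single point carry no direction and are
dropped. Run directions combine with weights `w_s = n_s²/Σn_s²`, favouring
long coherent passages.

Smoothing uses the Gaussian radial basis kernel
`φ = exp(−(p‖x_i−x_e‖/L)²)` per muscle, with `L` the muscle's
axis-aligned bounding-box diagonal and `p = 20` by default; larger `p`
narrows the neighbourhood. Because the AABB diagonal depends on
orientation, an explicit `length_scale` can be passed when exact rotation
equivariance matters. An optional density-scaled mode multiplies `p` by
the cube root of the part's element count relative to a 1000-element
reference, implementing the rule that denser meshes warrant narrower
kernels; it is off by default. Smoothing runs once (not iterated) and
fills every element of a muscle that has at least one seeded direction.
Overlapping bundles are not mutually exclusive; overlaps are the caller's
to resolve.

The `*ELEMENT_SOLID_ORTHO` export writes fixed-width 8-column integer
fields, one connectivity line (tets occupy the 8-node slots with the 4th
node repeated) followed by the fibre axis and an auto-generated orthogonal
second axis; missing directions fall back to the global x-axis with a
logged warning.

## Constitutive law

Soft tissue is modelled as hyperelastic, quasi-incompressible and
transversely isotropic about the fibre direction a0, with
`S = S_iso + (1−γ)(S_pas + α S_act)`; γ = 1 switches the fibre terms off
(fat/skin), α ∈ [0, 1] is a constant activation. Viscoelasticity and
activation dynamics are out of scope. The isotropic matrix is a
compressible Mooney-Rivlin-type law whose B-coefficients cancel exactly at
C = I, so the reference configuration is stress-free for every admissible
parameter set. The volumetric penalty `k(J−1)J C⁻¹` derives from the
energy `k/2 (J−1)²`.

Parameters (mm–MPa–ms–g units) ship as three presets: muscle
(C1 = 2.5×10⁻⁶, C2 = 6×10⁻³, C3 = 10⁻³ MPa, C4 = 6, S_max = 0.1 MPa,
ΔW_asc/dsc = 0.15/0.16, ν_asc/dsc = 2/4, Λ_opt = 1.3, γ = 0), skin/fat
(same numbers, γ = 1, where the stored fibre constants are inert), and a
stiff isotropic liner (C1 = 0.33, C2 = 0.01 MPa). The bulk modulus is not
part of the published soft-tissue set; the default k = 0.1 MPa (≈17× C2)
gives near-incompressible response without dominating the conditioning,
and is a prominent knob — the incompressibility test runs at 10× the
default and holds the volume change of a compressed cylinder under 0.5%.

Both fibre branches are continuous at their switch points: the passive
power law vanishes at Λ = 1, and both active branches equal S_max/Λ_opt²
at Λ = Λ_opt. The active envelope's descending branch is quartic in the
normalised offset, so in double precision the envelope is flat within
~3×10⁻⁵ of the peak — numerical argmax localisation is limited to about
1e-4, far tighter than the 0.1 reporting precision used for it.

Tangents are analytic: `C_mat = 2 ∂S/∂C` assembled from invariant
derivatives (the fourth-order symmetric identity and the C⁻¹ derivative
handle the tensorial parts), and the spatial push-forward
`B_ijkl = J⁻¹ F_iM F_jN F_kO F_lP C_MNOP`. The J⁻¹ factor is included —
the standard spatial tangent conjugate to the Cauchy stress. Consistency
is verified against central finite differences of S in random directions
(1e-6 relative).

## Injury model

The critical strain is a Boltzmann sigmoid in loading time,
`ε_crit = K/(1+exp(β(t−t0))) + C`, strictly decreasing from K + C = 0.6 to
C = 0.332, with midpoint C + K/2 = 0.466 at t0. "Symmetric Green strain"
is taken as the Green-Lagrange tensor E = (C−I)/2, and ε_eff uses the full
(not deviatoric) contraction √(⅔ E:E), exactly as the criterion is
written. Time is measured from load onset; the default analysis window is
2 h = 7.2×10⁶ ms. The sigmoid argument is clipped at ±700 before
exponentiation, so extreme times return the exact asymptotes instead of
overflowing. Classification compares strain histories against the
threshold at the supplied instants (not continuously); flags are
irreversible, and damage is the injured volume percent of the tracked
parts — by default every part not labelled bone/femur/fat/skin/liner/
socket, i.e. muscle.

## Static FE solver

The solver is a deliberate desk-scale reduction: static (ẍ = 0) total
Lagrangian, linear tetrahedra with single-point integration (shape
gradients of linear tets are constant), Dirichlet constraints, nodal
loads and per-part body forces, no contact. Sustained-stance loading is
quasi-static in effect, which is what the static solver represents;
donning, mortar contact and tied interfaces are out of scope. Single-point
linear tets are prone to volumetric locking; the bulk-modulus knob is the
mitigation, and the element is documented as an approximation of
constant-pressure tet formulations, not a bit-match.

Newton's method runs on the residual with the analytic consistent tangent
`A_iJkL = δ_ik S_JL + F_iM C_MJLN F_kN`; loads ramp in equal increments
(default 10; mild cases use fewer). Convergence demands the free-DoF
residual norm fall below tol (default 1e-8) times the larger of the
external-force norm and the increment's initial residual — the fallback
matters for Dirichlet-driven problems whose external-force norm is zero.
Element inversion or a singular system raises a diagnostic error rather
than looping. Observed convergence is quadratic on the logged residuals.
The element-level constitutive evaluation is vectorised over elements; the
FE patch test (affine boundary data on a multi-element box) pins it
against the material-point implementation to 1e-8.

The linear solves use SuperLU with COLAMD ordering; problem sizes are kept
in the tens of thousands of DoFs, where factorisation times are seconds.

## Phantoms and what they do (not) show

Generators are all seeded and deterministic and return ground truth
alongside data. DWI phantoms follow the mono-exponential signal model
`S = S0 exp(−b gᵀDg)` with eigenvalues (1.8, 0.3, 0.3)×10⁻³ mm²/s and
axial, helical or parallel-bundle direction fields, magnitude-Rician noise
added per seed; the default 13-volume scheme (12 Fibonacci-hemisphere
directions at b = 700 s/mm², one b0) mirrors a muscle DTI protocol at
3.2×3.2×3 mm spacing with a reduced matrix. They contain no partial-volume
effects, susceptibility distortion, motion, or crossing fibres, so passing
tests demonstrate algorithmic correctness on the signal model, not
robustness to clinical artefacts.

The cylinder mesh extrudes a triangulated disc (boundary ring on the exact
radius) and splits each prism into three tets with the smallest-global-
index diagonal rule, which makes neighbouring prisms agree — the mesh is
conforming by construction and its volume equals the extruded polygon's,
approaching πr²L as the edge shrinks (≈0.07% deficit at the default
edge = r/5). The box mesh uses the Kuhn 6-tet subdivision. The
mesh-convergence study runs cylinders of r = 5 mm, L = 10 mm at target
edges 4, 2, 1, 0.5 mm (48 → ~38 000 elements) under 5% axial compression
between clamped platens with the isotropic skin/fat preset — sizes chosen
so the whole family solves in a couple of minutes on one CPU while the
two finest levels already agree in σ̄ to well under a percent.

## Known limitations

- No image-based segmentation or meshing: meshes are consumed or
  synthesised, never derived from real scans.
- Tendons, muscle-activation dynamics, viscoelasticity, contact and
  full-limb load cases are out of scope.
- The tracker is single-tensor and deterministic; no crossing-fibre or
  probabilistic variants.
- The ICP is point-to-point; point-to-plane is not implemented.
- Field smoothing can over-smooth sparse muscles; no mutual-exclusion
  checking between overlapping bundles (overlaps are reported upstream,
  not resolved).
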