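# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the limitations of `minfuse`, in the order the pipeline runs.

## Phantom: what it emulates and what it does not

The phantom stands in for a CT scan of an instrumented long bone (an
artificial tibia with a transverse fracture and a lateral locking plate).
It is a geometric idealization, not an anatomical reconstruction:

| feature | phantom | real scan |
|---|---|---|
| diaphysis | circular cortical shell + cancellous core | irregular cross-section, metaphyseal flare |
| fracture | clean transverse gap, soft-tissue filled | oblique/wedge patterns, partial contact |
| implant | rectangular plate slab + cylindrical bicortical screws | anatomical contoured LCP, threads, locking heads |
| image physics | class gray level + Gaussian noise (σ configurable) | beam hardening, metal artifacts, partial volume |

Default geometry (desk scale, 1 mm voxels on a 48×48×120 grid): bone outer
radius 14 mm, cortical thickness 3 mm, 6 mm gap at mid-shaft, 4 mm thick ×
12 mm wide plate in contact with the cortex, 2.5 mm radius screws at
z = 30, 45, 75, 90 mm (two on each side of the gap).  Gray levels 0 / 300 /
1300 / 2600 / 4000 (12-bit) for background / soft / cancellous / cortical /
implant were chosen to be cleanly separable by thresholds — the implant is
deliberately brightest, mirroring how implants are made radiographically
conspicuous.  With the default noise σ = 25 the class separations are ≥ 20σ,
so segmentation errors are rare (the tests assert ≥ 99 % voxel agreement at
σ = 50); what passing tests therefore show is that the *pipeline* is
correct, not that segmentation of clinical CT is solved.

Long axis = third array axis; voxel centers at `origin + (i + 0.5)·spacing`;
the grayscale value is attached to the voxel barycenter.

## Segmentation

Perona–Malik anisotropic diffusion, explicit forward Euler: 6-neighbour
fluxes `g(d)·d` with exponential conductance `g(d) = exp(−(d/κ)²)`,
zero-flux boundaries.  The flux form conserves the global gray sum to
round-off; the explicit 3-D scheme is stable for `dt ≤ 1/6` (enforced).
Defaults: 10 iterations, κ = 120 gray units — κ sits well below the
smallest class separation (500), so class edges are preserved while
in-class noise diffuses.  Segmentation then bins the smoothed grayscale at
cut points (150, 800, 1950, 3300), the midpoints between default class
levels.

The nonunion is marked by an axis-aligned slab in mm (default: the
phantom's gap extent).  Implant and background voxels are never part of
the nonunion mask.  This replaces an interactive outlining step with a
declarative, reproducible specification.

## Coarsening

A `level × level` window in the transverse plane is averaged into one
coarser pixel; trailing pixels that do not fill a window are dropped, so a
width N becomes `floor(N/level)` (512 → 256, 170, 128, 102, 85, 73, 64 for
levels 2–8).  The slice axis is untouched: slice thickness is already
coarse relative to pixel spacing.  An averaged window is *re-classified*
with the same cut points used for segmentation — one consistent
classification rule — which for a grayscale stack is realized by running
`segment` on the block-mean image; the block-mean grayscale itself is kept
because the power-law material map consumes it.  For label volumes the
classes are mapped to their representative gray levels before averaging,
and the nonunion mask is coarsened by majority.

Epiphysis cropping removes a fraction of slices from each end of the long
axis (the load paths of interest are diaphyseal); the pipeline default is
no cropping because the phantom is all shaft.

## Materials

Grayscale `g` → Hounsfield `HU = g − 1024` → apparent density
`ρ = 0.001·HU + 0.224` g/cm³ → modulus `E = 6850·ρ^1.49` MPa.  The density
line plays the role of a scanner calibration phantom: it anchors the
cancellous and cortical gray levels (1300, 2600) at ρ = 0.5 and 1.8 g/cm³.
Bone moduli are clamped to [0.1 MPa, 16.7 GPa]; fixed constants are
soft tissue E = 1 MPa, ν = 0.45; titanium E = 105 GPa, ν = 0.34;
ν_bone = 0.3.  These are standard literature-range values and are fully
configurable; the pipeline's output is explicitly qualitative, so no
site-specific density–modulus relation is attempted.  Apparent and real
density are collapsed into the single calibration line (one configurable
scale) because nothing downstream distinguishes them.

Scenario overrides touch only nonunion-masked voxels: *worst case* sets
them to soft tissue, *full fusion* to cortical bone, and an explicit
boolean mask mixes the two.

## Finite elements

One trilinear hexahedron per non-background voxel (background is removed
rather than given near-zero stiffness — conditioning).  Element stiffness:
isotropic Hooke matrix, 2×2×2 Gauss quadrature; assembly exploits that all
voxels share one geometry, so one unit stiffness per distinct Poisson
ratio is scaled by the element's E.  Units: E in Pa, lengths converted to
meters internally, forces in N, hence displacements in meters and stresses
in Pa.

Boundary conditions for axial body-weight loading: total force
`m·g` (80 kg × 9.81 m/s² = 784.8 N) along −z, split equally over the
top-face nodes of the bone elements in the highest bone slice; every node
of the lowest occupied node plane is fixed in all three components.  Only
the load direction and magnitude are physically prescribed; the
distribution conventions are declared choices.

Solver: sparse direct LU below 30,000 free DOF, Jacobi-preconditioned
conjugate gradients above (relative tolerance 1e-8, cap 20,000 iterations
by default).  Every solve verifies the final residual and the reaction
balance; a disconnected load path surfaces as a singular-system
diagnostic rather than a silent garbage field.  Stress is evaluated once
per element at the centroid — the simplest choice consistent with a voxel
mesh — and condensed to von Mises.  Scaling maps a reference maximum
(the worst-case peak) to 100.

Reference problem sizes: the full-resolution desk phantom meshes to
78,528 elements / 260,595 DOF and solves in ≈ 2,850 CG iterations; the
level-2 grid used for the optimization runs is ≈ 21,000 elements / 74,000
DOF.  These sizes were chosen so a complete pipeline run stays in the
minutes range on a single core.

## Optimization

The loop starts from full fusion and repeatedly demotes every still-fused
nonunion cell whose von Mises stress (from the current state's solve) lies
below `threshold × max`, with `threshold = 0.2`.  Demotion is simultaneous
per sweep; ties (σ exactly at the threshold) are retained; demoted cells
are never restored.  Termination: (a) the post-sweep solve would push the
scaled global maximum past the stop cap (default 84 on the 0–100 scale) —
that sweep is rolled back so the reported state never leaves the validity
envelope; (b) no cell qualifies; (c) a step cap.  The active set strictly
shrinks, so termination is guaranteed, and the whole loop is deterministic
given its inputs.

**Choice of the threshold anchor.**  `max` can be read as the fixed
worst-case maximum or as the maximum arising in the current step; the
package defaults to the *per-step* anchor (`per_step_reference=True`),
with the fixed anchor available as a switch.  The reason is structural:
with a plate bridging a fully severed gap, the worst-case maximum is
dominated by plate bending and sits two orders of magnitude above any
stress a fused gap cell ever carries (172 MPa vs ≤ 3.5 MPa on the desk
phantom).  A fixed anchor then classifies *every* gap cell as irrelevant
in the first sweep, the post-sweep state is the worst case itself
(scaled 100 > cap), and the loop degenerates to an immediate rollback.
The per-step anchor compares gap cells against the stress scale of the
current, fused configuration and recovers the intended progressive
removal.  The stop cap stays anchored at the worst-case scale, which is
also the scale on which results are reported.

On the desk phantom the loop removes 74.3 % of the nonunion in one sweep
and keeps 25.7 % — the cells along the plate-side cortex where the screws
and plate transfer load.  The tests verify against an exhaustive oracle
(solving every single-cell-removal variant of a ~100-cell gap) that the
survivors are the high-impact, load-bearing cells.  The exact surviving
fraction is geometry-specific: a clean transverse gap with four screws is
not a spiral wedge fracture with a 14-hole plate, so the published-style
multi-step trajectories and single-digit remaining fractions should not
be expected from this phantom, only the qualitative finding that far less
than the full cross-section is mechanically relevant.

## Degenerate inputs and edge behaviour

Zero diffusion iterations is the identity; a constant image is a fixed
point.  A nonunion slab that misses all tissue warns and yields an empty
mask; an empty mask is rejected by the optimizer (there is nothing to
optimize).  Coarsening levels larger than the image width, non-monotone
thresholds, crop fractions summing to ≥ 1, non-positive reference maxima
and elastically inadmissible constants (E ≤ 0, ν outside (−1, 0.5)) are
all rejected with specific errors.  A solver failure mid-optimization
returns the trajectory up to the last completed step with a failure flag.

## Known limitations

- Single static axial load case; no torsion, shear or gait kinematics, so
  the minimal fusion area found here is a lower bound on what multi-axial
  loading would require.
- Linear elasticity; no contact, screw threads, or implant–bone
  micromotion; "cyclic" loading is represented by one static solve, which
  is exact up to amplitude scaling in a linear model.
- No remodeling feedback: the loop removes mechanically idle cells but
  does not model how bone would actually adapt.
- Centroid stress on voxel meshes underestimates local concentrations at
  stair-stepped boundaries.  (For box-shaped trilinear elements, averaging
  the stress over the 2×2×2 Gauss points reproduces the centroid value
  exactly — the symmetric quadrature cancels the odd shape-gradient terms —
  so the centroid estimate is the canonical one here.)
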