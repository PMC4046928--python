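# Methods

## Model

The substrate is a rectangular block of isotropic linear-elastic material
(Young's modulus E in kPa, Poisson's ratio ν < 0.5, thickness t in µm),
bonded to rigid glass at the bottom and fixed at four lateral walls placed
far from the cells. Units are kPa–µm–nN throughout (1 kPa × 1 µm² = 1 nN),
so no conversion factors appear in the code. Deformations of soft
polyacrylamide gels under cell traction are small (≲1 µm over tens of µm),
so linear elasticity and the small-strain kinematics are adequate; the gel
is treated as homogeneous and isotropic.

Traction recovery is posed as a mixed boundary value problem (MBVP). On the
top surface every node-axis pair carries exactly one prescription: a
displacement (µm) or a force (nN). The mixed-boundary scheme prescribes the
measured displacements under the cells and exact zero force outside them;
the solution of the resulting sparse system yields reaction forces at the
displacement-prescribed DOFs, which are the cell tractions. Because the
extracellular boundary condition is exact, the solution is unique and no
regularization is applied (an optional Gaussian pre-smoothing of the
displacement field exists for noisy inputs but is off by default). Nodal
forces and tractions are related by tributary areas (full cell for interior
nodes, half/quarter at edges/corners), which tile the surface exactly.

### Discretization

The block is meshed with 8-node trilinear hexahedra on a structured
lattice, assembled in kPa/µm units with 2×2×2 Gauss quadrature. The
volumetric part of the strain-displacement operator is replaced by its
element average (mean-dilatation, "B-bar"). This choice is load-bearing:
the fully integrated trilinear brick locks volumetrically as ν → 0.5, and
polyacrylamide sits at ν ≈ 0.47. In a direct experiment, recovering
in-plane forces with the locking element under combined in-plane and
out-of-plane loading at ν = 0.47 gave ~40% in-plane force error; with the
mean-dilatation element the same experiment gives ~1.8% (lumped per-cell
measure, below). B-bar preserves the patch test (uniform-strain fields are
reproduced to ~1e-15) and the six rigid-body modes, and is essentially what
commercial FEM codes use by default for near-incompressible solids. ν = 0.5
exactly is rejected (a displacement formulation cannot represent full
incompressibility); values up to 0.49 are accepted.

The surface mesh size (Δx = Δy, default 4.84 µm, with 3.23/4.84/6.45 µm
used in the convergence study; a warning fires above 20% of the cell size)
is decoupled from the vertical spacing: elements default to a 2:1 vertical
aspect ratio (`z_aspect`). The through-thickness response is smooth, the
in-plane traction pattern is not; the coarser vertical spacing roughly
halves the number of unknowns. The forward–inverse round trip is an
algebraic identity at any discretization (both passes share one mesh), and
measured error ratios change only in the third decimal between z-aspect 1
and 2.

Node ordering is lexicographic (x fastest, then y, then z), DOFs (x, y, z)
per node — fixed so assembly and outputs are bit-reproducible. The reduced
(free-free) system is solved by sparse LU (SuperLU, minimum-degree ordering
on A+Aᵀ) up to 2×10⁵ free DOFs and by diagonally preconditioned conjugate
gradients above, relative tolerance 1e-8. Reactions are computed as the
residual K·u − f at Dirichlet DOFs: variationally consistent and exactly
equilibrated, unlike stress extrapolation. Every solve verifies global
equilibrium to the solver tolerance. The iterative whole-field scheme
reuses two cached factorizations (the Dirichlet pattern of each phase is
cycle-independent), so extra cycles cost only triangular solves.

### Out-of-plane handling

If the displacement field has no u_z, zero out-of-plane force (F_z = 0) is
prescribed under the cells. For ν ≥ 0.4 this is accepted silently: near
incompressibility the in-plane surface response decouples from the normal
traction (the coupling terms of the surface Green's function carry a factor
1 − 2ν). For ν < 0.4 the coupling is strong and the recovery refuses to run
on in-plane data unless explicitly overridden (`allow_low_poisson=True`,
used by the Poisson study itself).

The decoupling is exact only for a half space. On a bonded slab of finite
thickness the normal load still induces in-plane surface motion of order
(cluster size / thickness)² even at ν → 0.5, and concentrated nodal F_z
loads carry unresolved near fields at the mesh scale. Both effects are
amplified by the inverse operator into node-level force errors. The Poisson
study therefore reports two error measures per ν: the **node-by-node
relative L2 error** of the in-plane nodal forces (sensitive to those near
fields; several percent at ν = 0.47 with k = 1 loading at the default mesh)
and the **per-cluster total in-plane force error** (mean over clusters of
the relative error of Σ‖F‖ — the per-cell contractile force a TFM user
actually reports; ~1.8% under the same conditions). The lumped measure is
the one quoted as "the" in-plane force error of the F_z = 0 approximation,
matching the lumped-model character of the underlying decoupling argument.
In the swept ν range, both measures fall from ν = 0.3 to ν ≈ 0.45 (the
1 − 2ν physics) and rise again by ν = 0.49: near incompressibility the
residual discretization error grows and dominates the shrinking physical
coupling at practical mesh sizes. The study documents this; only the
physical 0.3 → 0.45 decrease and the k = 0 null case (error at solver
precision) are asserted by tests.

## Synthetic data

All validation inputs are generated, never measured, and every generator is
deterministic given its arguments (seeds are stored in fixture metadata).
The canonical geometry is two circular "cells" of 20 µm diameter separated
by a 10 µm (half-cell) edge-to-edge gap on a 1 kPa gel, 70 µm thick — cell
size and substrate of a typical fibroblast experiment. The default force
pattern (`contractile_pair`) splits each circle across the inter-cell axis
into halves that pull toward each other with ±0.5 nN peak nodal force; the
circles' centers are generally off-grid, so the larger-count half is scaled
down to keep each cluster's net in-plane force exactly zero. Alternative
patterns: `ring` (radially inward, constant magnitude) and `tapered_pair`
(amplitude ∝ (dx/R)(1 − (r/R)²), continuous at the mesh scale — used by the
convergence study, since pointwise mesh convergence is only meaningful for
a traction field without O(1) jumps). The out-of-plane loading option
follows P = kQ nodally: f_z = k × (signed in-plane force). The fixtures'
wall margin follows max(thickness, 0.75 × cluster bounding-box diagonal,
30 µm), so the fixed walls cannot clamp the solution near the cells.

Noise injection adds i.i.d. Gaussian displacement noise per node and axis.
What the generators do **not** emulate: spatially correlated DIC error,
drift and rigid-body motion between image pairs, segmentation error in the
cell mask, gel thickness variation, or viscoelasticity. Passing tests
therefore demonstrate the correctness and conditioning of the inverse
machinery, not robustness to every experimental artifact; the
region-robustness study with noise and the mask-enlargement property cover
the mildest of these.

The half-space (Cerruti) surface solution for a tangential point load,
u_∥ = F(1+ν)/(πEr) on the force axis, is the independent analytic oracle
for the deep-substrate limit. The comparison model is a quarter-symmetry
slab (antisymmetry plane x = 0: u_y = u_z = 0; mirror plane y = 0:
u_y = 0; F/4 at the shared corner node), 400 µm deep with walls 240 µm away
along the measurement axis — both ≥ 10× the largest observation radius
(6 grid spacings = 24 µm) — and stretched (coarser spacing) along y and z
where the field varies slowly. FEM agrees with the closed form to 1–7%
over r = 3–6 spacings; inside 3 spacings the discrete point load's smeared
near field makes the comparison meaningless, so it is excluded.

## Iterative whole-field scheme

The traditional alternative needs displacement data everywhere and runs:
(a) prescribe the measured (u_x, u_y) at all surface nodes with F_z = 0
(in and outside the clusters — the extracellular z-condition is not pinned
down by the scheme's description; F_z = 0 every cycle is the choice here);
(b) solve and zero all extracellular forces; (c) forward-solve a new
displacement field from the retained intracellular forces; (d) restore the
measured intracellular displacements, keep the computed extracellular
ones; repeat until the RMS of surface nodal-force magnitudes changes by
less than 5% (configurable) between cycles, with a 50-cycle budget that
raises a descriptive error carrying the residual history. On noiseless
synthetic data the first pass already satisfies the field equations, so the
loop converges in two cycles and matches the mixed scheme to solver
precision; on real data the two methods agree to a few percent RMS, which
is what the method-agreement test asserts (≤ 5% of peak nodal force).

## Studies

- **Mesh convergence**: one reference displacement field is generated at
  the finest spacing (3.23 µm) and recovered on meshes of 6.45, 4.84 and
  3.23 µm (bilinear resampling, mirroring the fact that the measured DIC
  grid is independent of the analysis mesh). The RMS in-plane traction
  difference between successive refinements, evaluated at the finest mesh's
  labeled nodes, strictly decreases; ε stays below 7% at every spacing.
  Walls at 40 µm (rather than the fixture default 70 µm) keep the finest
  mesh at ~50k DOFs; the study measures differences between meshes, which
  are insensitive to the common wall placement.
- **Poisson decoupling**: described above.
- **Region robustness**: the same displacement field recovered with the
  true mask vs an enlarged region (1-node ring or a bounding box). On
  noiseless data the two recoveries coincide to solver precision — the
  uniqueness property in its practical form: displacement data consistent
  with zero traction in the extra ring prescribe exactly that. With added
  noise the difference grows but stays a small fraction of the peak
  traction; the noisy bounding-box case is asserted below 10%.

## Numerical choices and degenerate inputs

- Solver tolerances: direct solves hit machine precision (~1e-15 relative
  residual); the CG fallback targets 1e-8. A solve whose equilibrium
  residual exceeds 100× tolerance raises rather than returning quietly.
- Ill-posed prescriptions fail loudly: no Dirichlet DOF at all (free rigid
  modes), a singular reduced system, labeled nodes with invalid
  displacement data (named in the error), masks reaching within the wall
  margin, ν = 0.5, in-plane-only data at ν < 0.4.
- ε of a cluster with identically zero forces is returned as NaN (flagged
  "undefined") rather than 0, since a zero field is perfectly balanced only
  vacuously.
- Rasterization: a node belongs to a cluster if the mask pixel containing
  the node center is labeled; mask images are y-flipped exactly once, at
  file I/O, so array row index always increases with physical y.
- CSV outputs use fixed 9-significant-digit formatting and deterministic
  row order; reruns are byte-identical, and every artifact carries the
  tool version, config hash, seed and input digests in comment metadata.
- DIC windows with correlation peak < 0.5 or a peak on the search border
  are marked invalid; the quadratic sub-pixel fit is clipped to ±0.5 px and
  degrades to 0 for flat correlation plateaus. Window/step/search defaults
  (32/16/10 px) are conventional and configurable.

## Problem sizes

Default validation runs use ~40×35×9 nodes (≈39k DOFs, two sparse LU
factorizations of a few seconds each) for the two-cell geometry, ≈50k DOFs
for the finest convergence-study mesh, and ≈80k DOFs for the deep-substrate
oracle comparison — sizes chosen so the full validation suite completes in
minutes on one core while every asserted property is comfortably inside its
tolerance.

## Known limitations

- Linear elasticity on a rectangular slab: no hyperelasticity, no
  viscoelasticity, no curved or adaptive meshes, no exact incompressibility.
- The iterative scheme is implemented for in-plane measured data (F_z = 0
  on the surface); a u_z-measuring variant would need a third phase.
- DIC is the minimal NCC + sub-pixel formulation: no iterative subset
  warping, no strain-window weighting; large rotations or strains within a
  window will degrade it.
- The Fourier/Boussinesq (FTTC) and Bayesian-regularized recoveries are
  intentionally out of scope; the half-space solution appears only as a
  validation oracle.
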