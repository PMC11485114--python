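# Methods

## The mechanical model

The package models the bench configuration in which a cylindrical block of
passive ventricular myocardium (radius 80 mm, height 40 mm) is lifted by a
prescribed bottom displacement *D* against a fixed rigid transparent plate,
after which a rigid cylindrical electrode (radius 1.165 mm, blunt tip with
a fillet of 1/8 the radius) descends through a small clearance hole in the
plate under a prescribed axial force.  Everything is axisymmetric about the
electrode axis; the analysis is static (no inertia, no viscous relaxation)
and all contacts are frictionless.  The two reported outcomes are

* **insertion depth (ID)** — the distance from the plate underside (the
  undeformed surface reference) down to the electrode tip apex, and
* **surface diameter (SD)** — twice the outermost radius at which the
  tissue surface has separated from the plate by more than a detachment
  threshold.

### Constitutive model

Tissue is a three-parameter Mooney-Rivlin hyperelastic solid,

    W = c10 (Ī1 − 3) + c01 (Ī2 − 3) + c11 (Ī1 − 3)(Ī2 − 3) + (J − 1)²/d,

with the isochoric invariants of C = FᵀF and J = det F.  The constants are
interpreted in Pa: the fitted card (c10 = 1271, c01 = 1156, c11 = 1501)
then has small-strain shear modulus 2(c10 + c01) ≈ 4.9 kPa, the expected
order for passive myocardium — any other SI reading is physiologically
absurd.  The Poisson ratio is fixed at ν = 0.49 (near incompressibility)
and enters only through the volumetric coefficient

    d = (1 − 2ν)/(c10 + c01),

the convention used by the commercial material cards this model mirrors;
`d` is always derived, never an independent input.  (The alternative
convention `d = 2/κ` with κ from the consistent small-strain bulk modulus
differs by the factor 3/(2(1+ν)) ≈ 1.007 at ν = 0.49 — immaterial.)  The
cross term c11 supplies the large-strain stiffening that a Neo-Hookean
model lacks; at the 80 g force level the tip indents ~6× its own radius,
far outside the small-strain regime.

## Discretization and solver

* **Mesh.**  Only the tissue is meshed: the electrode and plate are
  analytic rigid obstacles (their Young's modulus would exceed the
  tissue's by eleven orders of magnitude, so meshing them buys nothing but
  conditioning trouble).  The half-section is covered by a logically
  rectangular grid graded geometrically from the tip contact zone (default
  27 µm) to the far field (default 2.4 mm), with a transfinite blend that
  relaxes the fine surface/axis spacing toward a uniform grid away from
  the tip so far-field elements stay reasonably shaped (stated quality
  floor: 3° minimum angle).  Each warped quad is split into two 6-node
  triangles; the quadratic displacement field on straight-sided triangles
  is the standard locking remedy at ν = 0.49.  The default spec produces
  ~10,100 elements / ~20,400 nodes.

* **Kinematics.**  Total-Lagrangian axisymmetric deformation gradient with
  the hoop stretch 1 + u_r/R in the (3,3) slot.  The 1/R factors cancel
  against the 2πR volume weight, so axis elements need no special
  handling beyond interior quadrature (degree-4, 6-point rule).

* **Tangent.**  Element residuals are closed-form; the element tangent is
  obtained by complex-step differentiation of the residual kernel (twelve
  perturbed kernel sweeps, exact to machine precision), which keeps the
  constitutive code in one place.

* **Contact.**  Node-to-analytic-surface penalty with consistent surface
  weights (∫N 2πR dΓ).  Penalty stiffness defaults to 1e3·E/min_edge
  (E the small-strain Young's modulus), which keeps rigid-obstacle
  penetration around three orders of magnitude below the local element
  size; every reported state asserts penetration < min_edge/10.  Corner
  geometry (electrode fillet, plate hole edge) is represented by rounded
  signed-distance fields.

* **Newton solve.**  Energy-based Armijo line search on the total
  potential (elastic + penalty energy) — a residual-norm search stalls
  whenever a stiff contact switches on mid-step.  The first two iterations
  of each solve add a thin predictive contact band to the Jacobian so
  that first-touch directions are not blind to imminent contact.  When
  the tangent goes indefinite near discrete folds (a surface node
  flicking around the electrode fillet), a Levenberg ladder
  (K + λ diag-scale·I) restores descent.  Linear solves use symmetric-mode
  SuperLU.

* **Force control.**  The electrode is advanced by an outer secant /
  regula-falsi iteration on its apex height, each inner problem solved
  displacement-controlled with the advance capped (default 0.25 mm) so
  the active set grows a few nodes per solve.  Deep cold advances are
  preceded by penalty-continuation solves at k/64 and k/8.  Intermediate
  ramp targets are hit loosely (5%); each reported force level is
  converged to 1% and asserted as such.  A displacement-controlled public
  mode exists and must agree with force control on the CF↔ID map (tested
  to 1%).

* **Tolerance hierarchy.**  The Newton target is `newton_tol = 1e-8`
  (relative to the force scale).  Two irreducible floors are accepted
  when the iteration stalls: a relative one at 0.5% of the force scale
  (penalty active-set chatter; half the 1% equilibrium fidelity asserted
  on every reported state) and an absolute one of ~5 mN — the
  contact-force quantum of a single surface node at the default penalty
  and mesh scales, which one marginal node under the flat punch can
  carry indefinitely near a discrete fold.  The penalty force law is
  C1-smoothed over a band of min_edge/1000 so that the force-law kink
  itself contributes no chatter.  These floors measurably matter:
  loosening the relative floor to 1% biases insertion depths by ~0.1 mm
  on mid-size meshes.

* **Load protocol.**  Phase 1 ramps the bottom lift 0 → D (default 5
  steps, bisected on failure); phase 2 ramps the electrode force (default
  10 intermediate targets).  The pseudo-time ramps of the physical
  protocol (0.1 s / 1 s) are load-step fractions — the problem is static.
  The converged equilibrium at a given force is defined by this monotone
  loading path; like any deep frictionless-contact problem the system is
  not guaranteed to have a unique equilibrium under arbitrary load
  histories, so all comparisons use the standard ascending protocol.

## Verification

* Flat-punch oracle: at CF = 0.1 g, D = 0, minimal fillet, the computed
  depth matches the rigid-flat-punch closed form δ = F(1 − ν²)/(2aE)
  within 5% (the residual difference is finite-layer + discretization
  effects).
* Energy consistency: internal forces equal the strain-energy gradient;
  the analytic axisymmetric Piola kernel equals the general batched
  constitutive routine to round-off.
* Small-strain limits: simple-shear and dilatation probes reproduce
  μ = 2(c10 + c01) and κ = 2/d within 1%.
* Mesh convergence: the acceptance discretizations are chosen so that the
  deepest-load insertion depth changes by < 0.1 mm under a 1.5× refinement
  — the same criterion the original study used for its own mesh.
* Equilibrium: the integrated electrode reaction equals the applied weight
  within 1% at every reported level; volume-averaged |J − 1| stays below
  3% even at 80 g.

## The surface-diameter threshold

The experimental deformed-area border was identified *visually* through
the transparent plate.  The simulated plate-tissue gap decays shallowly
with radius (at 20 g the gap still exceeds 50 µm at a 7 mm radius), so the
measured SD depends strongly on what gap one treats as detached:

| detachment threshold | SD at 20 g | SD at 80 g |
|---|---|---|
| 0.05 mm (default) | ~13.9 mm | ~28.5 mm |
| 0.8 mm | ~4.7 mm | ~14.3 mm |
| experiment (mean MSD/mSD) | 5.2 mm | 13.5 mm |

A *single* visibility threshold of ≈0.8 mm reproduces the experimental
diameters at every measurable force level to sub-millimetre accuracy
(`cathmech report` emits this scan), which says the computed deformation
field is compatible with the experiment and that the visually identified
border corresponds to a sub-millimetre, not 50 µm, gap.  The package
nevertheless keeps 0.05 mm as the default: the visual criterion is not
quantifiable a priori, the threshold is exposed in the configuration, and
choosing it post hoc to match the data would make the SD comparison
circular.  Insertion depth is unaffected by this choice by construction.

## Synthetic data

The generator emulates the study's replicate structure: ten force levels
(10, 15, 20, 25, 30, 40, 50, 60, 70, 80 g), three replicates, Gaussian
noise with standard deviations taken from the reported endpoint values
(ID: 0.3 mm at 10 g to 0.1 mm at 80 g, linearly interpolated between;
likewise for the two surface diameters), negative draws truncated at
zero.  Per-level means come either from the reported summary table — with
unprinted intermediate ID means reconstructed from the reported line
ID = 0.0942·CF − 0.2522 and flagged `reconstructed` — or from the forward
model.  What passing tests on these data do *not* show: anything about
non-Gaussian replicate scatter, the elliptical (fiber-driven) anisotropy
of the real footprint (the axisymmetric model produces one diameter), or
drift between hearts; the generator is a scaffold for pipeline
correctness, not a tissue model.

## Inverse fit

Only ID enters the objective, matching the original procedure; SD is a
validation output.  The fit runs on scaled coordinates (log moduli, D
normalized by its initial value) with forward-difference gradients at a
5% probe step — chosen to dominate the solver's force-targeting noise —
and Barzilai-Borwein "short" (BB2) steps clipped to [1e-4, 1e2], the
first step moving the steepest coordinate by 5%.  Stops: two consecutive
MSE changes below 1e-3 mm², gradient norm below 1e-3, objective below
1e-3 mm², or 50 iterations; BB iterates are non-monotone, so the
best-so-far iterate is returned.  Because the small-strain response
depends on c10 and c01 only through their sum, the individual constants
are not identifiable from CF-ID data; recovery is judged on the predicted
curve and on D.

## Problem sizes used in tests and acceptance

FEM test fixtures run on reduced, convergence-checked meshes: ~500
elements for unit tests, ~800 for the shared CF sweep, ~330 for the
inverse-fit recovery oracle (five force levels), ~900 for the flat-punch
oracle.  The acceptance script sweeps the eight measurable force levels
(20-80 g) on a ~1,400 element mesh whose deepest-load insertion depth
agrees with the next refinement level within the 0.1 mm criterion.  These sizes are the
package's default trade-off between discretization error (≲0.1 mm in ID)
and turnaround; the full ~10k-element default mesh changes the reported
mean-square errors by less than the experimental replicate scatter.

## Known limitations

* Isotropic, purely elastic tissue: no fiber anisotropy (the experimental
  footprint is elliptical; the model cannot reproduce MSD ≠ mSD), no
  viscoelastic relaxation (the bench protocol read forces immediately for
  the same reason).
* Electrode perpendicular to the surface only (axisymmetry).
* Penalty contact with stall acceptance: nodal equilibrium on coarse
  meshes is guaranteed only to 0.5% of the force scale.
* The plate pre-compression D is a fitted surrogate for an unmeasured
  experimental clamping force.
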