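# Methods

`tevgsim` simulates the virtual implantation of a tissue-engineered
vascular graft (TEVG) into an idealized porcine thoracic aorta and maps
how far the graft's placement may deviate from its design — in
translation, rotation and size — before hemodynamics leave clinically
safe limits.  This note records the models, the numerical choices, and
what the synthetic conditions do and do not represent.

## Geometry

Anatomies are parametric, seeded surface meshes, not image
reconstructions.  The centerline is a candy-cane: a straight ascending
limb along +z (superior), a semicircular arch in the x–z plane, and a
straight descending limb, with 0–2 supra-aortic branch tubes rooted on
the arch.  Tubes are lofted as structured quadrilateral shells
(`n_circumferential x n_axial`) along rotation-minimizing frames
(double-reflection propagation), which avoids the frame flips Frenet
frames produce at curvature sign changes.  The patient frame is
right-handed: +x = anatomical Left, +y = Anterior, +z = Superior; all
geometry is in millimetres.

Defaults size a 20–30 kg pig: proximal lumen radius 8 mm tapering to
6 mm, arch radius 20 mm, branch radii 4/3.5 mm, wall thickness 1.5 mm.
These are plausible placeholders chosen once, not fitted measurements.
Design-time growth anticipation is a uniform +5% scale about the model
centroid.  Optional seeded low-amplitude radial noise emulates anatomic
irregularity and is off by default.

Enclosed volumes use the divergence theorem on the triangulated shell
closed by flat virtual polygon caps over each boundary loop; nothing is
added to the mesh.  Because ring polygons are inscribed in the ideal
lumen, areas and volumes carry an O(1/n^2) low bias (−0.6% at 32
circumferential nodes); tests account for this discretization, and mesh
refinement converges as expected.

## Resection and graft design

Clamp/anastomosis planes are placed perpendicular to the centerline
tangent at requested arclength stations; placement is rejected if a
plane would slice a branch ostium.  Cut-band re-meshing projects the
mesh ring nearest each plane onto that plane (node repositioning rather
than element splitting), which conserves the element count exactly and
guarantees that the two mating loops carry equal node counts — the
contract the suture pairing requires.  A branch whose takeoff lies
inside the resected interval is cut at half its length, so the remnant
keeps a native branch stump and the full scenario has the four parts
(ascending aorta, descending aorta, branch, graft).

The designed graft reuses the resected segment's rings, dilated
radially about their own centroids by the diameter scale, preserving
the design centerline.  Deviations are applied as: rotation (intrinsic
Euler angles about L-R, then A-P, then I-S, right-hand rule) about the
proximal anastomosis-loop centroid, then uniform scaling about the same
point, then translation.  The anastomosis plane co-moves with rotations
and with the L-R translation component only; A-P and I-S translations
leave it in place, since they do not change where the vessel is cut.
Scaling about the anastomosis center (rather than the graft centroid)
keeps size deviations from doubling as translations; this was a
genuinely open choice and is isolated behind `apply_deviation`.

## Implantation mechanics

Both walls are hyperelastic membranes: 4-node quadrilateral elements,
2x2 Gauss quadrature, no bending DOFs, with the incompressible Yeoh law
`W = C10 (I1-3) + C20 (I1-3)^2 + C30 (I1-3)^3` and the thickness
stretch eliminated analytically (`lam3 = 1/(lam1 lam2)`).  Native
defaults are C10 = 30, C20 = 150, C30 = 1000 kPa at 1.5 mm thickness —
order-of-magnitude placeholders for porcine aorta, fully configurable —
and the graft wall uses the same form with all coefficients multiplied
by 2.5 (a stiffer, less compliant scaffold) at 1.0 mm thickness.  The
multiplier interpretation ("2.5x less compliant" read as 2.5x
coefficient scaling rather than 2.5x tangent stiffness at a reference
strain) is a documented reading, switchable by supplying materials.

Suturing is node-to-node: mating loops are paired by the cyclic offset
(and winding orientation) minimizing the summed angle between
loop-centroid direction vectors, then each native edge node is tied to
its graft partner by the multi-point constraint
`u_native = u_graft - (X_native - X_graft)`, imposed by exact slave-DOF
elimination — not penalties — so paired nodes coincide to machine
precision once the offset is fully applied.  The offset is ramped
linearly over the load steps (default 10).

Two fixation modes exist, and the distinction matters:

* `graft_fixation="free"` keeps the coupling symmetric; native and
  graft share the gap-closing deformation.  This is the right setting
  for studying the suture mechanics itself (energy partition between
  walls, symmetry, frame indifference).
* `graft_fixation="edges"` (pipeline default) additionally holds the
  graft's sutured edge nodes at their placed positions, so the
  constraints prescribe the native edge displacements.  Without this, a
  *rigidly* misplaced free graft simply slides back to its designed
  pose at equilibrium (a rigid deviation changes no strain energy once
  the gaps close), and every translation/rotation scenario would
  degenerate to the baseline.  Holding the sutured edges encodes the
  surgical reality that the graft is sewn where it lies.

Equilibrium at each load step minimizes total strain energy by damped
Newton iteration with an analytic gradient and analytic Hessian,
Armijo-style backtracking on the energy, and adaptive Tikhonov damping
when the Hessian is indefinite.  Convergence requires the reduced
residual to fall below 1e-8 of the step's initial residual (or the
displacement increment below 1e-10 mm); divergence returns a flagged
report with diagnostics rather than raising, and element inversion
aborts with the element id.

A pure membrane has no bending stiffness, so compressed regions wrinkle
and the equilibrium is not unique at the element scale.  Two
regularizations keep the problem well-posed without changing its
large-scale mechanics:

* a constant graph-Laplacian edge-spring term (`k_e = 0.1 C10 t` per
  element edge, acting on relative nodal displacements) stands in for
  the real wall's neglected bending rigidity — for a 1.5 mm aortic wall
  `D = E t^3/12 ~ 70 kPa mm^3`, i.e. `D/h^2 ~ 5-10 kPa mm` at 3 mm mesh
  size, which is the chosen spring scale.  It is exactly zero at zero
  displacement, frame-indifferent, and excluded from reported strain
  energies;
* the lumen profiler (below) averages station areas over a 3-station
  window, because a single folded ring's polygon area under-measures
  the lumen and the r^-3/r^-4 closures amplify that error.

Residual consequence: at extreme deviations (e.g. +-20% size on the
branched case) the buckled state of the short native branch stump is
path-dependent, and max-TAWSS — which keys on the narrowest station —
inherits some of that sensitivity.  PSPD, an integral along the trunk,
is stable.  Everything remains deterministic for fixed inputs.

## Hemodynamic surrogate

The 3-D CFD stage is deliberately replaced by a 0-D surrogate; this is
the package's central fidelity decision.  The deformed lumen is profiled
into cross-section areas at the structured rings (planar polygon vector
areas at ring centroids), chained into a trunk split at branch takeoffs,
and condensed to Hagen-Poiseuille resistances `R = 8 mu L / (pi r^4)`
integrated station-by-station (trapezoidal in r^-4).  Blood is Newtonian
with density 1060 kg/m^3 and viscosity 0.00371 Pa s.  A pulsatile flow
rate drives the inlet; each outlet carries a 3-element Windkessel (Rp,
C, Rd).  Time integration is implicit Euler with the (constant) system
matrix factorized once; cycles repeat until the cycle-to-cycle maximum
nodal pressure change is below 0.1 mmHg (at most 10 cycles; the
Windkessel states start from their conductance-split steady estimates,
which removes the slow RC filling transient).  Mass is conserved at
junctions to solver precision.

Metrics: PSPD is the inlet-minus-descending-aorta pressure difference
at the instant of peak inflow (a "max over the cycle" definition is
available behind a switch), floored at zero.  Wall shear uses the
Poiseuille closure `tau = 4 mu Q / (pi r^3)`; TAWSS is its time average
over the final cycle, reported per segment (worst station) and as the
global maximum.

Default boundary conditions are placeholders scaled to a young pig:
half-sinusoid systolic ejection (a third of a 0.6 s cycle, peak
280 mL/s, mean ~60 mL/s), mean pressure 90 mmHg, 25% supra-aortic flow
share, 10% of each outlet's resistance proximal, RC decay constant
1.2 s.  With the default anatomy this puts the designed baseline at
~1 mmHg PSPD and station TAWSS of ~0.5-1.2 Pa — inside the physiologic
window, as a sound design should be.

What the surrogate preserves from a 3-D solve: the metric definitions,
the boundary-condition structure, and the monotone geometry-to-
hemodynamics relationships (narrower lumen -> higher PSPD and TAWSS)
that tolerance mapping relies on.  What it cannot represent: secondary
and recirculating flows, turbulence, curvature- and kink-induced
pressure losses beyond their area effect, and spatial WSS patterns on
the wall.  Absolute sensitivities to rotations and translations are
therefore conservative relative to a 3-D solver, and the tolerance maps
should be read as surrogate-level, not CFD-level, statements.

## Tolerance mapping and shape validation

Sweeps are one-factor-at-a-time: translations in 1-mm steps, rotations
in 5-degree steps, size in 5% steps, each axis walked outward from the
baseline so every FE solve warm-starts from its inner neighbour
(continuation with a cold-solve fallback; deterministic).  Deviation
ranges can also be derived from observations as mean +- 2 sample
standard deviations per axis.  A case is safe when PSPD < 20 mmHg and
every station TAWSS lies strictly between 0.4 and 15 Pa; the allowable
range per direction is the maximal contiguous safe interval containing
the designed pose (a safe island disconnected from baseline does not
count).  Failed solves are recorded as unevaluated, never dropped.

Shape validation asks whether simulating an observed misplacement
improves the predicted postoperative shape: distance A compares the
original design to the postoperative reference, distance B compares the
FE-deformed, deviation-transformed design to the same reference, and
the improvement is `100 (A_mean - B_mean)/A_mean`.  Surface distances
are symmetric: seeded area-weighted samples of each surface measured
point-to-triangle against the other (an exact vertex-to-vertex mode
exists for oracle checks); the Hausdorff value is the max of the two
directed maxima.  Synthetic ground truth is built by applying a known
deviation and solving on a mesh twice as dense, so the comparison is
made against an independent discretization rather than the pipeline's
own output.

Rigid registration is closed-form Kabsch/SVD for known correspondence
and iterative-closest-point refinement otherwise; deviations decompose
in an anatomical frame whose origin is the designed anastomosis center
and whose axes are the global patient axes (deviations are reported
along anatomical directions, not plane-aligned ones).  The Euler order
(L-R, then A-P, then I-S, intrinsic) is a convention; near gimbal lock
(middle angle +-90 deg) the per-axis split is convention-dependent and
the report is flagged.

## Problem sizes and determinism

The tolerance-sweep study mesh is a one-branch arch of 2,000 elements
(16 circumferential x 115 axial trunk, 10-ring branch); the quick-start
default case is a 928-element version of the same anatomy; unit
fixtures use 256-1,000 elements; shape validation runs a 640-element
case against a 2,176-element ground truth.  All randomness (anatomy noise, surface
sampling, test clouds) flows from explicit integer seeds; identical
configuration and seed reproduce outputs byte-for-byte.

## Known limitations

* No bending shells, no contact, no pressurized equilibrium, no
  anisotropic or layered walls; the stabilization term is a surrogate,
  not a bending model.
* The 0-D surrogate understates rotation/translation sensitivity (no
  kink losses) — on the default synthetic anatomy the +-5 mm / +-20 deg
  grid stays hemodynamically safe, while size deviations do reach the
  TAWSS limits.
* Max-TAWSS at extreme size deviations inherits wrinkle
  path-dependence from the membrane model (see above).
* Material constants, Windkessel parameters and the inflow waveform are
  literature-scale placeholders, not fitted to any animal.
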