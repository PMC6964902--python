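# Methods

This note documents the models, numerical choices and limitations of
the `endofuse` pipeline: what each stage assumes, why its defaults are
what they are, and what the simulated validation does and does not
demonstrate about real hardware.

## Frames and the fusion chain

All rigid transforms are elements of SE(3) carrying `target ← source`
frame labels; composition checks the labels, which turns most wiring
mistakes into immediate, descriptive errors.  `T_XO` is the pose of
frame X in the OTS/world frame O, i.e. the O←X transform.  Under this
convention the fusion identities

    T_CO = T_MO · T_CM
    T_CP = T_PO⁻¹ · (T_MO · T_CM)

type-check exactly: `T_CP` is the camera pose expressed in the
patient/CBCT frame (P←C).  A point segmented from the CBCT is mapped
into the camera by the *inverse* of `T_CP` and then projected;
`camera_from_patient()` packages that inverse because the forward pose
form, while faithful to the equations, is one inversion away from what
the renderer needs.  Nothing in the algebra depends on this reading
beyond internal consistency — if the original system defined its
transforms the other way around, every derivation here holds with all
transforms inverted.

Rotations are stored as matrices (validated orthonormal, det +1, to
1e-9) and converted to quaternions only inside averaging and solvers;
quaternions use the scalar-part-≥-0 convention.  Units are millimetres
for 3D quantities and pixels for image quantities throughout.
Products are re-orthonormalized only when drift exceeds 1e-12, so
long transform chains cannot silently decay.

## Camera model and planar calibration

The endoscope camera is a distorted pinhole: perspective division,
radial (k1, k2, optional k3) + tangential (p1, p2) polynomial on the
normalized coordinates, then the affine intrinsic map (skew supported,
default 0).  k3 is off by default: an endoscope coupled through a
35 mm lens is dominated by low-order radial distortion, and a
superfluous k3 degrades conditioning.  Undistortion inverts the
polynomial by fixed-point iteration (tolerance 1e-12 in normalized
coordinates, max 200 iterations); the iteration converges inside the
lens's invertible region, and pixels outside it raise an explicit
convergence error rather than returning garbage.

Intrinsic calibration is the classical planar pipeline: per-view
normalized-DLT homography; closed-form intrinsics from the
image-of-the-absolute-conic constraints (the constraint matrix's
second-smallest singular value is checked against 1e-8 of the largest
— an all-fronto-parallel view set is reported as degenerate rather
than silently producing nonsense); per-view extrinsics from the
homography columns; then a joint Levenberg–Marquardt refinement of
intrinsics + distortion + all view poses.  The residual is evaluated
in a vectorized raw-array path (no per-iteration object validation),
which keeps a 15-view refinement under a second.  Reported RMS is per
pixel *coordinate*, so with i.i.d. Gaussian corner noise of σ px the
expected RMS is ≈ σ·√(1 − p/N).  If refinement ever fails to improve
on the closed-form start, the start is returned — the reprojection
error is non-increasing by construction.

## Pose estimation (P3P + refinement)

The minimal solver reduces the three law-of-cosines equations in the
view-ray depths to a quartic in one depth ratio via the resultant of
two quadratics.  Quartic roots are only eps^(1/2..1/3)-accurate near
multiple roots — which occur precisely at the symmetric marker
configurations an engineer will test first — so every root is polished
by a 2×2 Newton iteration on the full (u, v) depth-ratio system before
depths are reconstructed; near-multiple roots seed both branches of
the u-quadratic.  Each candidate pose then comes from an exact
three-point rigid fit.  Candidates are returned sorted by quaternion
lexicographic order for determinism.

With ≥4 correspondences the triple of maximal triangle area (ties
broken by marker id) defines the candidates, the remaining markers
vote by reprojection error, and LM refines over all points.  RANSAC is
available but off by default: the calibration plate is a controlled
setting, and the 25 surplus markers make the plain estimator robust to
realistic noise.  Correspondence order does not affect the result.

## Hand-eye calibration

Both the endoscope-marker pose `T_MO` and the plate-derived camera
pose `T_CO` live in the same world frame, so each view gives an exact
sample `X_i = T_MO⁻¹ · T_CO` of the hand-eye transform, and the
default solver simply averages: rotation by the quaternion
outer-product eigenvector method (signs aligned to the first sample to
handle the double cover), translation by the mean.  The classical
AX = XB formulation over relative motions is implemented as an
independent cross-check: rotation from a Kabsch alignment of
angle-weighted rotation axes, translation from the stacked linear
system (R_A − I)·t_X = R_X·t_B − t_A.

AX = XB needs at least two relative motions with non-parallel rotation
axes.  The protocol in which the endoscope is fixed in a surgical arm
while the plate is moved by hand produces *constant* T_MO — every
relative motion is the identity — so on that protocol AX = XB is
structurally degenerate while the direct path is unaffected.  The
solver detects this (rank of the axis set) and by default falls back
to direct averaging with a warning; a strict mode raises instead.  The
simulator's hand-eye scenario generator therefore supports both a
`fixed_endoscope` mode (the physical protocol) and a
`moving_endoscope` mode in which both solver paths are well
conditioned and can be compared.

## Tracking, registration and motion compensation

Point-set registration is the closed-form SVD (Kabsch) fit with the
determinant guard against reflections — phantom marker sets are
near-planar, where the reflected solution is a genuine hazard.  Inputs
flatter than a 1e-9 singular-value ratio are rejected as collinear.
The fiducial registration error (FRE, RMS in mm) is reported with
every fit as a tracking-quality indicator; it is distinct from the
overlay TRE.

The virtual reference grid freezes the patient-surface marker
positions at CBCT-acquisition time.  When hybrid (optical +
radiopaque) marker coordinates in the CBCT volume are supplied, the
OTS→CBCT transform is estimated by registration; otherwise the CBCT
frame is *defined* as the OTS frame at acquisition — the rigid
integration of tracker and C-arm means that mapping is fixed and
known.  Patient motion is compensated by registering the reference
markers to their current positions; at least 3 shared visible markers
are required, and fewer is a signalled tracking-loss state (a normal
transient under occlusion), not an exception.

## The virtual rig

The simulator generates every physical object of the study: the
accuracy grid (13 spheres of exactly 2.0 mm diameter on a jittered
4×4 lattice, 5 mm pitch, ±1 mm jitter — which guarantees the 3 mm
minimum spacing — inside the central 20×20 mm of a 60×60 mm plate,
with 11 border markers; the real grid's layout is unpublished, so this
is a constraint-respecting stand-in), the 25-marker calibration plate
(5×5, 8 mm pitch), checkerboards, and a 5-marker endoscope disc.  The
simulated sensor is 2590×1942 px (the physical camera's resolution);
focal length (1300 px) and distortion (k1 = −0.20, k2 = 0.05) are
plausible wide-angle-endoscope defaults, not measured values, and
tests usually run at quarter scale (648×486).  The optical tracker is
abstracted as a 3D marker sensor with isotropic Gaussian noise
σ_marker per axis — its four-camera triangulation internals are not
public, and a noise-level sweep is the more informative model anyway.

Noise is always drawn from the seeded generator and scaled by σ, so
σ = 0 is the continuous limit of the noisy model, not a separate
branch; every entry point is bit-reproducible given its seed.

Spheres are rendered as anti-aliased filled circles (per-pixel
coverage from the signed distance to the rim); the projected radius
uses the tangent approximation f·r/z, with the exact tangent-cone
radius available by flag (the difference is ~0.1 % at the protocol's
geometry).  Each rendered frame carries its exact ground-truth
circles, consistent with the projection model to 1e-9 px.

The accuracy protocol holds the endoscope fixed and moves the grid,
perpendicular to the line of sight, through ≥100 in-plane positions
per working distance (5–30 mm), targeted at a sunflower (Fibonacci)
layout over the field of view so the union of sphere projections
covers it; an in-plane rotation of up to ±25° varies marker geometry.
A CBCT acquisition at a centred 20 mm reference pose freezes the VRG
and defines the sphere structures in the CBCT frame.

## TRE evaluation and statistics

The reported TRE is the 2D image distance between a real sphere and
its overlay, re-expressed in object-plane millimetres via
TRE[mm] = TRE[px]·Ø[mm]/Ø[px].  This is deliberately *not* the 3D
point-registration TRE of the fiducial literature: it measures what
the operator sees.  The pixel diameter comes from the **real**
(detected) sphere — the physical object anchors the millimetre scale;
using the overlay diameter instead changes results only at second
order.  The conversion makes TRE invariant to pixel scale, which the
test suite verifies by doubling the simulated sensor.

Real circles come either from the simulator's ground truth (isolating
the geometry chain from segmentation error) or from image detection:
background-normalized threshold at 0.5, connected components,
size/circularity filters, sub-pixel centre from the intensity centroid
(exact for anti-aliased discs), radius from a Kåsa circle fit to the
sub-pixel 0.5-level contour.  Non-circular or border-clipped blobs are
flagged ambiguous rather than dropped.  Real/overlay pairing is
mutual-nearest-neighbour with a 50 px gate; unpaired circles are
reported.

Statistics follow the protocol's conventions: SD with the n−1
denominator; quartiles by linear interpolation between order
statistics; one-way fixed-effects ANOVA with p from the F
distribution; Tukey–Kramer pairwise intervals using the
studentized-range distribution with the unequal-n standard error
√(MSE/2·(1/nᵢ+1/nⱼ)).  The implementation is cross-checked in the
test suite against independent library routines.  Spatial error maps
bin the mean TRE on an 8×8 grid over the image; empty bins are NaN
(never zero), and bins whose centre falls outside the circular
endoscopic field are flagged invalid.

## What the simulated validation shows — and what it does not

With zero noise and exact calibrations the full protocol (600 frames)
yields a maximum TRE below 1e-6 mm: the chain of estimators —
registration, VRG, fusion algebra, projection — is numerically exact,
so overlay error on hardware is attributable to sensors and
calibration residuals.  Mean TRE grows monotonically with tracker
noise, and an uncorrected radial distortion in the overlay path
produces the characteristic low-centre / high-periphery error map.
The physical system's published accuracy (≈0.5 mm) depends on
hardware noise characteristics — tracker triangulation error, real
lens residuals, machining tolerances — that are not public, so the
simulation makes no claim to reproduce that number; it validates the
algorithms, their degeneracy handling and their scaling behaviour.
Other idealizations worth keeping in mind: synchronized tracker and
camera timestamps, rigid patients/phantoms, exact marker
identification, and spheres rendered on a uniform background far
cleaner than endoscopic imagery.

## Problem sizes used in the shipped validation

The test suite and `scripts/acceptance.py` run the full 6×100-position
protocol at quarter sensor resolution (648×486), 15-view calibrations,
20-view hand-eye datasets, noise sweeps over σ_marker ∈ {0, 0.05,
0.1, 0.2} mm with 3–5 seeds, and 1000-replicate null simulations for
the ANOVA calibration — sizes chosen to give Monte-Carlo error well
inside the asserted tolerances while keeping a full run in the
minutes range on a single CPU.
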