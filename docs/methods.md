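# Methods

## The measurement problem

During diastole, blood entering the left ventricle (LV) through the mitral
valve rolls up into a vortex ring. Its outer boundary is a *material*
surface: the interface between freshly inflowing blood and blood that
remained in the chamber after the previous ejection. `vortexlcs` locates
this boundary in time-resolved, three-component (4D phase-contrast) velocity
fields as a ridge of the backward-time finite-time Lyapunov exponent (FTLE),
turns the ridge into closed contours, and quantifies the vortex against the
chamber: vortex volume as a fraction of LV volume (VV%), the sphere-
equivalent vortex-wall distance, effective valve/vortex diameters and their
ratio, and the vortex formation ratio (VFR).

## Units and coordinates

One unit regime everywhere: velocity cm/s, length mm, time ms (1 cm/s =
0.01 mm/ms). Voxel indices are 0-based; voxel centers sit at
`origin + index * spacing`; all contour vertices are world mm. Unit
conversion happens only at the I/O boundary.

## Preprocessing

*Background phase.* Eddy currents leave a slowly varying velocity offset.
Per timeframe and component a first-order polynomial in world coordinates is
fitted by least squares over a stationary-tissue mask (>= 10 non-coplanar
voxels) and subtracted everywhere. Coordinates are centered on the mask
centroid for conditioning. The operation is idempotent; a rank-deficient
mask raises rather than silently extrapolating.

*Velocity aliasing.* A velocity map is the scaled phase of the acquisition
(v -> pi v / VENC, aliasing = wrapping modulo 2 VENC). Each volume is
unwrapped with the reliability-sorted spatial phase unwrapper and
re-anchored so that the median wrap count is zero (most voxels are assumed
unaliased — true whenever aliasing is confined to jet cores). A temporal
pass then shifts voxels that still disagree with the mean of their
neighbouring (already unwrapped) timeframes by more than VENC, iterated to a
fixed point (cap: 50 sweeps, warning on non-convergence). Residual manual
corrections are declarative config entries (voxel, timeframe, wrap count)
applied last, so re-running the pipeline reproduces the operator's decision.
Only single wraps are expected from the generator; the spatial unwrapper
itself handles deeper wraps where the field is smooth.

*Interpolation.* "Linear upsampling in space and time" is implemented as
on-demand trilinear + linear-in-time interpolation, vectorised over
particles. Values are identical to materialised upsampling at any factor.
Outside the grid the sampler returns zero velocity and sets a sticky
out-of-domain flag (the particle freezes and everything derived from it is
marked, rather than extrapolated).

## LCS computation

Particles are seeded on rectangular planar grids, 0.8 mm apart (default),
and advected *backwards* with classic RK4 at a 5 ms step from each seeding
timeframe to the beginning of vortex ring formation; the final partial step
lands exactly on the origin time. The integration origin is detected as
E-wave onset: the first timeframe of the contiguous run before the peak in
which transmitral flow exceeds 5% of its diastolic peak (overridable).

The flow-map gradient G is taken with respect to the two in-plane seed
coordinates by central differences over neighbouring seeds (one-sided at
edges); C = G^T G is the Cauchy-Green tensor and

    FTLE = ln(sqrt(lambda_max(C))) / |T|,   in 1/s.

Seeds whose difference stencil touches an out-of-domain neighbour are
flagged and excluded from everything downstream.

Per timeframe the FTLE field is normalised to its 95th percentile
(linear-interpolation percentile over all unflagged seeds of the plane) and
seeds above 50% of that value form the ridge mask. A normalisation value
below 1e-6 1/s is treated as "no Lagrangian structure on this plane": on a
deformation-free plane the FTLE is floating-point noise (~1e-14) and a
relative threshold would otherwise select most of the plane.

## Ridge delineation

Two paths convert a ridge mask into closed contours.

*Plain masks* (no FTLE attached): the mask is skeletonised; skeleton
components containing a cycle are spur-pruned and ordered by angle about
their centroid; open components contribute their longest path as an arc.
Arcs are ordered by the angle of their centroid about the overall ridge
centroid and chained, bridging each arc end to the nearest endpoint of the
next arc with a straight segment (ties broken counterclockwise) — blindly
ending ridge segments are closed with straight lines.

*FTLE-backed masks* (the pipeline path): masked seeds are grouped into
angular sectors about the ridge centroid; per sector the ridge is located
from the band of masked seeds and the ordered sector points form the closed
contour, with empty sectors bridged straight across. The within-band
locator matters because the band is asymmetric: a *growing* vortex leaves a
deformation imprint on the inner side of the current boundary (the boundary
has been sweeping outward through the sampled voxel ramp), while a
*travelling* vortex drags a wake layer along the outer side. The default
locator is the midpoint of the FTLE crest and the outer band margin, the
least-biased single rule across both regimes (measured on the phantoms:
Hill-vortex radius +4.8%, ventricle VV% within 5 percentage points; the pure
crest gives -0.8% on Hill but up to -9.5 pp on the growing ventricle).
This sector-based tracing automates what was a manual delineation step in
clinical practice; it assumes one dominant, star-shaped ring per plane,
which holds for transmitral vortex cross-sections but would merge multiple
separate vortices.

Polygons below a 30 mm^2 floor are discarded. Contours are finally
intersected with the endocardial contours per slice/timeframe (shapely), so
ridge overgrowth across the wall cannot inflate volumes.

## Volumetrics and interaction metrics

Slice-summation volumetry: per short-axis slice the *union* of delineated
areas (never double-counting overlaps) times the slice thickness (8 mm
default), summed over slices; 113.1 ml sphere digitised at 8 mm slices is
recovered within 3%. The vortex-wall distance is the difference of
sphere-equivalent radii, (3V/4pi)^(1/3), of chamber and vortex. Mitral
annular area is measured on the through-plane velocity map at the peak-flow
timeframe as the ROI area above a speed threshold (default 10 cm/s — the
paper-style manual ROI is replaced by a threshold because automation needs
an explicit rule; the value separates a transmitral jet from typical 4D-flow
noise), in the candidate slice with the smallest flow-profile area; the
effective diameter is that of the equal-area circle. The largest LCS
diameter uses the same equal-area-circle construction per slice/timeframe.
VFR = 4V/(pi D^3) with V the E-wave inflow volume and D the inlet diameter.
Peak filling rate is the maximum central-difference derivative of the LV
volume curve.

## Statistics

Group comparisons use the two-sided Mann-Whitney-Wilcoxon test (exact null
distribution for combined n <= 20 without ties, otherwise the normal
approximation with tie and — by default — continuity correction; the
clinical group sizes 16 and 23 fall in the approximation regime).
Correlations are ordinary least squares with R^2 = squared Pearson r and p
from the t distribution on n-2 df; a constant outcome is reported as R^2 = 0,
p = 1. The canonical battery (8 covariates x 2 outcomes x 2 groups = 32
analyses) is declarative, with Bonferroni threshold alpha/n = 0.05/32 =
0.0015625. Under the null, the rank-sum type-I error is calibrated at
5% +- 1.5% over 2000 seeded replicates.

## Synthetic data

All validation inputs are generated, never downloaded.

*Analytic benchmarks.* Uniform translation, solid-body rotation
(RK4 order measurement), incompressible planar strain u = (kx, -ky, 0)
(closed-form FTLE = |k|), the standard time-periodic double gyre
(A = 0.1, eps = 0.25, omega = pi/5; unit square scaled to 100 mm, unit time
to 1 s), and Hill's spherical vortex (interior Stokes stream function
psi = (3U/4a^2) s^2 (a^2 - R^2), exterior stream + doublet; velocity
continuous and the sphere exactly material). The Hill boundary-recovery
benchmark uses a = 20 mm, U = 15 cm/s, a 1.6 mm field grid and a 600 ms
backward window, computed in the co-moving frame — FTLE is invariant under
the Galilean boost, and the steady field needs only two stored timeframes.
The window is long enough for the boundary ridge to dominate the vortex's
interior shear; much shorter windows leave interior and ridge FTLE
commensurate and no automatic threshold separates them.

*Ventricle phantom.* A kinematic left ventricle at the study's acquisition
scale: 3 mm isotropic voxels, 40 timephases over a 1000 ms cycle. The
cavity is an ellipsoid (semi-axes 28.5 x 28.5 x 44.2 mm at end-diastole)
scaled isotropically so its volume follows a biphasic raised-cosine filling
curve from 70 ml (end-systole) to 150 ml (end-diastole), E-wave 350-650 ms
carrying 70% of the filling volume, A-wave 800-950 ms the rest. A plug-flow
transmitral jet (27 mm orifice, peak ~65 cm/s) above the base carries
exactly dV/dt; trapezoidal bookkeeping of inflow vs cavity growth closes
within 2%. The vortex is a sphere growing as a(t)^3 proportional to the
filled volume fraction, reaching 53% of cavity volume at end-diastole;
interior motion is a radial growth flow r (da/dt)/a plus a rigid swirl
(4.5 rad/s), exterior fluid at rest. This choice makes the boundary
*exactly* material and the interior backward FTLE non-positive (rigid
rotation and conformal contraction carry no relative deformation), so the
ground truth the pipeline must recover — boundary radius, VV%(t), wall
distance(t), E onset, orifice diameter — is analytic and exact. It is
deliberately not a Navier-Stokes solution: the pipeline under test is purely
kinematic (it advects a given field), so dynamical realism would add
uncertainty to the truth without exercising any additional code path.

What passing the phantom does *not* show: robustness to papillary-muscle
deformation of the ring, to genuinely entraining (non-material) vortex
boundaries, to through-plane motion of the valve plane, or to the manual
judgement a clinical reader applies to ambiguous multi-ridge cases. Noise
and VENC-wrap injection are available but the headline phantom is clean.

## Numerical choices and degenerate inputs

- RK4 verified at order ~4.0 on solid-body rotation (measured >= 3.5).
- Flow-map composition over split windows agrees to < 0.1 mm on the double
  gyre at a 5 ms step.
- Percentile: numpy's linear-interpolation percentile.
- Nearest-endpoint bridging ties break counterclockwise; sector count for
  crest tracing defaults to 90 (4 deg).
- Empty masks, all-flagged planes, missing endocardial contours and
  sub-floor polygons warn and yield empty results rather than raising, so a
  cycle with frames before vortex formation processes cleanly; zero-span
  seeding frames are skipped (a flow map needs history).
- Timeframes are compared against ground truth only where the backward span
  is at least 10 ms (two RK4 steps).

## Problem sizes

Default validation sizes: double-gyre benchmark 100 x 50 seeds against a
brute-force `solve_ivp` oracle; Hill benchmark ~5.7 k seeds; ventricle
pipeline 24 timeframes x 11 slices at 0.8 mm seeding (~7 k seeds per
plane); 2000 null replicates for rank-sum calibration. These sizes keep the
full validation battery in the minutes range on a single CPU while leaving
every measured tolerance comfortably resolved.

## Known limitations

- FTLE gradients are 2-D in-plane; no volumetric 3-D ridge surfaces.
- One dominant ring per plane is assumed by the sector-based delineation.
- The flow-profile speed threshold (10 cm/s) replaces manual ROI judgement;
  very slow inflow jets would need a lower threshold.
- Slice-summation volumetry quantises along the slice normal (~2-3% for
  chamber-scale objects at 8 mm slices).
- The inward/outward ridge-band bias compensated by the "mid" locator is an
  empirical property of MRI-scale sampling; other resolutions may favour the
  crest locator.
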