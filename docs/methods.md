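# Methods

## Scope and model

`mtmesh` covers the mesoscale modeling loop for microtubule-based
artificial-muscle materials: CLSM z-stack volumes in, cylinder network
models out, and constraint-based contraction dynamics on those models.  It
does not model DNA sequence design, aster self-assembly, thermal (Langevin)
forces, stochastic kinesin stepping or force-dependent detachment, filament
flexibility, or inter-filament contact; filaments may interpenetrate.

## Dynamics engine

**State.**  Each rigid filament is two endpoint particles (half the filament
mass each) joined by an inextensible rod constraint, rather than a 6-DOF
quaternion body.  Kinesin heads and the multimer hub ("virtual node") are
single particles.  This representation makes every constraint a point
projection and every invariant exactly testable; torsion about the filament
axis is not represented, which is irrelevant here because no constraint
couples to it.

**Step.**  Per frame of length `dt`:

1. damping `v ← v·(1−d)^dt`, with `d` per body class — heads and hubs 0.4,
   filaments 0.05.  The per-second exponential convention is what makes
   those published factors meaningful at any time step;
2. ballistic prediction `x* = x + v·dt` (gravity is a config option,
   default zero: Brownian-scale objects);
3. motor targets advance: each attached head's target arc moves toward the
   minus end by `motor_speed·dt`, clamped to `[0, L]`.  Speed is interpreted
   as simulation-units per simulated second, and motors start at frame 0;
4. iterative projection of all constraints with mass-weighted,
   equal-and-opposite corrections;
5. velocity recovery `v = (x_new − x_old)/dt`.

**Constraint classes.**  Rod (endpoint distance = rest length), piston (head
to filament axis segment; the attachment that keeps a walking head on the
microtubule), hub (fixed arm length hub↔head), joint (point coincidence of
two filament ends; ball, not weld — origami linkages are flexible), motor
(axial servo of the head's arc coordinate to its target).  Piston and motor
corrections distribute their reaction onto the two filament endpoints with
barycentric weights `(1−t, t)`, which keeps every correction momentum-neutral
for arbitrary masses.

**Motor/attachment coupling.**  The motor transmits force through the
attachment: compiling a scene without piston constraints leaves the motor
targets advancing but mechanically inert, the model of a detached kinesin.
This reproduces the negative control (no contraction without the piston)
while preserving the momentum-pair property of every active constraint.

**Solver.**  Constraint classes are processed in a fixed order
(joints, rods, pistons, motors, hubs), but within a class all corrections
are computed from the same state and applied together (class-wise Jacobi).
A sequential Gauss-Seidel order would converge slightly faster but breaks
scene symmetries at the residual scale, and that bias accumulates over
hundreds of frames; the class-wise scheme commutes with any symmetry of the
scene, and the mirror-symmetric motility element stays bitwise symmetric for
all 200 frames.  The arms of one multimer share the hub particle, so the hub
class is half-stepped to prevent Jacobi overshoot.  Sweeps run at least
`solver_iterations` (default 20) times and continue (hard cap
`solver_iteration_cap`, default 400) until the structural residuals (rod,
piston, hub, joint) fall below `constraint_tolerance` (default 1e-6, with an
internal safety factor); closed rings such as the three-element aster
network need roughly 100 sweeps per frame early in the run.  All loops are
fixed-order with no unordered reductions, so repeated runs are bitwise
identical.

**Expected kinematics of the motility element.**  Both heads are hub-locked
(the arms close exactly across the lateral separation), so each motor's walk
slides its filament instead: the element contracts at twice the motor speed.
With overlap 1.0 the midpoint gap starts at ~3.015, reaches its minimum
(~the lateral separation, near frame 126 with the default damping) when the
filaments come fully abreast, and then regrows as the motors continue to
slide the filaments past one another — there is no collision or detachment
to stop them, by scope.  A head reaching the minus end clamps there and the
element stops; at speed 0.3 that happens only after the 200-frame window.
The gap is therefore strictly decreasing only up to the abreast point,
and the run ends well below its initial value.

## Scene builders

`build_motility_element(separation=0.3, overlap=1.0)` places two
antiparallel filaments (length 4.0, diameter 0.2) with minus ends on
opposite outer sides, lateral separation 0.3 and axial overlap 1.0 (an
overlap *length*, in the same units as the filament length: a fully
overlapped pair could only slide apart, so the element starts mostly
end-to-end with a 1.0-unit overlap around the origin, matching the
"starting" configuration of the published scene).  Heads sit at the
mid-overlap arc of each filament; the hub is their midpoint, which fixes the
arm length.  Neither the separation nor the overlap is published; both are
declared, overridable defaults.

`build_aster_network(n, scheme)` chains motility elements along the edges of
a regular polygon (closed) or a line (open), joining outer minus ends with
ball joints.  Each jointed filament is tilted (~2° at the defaults) so the
joined ends coincide exactly in the initial state — every constraint is
satisfied at frame 0 and the residual guarantee holds from the first
recorded frame.

Unit conversion µm↔sim multiplies lengths by a scale (default 1); entering
simulation units forces the filament diameter to the scene convention 0.2
regardless of the PSF-inflated fitted value.  Positions round-trip exactly;
the fitted radius is deliberately not recoverable after conversion.

## Synthetic volume generator

Filaments are rasterized as flat-capped solid cylinders via an exact signed
distance, with a one-voxel linear anti-aliasing rim — so the half-max
surface sits at the true geometric boundary — then blurred with an
anisotropic Gaussian PSF surrogate (defaults: lateral σ 0.1 µm, axial σ
0.25 µm).  A Gaussian is a desk-scale stand-in for the real (unpublished)
confocal PSF; it reproduces the essential artifact, apparent-diameter
inflation of 25 nm filaments to ~0.5 µm scale.  Signal is scaled so that
peak amplitude = `snr` × background noise SD, over a Poisson background
(default mean 20 counts) plus Gaussian read noise (SD 2), quantized to
16 bits; `snr=inf` renders noiselessly.  The default grid is 0.12 µm
isotropic, the working analysis pitch.  The linker channel renders Gaussian
blobs at every joint, hub, and head anchor, emulating localized dye at
origami binding regions.

Not emulated (hence not validated by passing tests): vectorial/aberrated
PSFs, depth-dependent blur, photobleaching, Brownian jitter between z
slices, and background structure in real specimens.  Recovery results on
these synthetic volumes bound what the fitting pipeline can do under its
own noise model, not under all real-microscope conditions.

Fixture scenes use radius 0.25 µm (the apparent, not physical, filament
radius), lengths 4 and 7.5 µm, and 1.0 µm between parallel filaments — wide
enough that two blurred filaments of ~0.5–0.6 µm apparent diameter remain
resolvable, as they are in the images that motivated the fitting pipeline.

## Cylinder fitting

Pipeline: Gaussian pre-smoothing (σ 0.12 µm ≈ 1 voxel; shot noise otherwise
roughens the binary surface and sprouts spurious skeleton branches) →
global threshold → despeckle (< 27 voxels) → 3D thinning → skeleton graph →
straight-run tracing → per-segment total-least-squares cylinder fits →
collinear merge → endpoint refinement → joint detection.

Numerical choices that matter:

- **Threshold policy** (default): background = intensity median (filaments
  occupy a tiny volume fraction), peak = 99.9th percentile, threshold
  halfway between.  Half-max is where a blurred cylinder's cap edge sits at
  its true axial position.  Histogram-splitting criteria such as Otsu's
  method fail here because the foreground mode carries almost no histogram
  weight.
- **Skeleton graph**: the raw 26-neighbor adjacency of a digital curve is
  full of staircase cliques; each component is reduced to its Euclidean
  minimum spanning tree, keeping true crossings as branch nodes while
  removing shortcut edges.  Spurs ≤ 0.5 µm hanging off branch points are
  pruned.
- **Thinning robustness**: the library thinning routine can erase an entire
  elongated component in unlucky grid orientations (a correct homotopic
  thinning always leaves ≥ 1 voxel).  Components are thinned per bounding
  box over a fixed sequence of axis permutations/mirrors until a plausible
  centerline survives; if none does and the component is clearly elongated
  (first singular value ≥ 3× second), the centerline is rebuilt from
  per-slice centroids along the principal axis.  Compact blobs (spheres)
  legitimately produce (near-)empty skeletons and are left that way.
- **Bend splitting**: local direction is measured over a 0.5 µm arc window
  on window-averaged coordinates (digital 26-connected lines zigzag voxel by
  voxel); paths split where the turn exceeds 20°; fragments < 1 µm are
  discarded and counted.
- **Axis/endpoints/radius**: axis = first principal direction of the
  polyline; endpoints = extreme axis projections of the polyline plus its
  nearest-assigned foreground voxels, then refined to the local half-max of
  the intensity profile sampled along the axis (±0.5 µm, with ~0.25 µm
  hysteresis against noise dips) — a global threshold erodes the caps of
  filaments dimmer than the scene's brightest, because ridge brightness is
  pose-dependent under an anisotropic PSF.  Radius = 1.5 × the mean axial
  distance of assigned foreground voxels (the exact inversion of that mean
  for a solid cylinder), clamped to ≥ 1 voxel pitch.  Fitted radii are
  apparent radii; the physical 12.5 nm microtubule radius is carried as an
  annotation constant (`TRUE_MICROTUBULE_RADIUS_UM`).
- **Merging**: fragments merge when a joint refit axis agrees with the
  *longer* fragment's axis within 10° (short fragments have noisy axes and
  must not veto), all four endpoints lie within 0.3 µm of it laterally, and
  the axial intervals abut or overlap.  Merging runs before and after
  endpoint refinement, because refined fragments of one filament can extend
  past each other.
- **Joints and polarity**: remaining end pairs < 0.3 µm apart become ball
  joints.  Polarity is unobservable in one channel; fitted filaments carry
  arbitrary minus/plus labels flagged `polarity_verified=False`.
- **Linker placement** (`place_linkers`): blobs in the second channel
  (half-max above background, gated at 4 robust σ so a blob-free channel
  yields nothing, ≥ 5 voxels) become two-headed kinesin multimers bridging
  the two nearest filaments within 0.8 µm reach, heads at the
  closest-approach arcs; blobs at detected joints are treated as origami at
  the joint, not motors.

All pipeline defaults (20° bend, 1 µm minimum length, 0.3 µm join radius,
27-voxel despeckle, 0.5 µm spur prune) are declared, config-overridable
parameters; no published values exist for them.

## Volume and surface I/O

Volumes are (z, y, x)-indexed multi-page grayscale TIFFs (8/16-bit
unsigned); physical spacing always comes from the caller and travels in a
sidecar JSON — TIFF resolution tags are a dialect minefield and are never
parsed.  Resampling is trilinear on a shared-origin grid covering the same
physical extent (exactly testable against closed forms; identity at the
identity spacing).  Richardson–Lucy deconvolution is the standard
multiplicative update, implemented directly on FFT convolutions so the
delta-kernel identity and the zero-volume case hold exactly; it is optional
preprocessing, not a reproduction of any vendor's deconvolution, whose PSF
and iteration counts are unpublished.

Isosurfaces use marching cubes (Lewiner) at a caller-chosen level, in
physical µm; collapsed zero-area facets are dropped.  A hard 0/1 voxel mask
measures ~8% high on the sphere-area oracle (staircase bias), so the
analytic oracles rasterize with a one-voxel anti-aliased rim, which is also
how PSF-blurred real data behaves near a surface; at 0.12 µm pitch the
sphere area is then reproduced to ~0.2%.  STL is written binary (normals
from winding) and read in either binary or ASCII form with exact-duplicate
vertex merging; STL carries no units, so µm-in-µm-out is recorded in the
sidecar convention.

## Problem sizes

Default test and acceptance workloads: 200-frame runs of the 7-body
motility element and 21-body aster ring; 20 fitting scenes of two filaments
each on ~3·10⁵-voxel grids; sphere oracles on ~10⁶-voxel grids.  The full
suite and the acceptance script each run in well under a minute on one CPU.

## Known limitations

- The motor is an ideal constant-speed servo: no stall force, no
  load-velocity relation, no stochastic stepping.
- Piston attachment is permanent (no binding/unbinding kinetics); the
  negative control models full detachment, nothing in between.
- Straight cylinders only; curved filaments are split at bends rather than
  fit with splines.
- Crossing filaments at shallow angles can merge into one fitted cylinder
  when the blurred volumes fuse; the recovery guarantees hold for
  non-intersecting scenes.
- Radius estimates are apparent (PSF-inflated) by design; no attempt is
  made to deconvolve true filament thickness.
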