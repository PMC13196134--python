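# Methods

This note documents the models, numerical choices and limitations behind
`graspmorph`. Units throughout: lengths in mm, angles in degrees, masses
in g; pose-space volumes in cubed degrees.

## Joint model and pose parameterisation

A joint is two watertight triangle meshes — a fixed proximal bone and a
mobile distal bone — plus a centre of rotation (COR), a joint coordinate
system (JCS) anchored at the COR, and a reference transform placing the
distal bone in the 0/0/0 pose. The COR is the centre of a least-squares
sphere fitted between the articular surfaces (algebraic fit: the linear
system `2 p·c + k = |p|²`, exact on noiseless samples, rejecting coplanar
input). The JCS x axis is perpendicular to the proximal articular surface;
the y/z assignment is clade-dependent (in primates and marsupials y runs
medio-laterally, in rodents and tree shrews dorso-ventrally), but in
either convention z = flexion-extension (FE), y = abduction-adduction
(ABAD) and x = inversion-eversion (IE), with positive angles meaning
flexion, adduction and eversion.

Poses are **intrinsic z-y-x Tait-Bryan** triples: the rotation matrix is
`Rz(z)·Ry(y)·Rx(x)`, so rotating about z carries the y and x axes with it.
Motion is a pure rotation about the fixed COR — no translational degrees
of freedom. Allowing intra-articular translation would capture real
joints more faithfully; it is deliberately out of scope here.

Reference-pose construction aligns the distal bone's proximal frame with
the JCS (axes parallel and co-directed) and then slides it along the JCS
x axis until its surface touches the interarticular gap sphere, preserving
the spacing that sphere defines. The misfit tolerance is tied to the mesh
facet scale (max of 0.1% of the distal extent and a quarter of the median
edge length): sub-facet misfits are treated as already satisfied, since
"touching" is not defined more precisely than the faceting error. The
clearance function is signed (negative once the bone swallows the sphere
centre) so the 1-D root bracket cannot step over the touching
configuration. A model whose reference pose interpenetrates is rejected.

## Collision predicates

Two predicates share one semantics ("viable = no interpenetration") at
different cost points:

* **Exact** (`classify_pose`, `sweep(engine="exact")`): triangle pairs are
  pruned with a KD-tree broad phase on triangle centroids and tested with
  a vectorised Möller–Trumbore segment-through-triangle crossing test in
  both directions; containment without surface crossing is decided by a
  ray-parity test (with automatic ray re-orientation on grazing hits);
  surfaces within 1e-9 mm count as touching, and touching counts as
  interpenetration (conservative: with a 5° grid, boundary-exact contacts
  are measure-zero and the conservative call is safer).
* **Voxel** (`sweep(engine="voxel")`, the default for full grids): each
  mesh is rasterised once into a cubic voxel grid (default resolution 96
  along the longest extent). Cells near a triangle's plane inside its
  bounding box form the boundary shell; flood fill from the grid border
  marks the exterior; the remaining **strictly interior** cells are the
  occupancy. A pose collides when any sample point of one bone (vertices
  plus face centroids, deterministically shuffled for early exit) lands in
  an interior cell of the other, tested in both directions. Collisions
  therefore register once penetration exceeds the boundary-shell thickness
  (~1 voxel); the predicate is neutral within a voxel of the surface. For
  a 10 mm joint at resolution 96 the spatial slop is ≈0.25 mm, i.e. ≈1.4°
  of arc — inside one 5° grid step. The inner loop is JIT-compiled with
  numba (pure-numpy fallback included), which makes a 75,295-pose sweep a
  ~1–3 s operation.

The voxel predicate is validated against the analytic clearance predicate
of the ball-and-socket fixture: ≥95% cell agreement required (measured
≈99.7–100%), all disagreements within one grid step of the analytic
boundary.

## Cosine correction and alpha shapes

With intrinsic z-y-x angles the invariant volume element of the rotation
group is `cos(y) dz dy dx`: equal Euler boxes at different |y| hold
unequal amounts of rotational freedom. The correction used here rescales
the first-rotation coordinate,

    zcc = z · cos(y),   ycc = y,   xcc = x,

which locally equalises that volume element. It is undefined past the
gimbal singularity (|y| > 90° raises). Two checks pin the formula down:
10,000 rotations sampled uniformly from SO(3), decomposed into z-y-x
angles and corrected, are uniform in (zcc, ycc) (chi-square, p > 0.01);
and the alpha-shape volume of a corrected analytic pose box matches
`∫∫∫ cos(y) dz dy dx` within 5% at a 5° step (measured ≈0.06%).

The **alpha shape** keeps Delaunay tetrahedra with circumradius ≤ α
(closed inequality); its volume is the sum of kept tetra volumes, never
exceeding the convex hull, which it equals for α beyond the largest
circumradius. The **critical alpha** is the smallest circumradius for
which the shape is a single face-connected region containing every input
point; both conditions are monotone in α, so a bisection over the sorted
circumradii finds it exactly. The working radius is
`max(floor, critical α)` with the dataset-level floor defaulting to 50°
(configurable per specimen). Grid-degenerate (flat) tetrahedra get
infinite circumradius and zero volume, so they never distort volumes.
Coplanar viable clouds report volume 0 with a warning rather than
raising, mirroring the exclusion workflow; clouds with fewer than four
viable poses are excluded outright (`check_inclusion`, default minimum 4
— the minimum for a 3D alpha shape).

Disarticulation — viable-coded poses whose articular surfaces no longer
face each other — is a per-specimen configuration (thresholds on positive
and/or negative z), not an automated detection: the original decision is
visual, and this package reproduces it as explicit, logged configuration.

## Moment arms

The muscle line of action is the **infinite** straight line through the
origin locator (fixed frame) and the insertion locator (carried by the
pose); the nearest point to the COR may fall outside the origin–insertion
segment. No via-points or wrapping surfaces: muscles are single straight
segments, one line per belly for multi-belly muscles. IMMA(model units)
is the perpendicular point-to-line distance from the COR;
IMMA(mm) = a/b · IMMA(model units) with a the specimen's calcaneal
tuberosity → fifth metatarso-phalangeal distance in mm and b the same
distance in model units; the unitless index divides by muscle length.
The implementation (vectorised cross-product form) is verified against an
independent 1-D scalar minimisation over the line parameter (1e-9) and on
fixtures with closed-form arms: a line through the COR (identically 0), a
parallel line at offset d (exactly d at reference), and a planar "flexor"
with IMMA(z) = r·|sin(z − z0)| whose argmax must land within one grid
step of z0 ± 90°.

## Torsion

Cylinders are fitted to the metatarsal head (axis parallel to the
sesamoids) and to the distal articular concavity by axis-seeded nonlinear
least squares over a 5-parameter chart (two axis tilts, two in-plane
offsets, radius). The seed axis is a required argument: the original
placement was interactive, and a required seed keeps results
deterministic. Frames sit at the area-weighted centroids of the articular
patches; x runs centroid-to-centroid; the cylinder axes, projected
orthogonal to x (rejected if within 5° of x), set the remaining axes per
clade convention — rodent/tree-shrew: distal z and proximal y; primate/
marsupial: distal y and proximal z. Torsion α is the unsigned rotation
about x between the frames, in [0°, 180°) (magnitudes only, as reported
in comparative work). The synthetic twisted-metatarsal generator emits
cylinder axes consistent with the chosen convention so that the
constructed frames differ by exactly the target twist; recovery across
2–86° twists and 20 seeds is required within 2° (measured ≤0.33°).

## Architecture

Storage corrections multiply raw segmented volumes: ×1.64 (short-term
ethanol), ×2.49 (long-term ethanol), ×1.32 (>1 month in ~4% formalin);
the ethanol factors are mutually exclusive, formalin composes with
either, and composition is order-independent. Muscle length is the
endpoint distance (or the sum of two segments through a mid-landmark for
curved muscles), averaged across bellies. ACSA = volume/length. The
Pearson gate tests each metric against body mass over muscles present in
more than two specimens; p < 0.05 (two-sided) triggers normalisation —
the 0.05 threshold is this package's choice, as is applying the gate per
metric. Exponents are used verbatim as 1, 0.33 and 0.66 (not 1/3, 2/3),
because reported relative values depend on that convention; report tables
round to 3 decimals.

## Synthetic data: what it does and does not emulate

* **Ball-and-socket** (oracle fixture): hemispherical cup with a conical
  opening (half-angle 5–90°) + spherical head with a cylindrical shaft,
  both surfaces of revolution, watertight by construction. Viability has
  the closed form ψ ≤ φ − asin(r_shaft/R) with cos ψ = cos z · cos y.
  Defaults: socket radius 10 mm, gap 0.5 mm (≈5% of the radius, a
  realistic interarticular spacing at this scale), shaft radius 1.5 mm,
  ~5,000 triangles per bone (reduced to 1,500 in the heavy sweep suites —
  facet sag at that resolution is ≈0.1% of the radius, far below the
  gap). Seeds randomise the azimuthal tessellation phase and add 1 µm-
  scale vertex jitter, varying the discretisation without moving the
  analytic boundary measurably.
* **Saddle-like anisotropic joint**: the same cup scaled anisotropically
  in y and z (y from the FE clearance, z from ABAD, via tangent ratios),
  giving an elliptic-cone opening with independent clearances. This
  realises the saddle joint's anisotropy property targets (FE excursion >
  ABAD excursion when its clearance is larger; pose-space volume strictly
  monotone in either clearance) without modelling congruent saddle
  curvature itself.
* **Two-pose exclusion fixture**: a rectangular bar through a matching
  rectangular tunnel in a hollow block, the bar pre-rotated 2.5° about x.
  The rectangle's IE contact window (±≈6°, from the corner geometry) is
  thereby shifted so exactly {(0,0,0), (0,0,−5°)} survive on a 5° grid;
  every swing ≥5° collides at the tunnel and large swings collide with
  the cavity walls. Mirrors specimens excluded for exhibiting only two
  viable poses.
* **Muscle fixtures** and the **specimen table** (log-uniform 6–300 g
  body masses — the span of small arboreal grasping mammals — with the
  three fluid-storage categories and clade/convention tags) are described
  above.

What passing these suites shows: the kinematic, geometric and statistical
machinery is correct on geometry with known answers. What it does not
show: agreement with any particular scanned joint — real articular
surfaces are incongruent, rough and asymmetric, real clearances vary over
the surface, and real disarticulation judgements are anatomical, not
threshold-based. Per-specimen published values (alpha volumes, IMMA maps)
depend on scan meshes available only on request and are out of scope.

## File formats

* Meshes: PLY/STL/OBJ via trimesh.
* Landmarks: CSV with columns `specimen, structure, x, y, z` (mm);
  structures used by the pipeline: `cor_sphere`, `gap_sphere` (point sets
  for sphere fits), `jcs_x`, `jcs_y`, `mt_x`, `mt_y` (two-point axes),
  `mt_origin`.
* Viability tables: CSV `z_deg, y_deg, x_deg, code, disarticulated`.
* IMMA tables: CSV `z_deg, y_deg, x_deg, zcc, ycc, xcc, imma_model,
  imma_mm, imma_norm`.
* Architecture input: CSV `specimen, muscle, raw_volume_mm3,
  ethanol_short, ethanol_long, formalin_month, body_mass_g,
  belly_points` (chains `x y z; x y z`, bellies separated by `|`).
* Specimen configs: YAML (see `graspmorph.pipeline.SpecimenConfig`);
  summaries as JSON with a provenance block (package version, seed, stage
  parameters and timings).

## Known limitations

* Rotation-only kinematics; no joint translation.
* Straight-line muscles; no wrapping, pennation or force estimation
  (ACSA, not PCSA).
* The voxel sweep is neutral within ~1 voxel of the surface; use
  `engine="exact"` where touching-level precision matters.
* The cosine-correction axis assignment is tied to the z-y-x hierarchy;
  other Euler conventions need a different correction.
* No formal cross-species statistics: sample sizes in this domain
  (n = 1–2 per species) do not support them.
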