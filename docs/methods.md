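# Methods

This note documents the models and procedures implemented in `synthrig`, the
conventions and defaults that matter, what the synthetic fixtures do and do
not emulate, and the design choices made where the design was genuinely open.

## Subject models and the digital population

A subject is a triangle mesh rigidly bound to a bone tree: every vertex
belongs to exactly one bone and moves with that bone's frame. This rigid
per-segment binding is an adequate model for arthropods, whose exoskeleton
segments barely deform; it deliberately excludes soft-tissue skinning.
Joints carry per-axis Euler (XYZ) angle limits in degrees and one of three
groups: `mesh_interacting` (leg joints posed against scene geometry via IK),
`mesh_independent` (head, antennae — randomized uniformly within limits), or
`fixed`. Forward kinematics composes, per bone, the parent frame, the rest
offset, and the joint rotation; uniform scale is applied about the root.

Models load from a Wavefront OBJ plus a JSON sidecar (`class_name`, `bones[]`,
`joints[]`, `keypoints[]`, `vertex_bone[]`, optional per-vertex `colors`).
Validation rejects bone cycles, multiple roots, orphan or doubly-bound
vertices, and keypoints naming unknown bones, and reports the offending
element. The built-in `stick` fixture is a box-segment hexapod: one body bone
and six two-segment legs (13 bones, six IK chains), with head/thorax/abdomen
and six foot keypoints.

A population multiplies one or more models into instances. Class counts follow
the configured fractions with largest-remainder rounding (so fractions
20/60/20 over 100 individuals give exactly 20/60/20). Per instance:

- **scale** ~ Uniform[1 − v, 1 + v], clipped below at 0.05. The fraction v is
  the "scale variation"; uniform is the least-informative reading of a
  percentage variation.
- **appearance**: hue shift (default ±15°) and saturation multiplier (default
  0.8–1.2) applied in HSV space; brightness as an additive offset (default
  ±0.1); contrast as `(x − 0.5)·c + 0.5` (default 0.8–1.2). These are the
  standard image-processing operators; ranges are configurable.
- **ID color**: instance k ↦ RGB `(k mod 256, ⌊k/256⌋ mod 256, ⌊k/65536⌋)`,
  a bijection for k up to 2²⁴−1 that never produces the reserved background
  color (0,0,0).

## Scene generation and the randomization hierarchy

Terrain is a square heightfield displaced by the red channel of a procedural
RGB control map: `height = (red − 0.5) · 2 · amplitude`, so 0.5 is mean ground
level and the mapping is linear and odd around it. The map is multi-octave
value noise (random lattice values, smoothstep-bilinear interpolation; base
frequency = granularity, octave count = pattern complexity, amplitudes halving
per octave). The green channel drives a two-color ground-material blend; blue
is filled but unused by the default routines. Default tessellation is 256²,
configurable — the tests and acceptance run use 48–64² grids, which preserve
every code path at desk scale.

Scatterers drop untextured assets (normalized so the largest extent is 1) onto
the surface: per scatterer one asset is drawn per iteration, a count uniform
in its integer range, per-instance uniform size and yaw, position uniform in
the extent, resting height = terrain height minus the scaled mesh bottom. All
instances of a scatterer share a procedural two-color face pattern. Lights are
a directional sun (random azimuth/elevation/intensity), 0–n colored
spotlights, an ambient term, exponential distance fog toward a randomized sky
color.

Randomization runs on a four-level schedule ordered by cost — terrain, assets,
subjects, then materials/lighting/camera — each with its own update period
(defaults 20/5/1/1; the last level always updates). Regenerating a lower level
cascades upward, because higher-level placements depend on the geometry below
them. Every element draws from a generator seeded by
`(master seed, regeneration iteration, element tag)`, which makes a run a pure
function of config and seeds: datasets reproduce bitwise, previewing iteration
k equals sample k of a full run, and changing only the subject seed fills
identical environments with different subjects.

## Placement and posing

Placement is rejection sampling: propose a position above the terrain
(uniform x,y; height uniform within a band over the local surface) and a
center rotation (uniform yaw, pitch/roll within ±20° by default); reject while
the subject's collision proxies intersect terrain, assets or previously placed
subjects, or start below the surface; then translate along the subject's
down-vector (world −Z rotated by the center rotation) to first proxy contact
(stepped march + 60-step bisection, ≈1e-9 precision). A trace that exits the
world redraws and retries; the retry cap (default 100) turns a crowded scene
into an explicit error carrying the attempt count.

Collision proxies are spheres fit per bone; elongated segments are covered by
a chain of spheres along their principal axis (capsule-like), since a single
bounding sphere would hold a long body unrealistically far off the ground.
Proxy-based tests replace triangle-exact collision — the same simplification
an engine's low-poly collision mesh makes.

Per leg chain, a downward ray from a jittered point above the foot's rest
position finds the first surface hit (terrain bilinear patch, asset
oriented-box slab test, or other subjects' proxy spheres). The IK solver is
cyclic coordinate descent with per-axis clamping to joint limits: sweeps run
tip→root; each axis update uses the closed-form angle that rotates the tip
toward the target in the plane normal to the axis, and is kept only if it does
not increase the tip-target distance (so accepted updates are monotone).
Unreachable targets leave the chain maximally extended toward the target. A
leg is `grounded` when its tip lands within tolerance (default 0.02 world
units) of the target; legs without a target, or randomly selected with the
mid-air probability (default 0.15), are solved toward a uniform point within
chain reach (rejected below the local surface) with restricted sweeps
(default 1) and flagged `mid_air`. Mesh-independent joints draw uniform angles
within their limits. Every returned angle satisfies its limits by
construction.

## Rendering

Right-handed world with Z up; camera space +X right, +Y down, +Z forward;
pixels 0-based from the top-left with centers at integer + 0.5. Intrinsics
follow the physical-camera parametrization: `fx = f·W/w_sensor`,
`fy = f·H/h_sensor`, principal point at the image center; the diagonal FOV is
`2·atan(d_sensor/2f)`. The camera aims at a randomly chosen subject from a
random spherical-shell position, then the boresight is perturbed by a rotation
up to the offset bound (default 8°) so subjects are not always centered.

The rasterizer is a per-triangle z-buffer with edge-function coverage and
perspective-correct interpolation of depth, color and world position; faces
are flat-shaded with their geometric normal flipped toward the camera
(double-sided). Triangles with any vertex behind the near plane are dropped
rather than clipped — at the configured camera distances this affects no
subject geometry. Depth is camera-plane distance (not ray length), stored in
world units in memory and as 16-bit PNG with a linear near/far mapping
(recorded per sample) on disk. Normals are encoded `(n+1)/2` in both view and
world space. Shading is Lambertian: ambient + sun + spotlights (smooth cone
falloff, inverse-quadratic distance attenuation), fog as
`exp(−density · depth)` blending toward the sky color, exposure as a `2^EV`
gain. Aperture is a depth-of-field proxy (post Gaussian blur scaled by
1/f-number), off by default. Post-processing — temperature/tint channel
gains, saturation, contrast, radial vignette `1 − s·(r/r_max)²`, seeded
zero-mean Gaussian grain — touches only the render pass; an identity spec is
a bitwise no-op. Shadows, ray tracing and HDRI environments are out of scope;
this renderer preserves the *pipeline structure* (passes, annotations,
randomization), not photorealism.

## Annotations

Bounding boxes are keypoint hulls (the smallest rectangle over all projected
keypoints, occluded ones included), clipped to the image; a subject fully
outside is flagged empty. A keypoint is `visible` when some pixel in the 3×3
neighborhood of its projection carries the subject's ID color at a depth
within 1% of the keypoint's own camera depth — the neighborhood and tolerance
absorb rasterization aliasing; it is `occluded` otherwise and `out_of_frame`
off-image or behind the camera (behind-camera points store the sentinel
xy = (−1,−1)). Occupancy is the fraction of the box's pixel window carrying
the subject's ID color. Sample and batch files are JSON with full-precision
floats (exact read-write round trips); the batch file records the population
table, seed and pass dimensions. The view-projection matrix stored per sample
reprojects every stored camera-relative 3D keypoint onto its stored 2D pixel
to well below 0.5 px (measured ~1e-12).

## Exporters

YOLO writes normalized `class cx cy w h` at 6 decimals (≈1e-4 px quantization
at 128 px); COCO uses bbox `[x,y,w,h]`, keypoint triplets with v = 2/1/0 for
visible/occluded/out-of-frame, segmentation as uncompressed column-major RLE
(exact pixel counts) or marching-squares polygons simplified to ≤1 px (area
within a few percent for convex masks), and `area` = ID-pixel count. The
keypoint table is a wide CSV (x/y/likelihood per keypoint, likelihood fixed
at 1.0 — synthetic ground truth has no annotation uncertainty; occluded
points blank when exclusion is on) with a skeleton JSON. Label maps are 8-bit
PNG, binary by default (background 0, any subject 1) or per-class. The 3D
pose export carries intrinsics recovered exactly from the stored matrices.
All exporters are read-only over the dataset; the train/validation split is a
seeded shuffle (default 80/20).

## Tracker

State per track is (cx, cy, vx, vy) with a constant-velocity transition
(dt = 1 frame), process noise on velocity (default 1e-2) and measurement
noise on position (default 1.0). Tracks initialize from their first detection
with a diffuse prior (variance 1e12), so two detections pin position and
velocity to the least-squares line through them — noise-free
constant-velocity targets are predicted exactly (≤1e-9) from the third frame
on. Association minimizes total center distance (Hungarian), gated at 100 px
by default. Unmatched tracks coast on their prediction and keep emitting while
within the termination buffer (default 30 frames), which is what lets an
identity survive detector dropout; tracks with fewer than 2 absorbed
detections stay silent while lost, so single-frame clutter does not pollute
the output. Ids strictly increase and are never reused. The tracker contains
no randomness. Gate, buffer and noise scales are configuration, logged in the
track-file header.

## Synthetic fixtures and what passing tests show

The detection simulator emits each ground-truth center with probability
1 − fn_rate, Gaussian position jitter, confidences uniform in a configurable
band, plus Poisson clutter uniform in the frame; the track simulator produces
constant-velocity targets on a jittered grid sharing one velocity vector, so
pairwise separations are constant and targets spaced beyond the minimum
separation provably never cross. These fixtures validate the *bookkeeping* of
the tracker and metrics — gating, association, identity logic, the exact
error sums — under controlled conditions. They do not emulate appearance
change, acceleration, prolonged mutual occlusion, or detector failure modes
correlated with pose, so scores on them bound implementation correctness,
not expected field performance. Likewise, the generated-image tests certify
geometry (reprojection, occlusion flags, determinism), not realism.

## Numerical choices and degenerate inputs

- AP: greedy matching (descending confidence, nearest unmatched ground truth
  within 5% of image width); thresholds with no detections contribute the
  seed values P = 1, R = 0; empty ground truth is an error.
- MOTA: overlap events are per-frame (any ground-truth pair closer than
  d_max); correspondences freeze on entry and are re-evaluated on the first
  frame after exit. A permanent swap across an overlap therefore costs one
  switch per reassigned id; a transient in-overlap swap costs none. Zero
  ground-truth detections is an error, as are inferred frames outside the
  ground-truth range.
- ACR: the per-image sum is explicitly normalized by the image count (the
  average reading); single-image cases are identical under both readings.
  Pose error with no keypoint above the confidence threshold raises an
  explicit undefined-result error rather than returning 0.
- IK ties: axis updates that change the tip distance by <1e-12 are skipped;
  sweeps stop early when no axis improves.
- NMS ties break by input order (stable sort on descending confidence).

## Problem sizes

Test and acceptance runs use 48–64² terrain grids, 96–128 px images, 2–3
subject populations, 8–20 samples per dataset, 200 placement/posing trials,
and 100-instance oracle comparisons; these sizes exercise every code path of
the pipeline. All sizes are configuration, and the generator scales to larger
grids, populations and resolutions linearly in pixels × triangles.

## Known limitations

No shadows or global illumination; no triangle-exact collision; no gait or
locomotion model (poses are static contact solutions); legs are solved
independently, so inter-leg self-collision is not prevented; near-plane
dropping instead of clipping; JPG render export is optionally randomized and
then excluded from the bitwise-reproducibility guarantee; the keypoint-table
skeleton lists chain connections in keypoint order rather than reading the
armature when exporting from files alone.
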