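# Methods

## Data model and coordinate conventions

A volume is a stack of 8-bit grayscale slice images read in
lexicographic filename order; the stack index is the depth coordinate
`z` (z = 0 is the topmost slice). Internally arrays are indexed
`(z, y, x)`; all public coordinates are `(x, y, z)` tuples in continuous
voxel units. Voxel `(z, y, x)` occupies the half-open cube
`[z, z+1) × [y, y+1) × [x, x+1)`, so its centre is at index + 0.5; a
node may sit anywhere between voxel centres, which the sub-voxel COG
positions require. The voxel resolution `r` (mm/voxel, isotropic,
default 0.3 in the examples — a typical pot-scale CT reconstruction) is
carried on the volume and in every `.rinfo` file, so all physical traits
are recomputable from stored voxel coordinates. Non-8-bit slice images
are min–max rescaled to 8-bit with a logged warning rather than
rejected, since 16-bit TIFF stacks are common upstream.

An RSA is a tree of depth exactly 2: one base node (seed position),
`N` root nodes (single roots), and per root an ordered list of relay
nodes. Registration order is preserved; root ids are never reused after
deletion. The `.rinfo` JSON schema is versioned (`"version": 1`) and
minimal: base, roots (id, interpolation method, relay nodes, optional
cached polyline), free-form string annotations.

## Interpolation algorithms

**Straight** emits exactly `[base] + relays`; duplicate consecutive
nodes are collapsed with a warning.

**Spline** fits `scipy.interpolate.splprep` with smoothing 0 (pure
interpolation) and chord-length parameterization, degree
`min(3, distinct nodes − 1)`, and samples 10 vertices per inter-node
span. Span-boundary samples are snapped to the registered nodes so they
appear verbatim in the output.

**COG tracking** walks from the relay farthest from the base back to
the base through the remaining registered nodes in reverse registration
order. Each iteration computes the intensity-weighted centre of gravity
of above-threshold voxels inside a forward-looking truncated cone and
snaps the next interpolated node to it; a registered node within the
arrival radius is consumed and appended with its exact coordinate. The
output is reversed to run base → tip, so `z_1` is the base-end depth.

Tracker parameters (all CLI-settable, defaults logged at run start):

| parameter | default | meaning |
|---|---|---|
| `step` | 4 voxels | correction interval / minimum node spacing |
| `search_radius` | 8 voxels (2·step) | cone length |
| `cone_half_angle` | 45° | cone angular half-width |
| `intensity_threshold` | 1 | 8-bit value at/above which a voxel is root |
| `arrival_radius` | = step | distance at which a target counts as reached |
| `max_steps` | 10·diagonal/step | non-convergence cap |

Two design points were genuinely open and are worth recording:

* **Cone axis.** Aiming the cone purely at the current target clips the
  outer half of a winding root whenever the local tangent is far from
  the chord direction — on a two-turn helical phantom this cost ~6% of
  arc length and a 2-voxel centerline bias. Aiming it purely along the
  previous travel direction tracks noiselessly curved tubes perfectly
  but loses the target under heavy salt noise. The axis used is the
  normalized mean of the two: the travel term keeps the window on the
  local root run, the target term guarantees the tracker reaches every
  registered node. Intensity weighting uses raw 8-bit values, not
  binary occupancy, because segmented images are graded.
* **Fallback.** When the cone contains no above-threshold voxel the
  tracker advances geometrically toward the target *without* adding a
  node. Consequently tracking through an entirely empty volume
  degenerates exactly to the straight polyline — the desired behaviour
  when there is no image evidence to follow.

If an operator registers relays out of along-root order (the farthest
relay is not the last), a warning is logged and reverse registration
order is still followed, since visiting every registered node takes
precedence over the farthest-first convention.

## Traits

Growth angle uses only the two end vertices (`atan2(|Δz|, horizontal)`),
so it is invariant under rotation about the vertical axis and horizontal
translation, and a zero horizontal displacement yields π/2 rather than
an error. Length is the cumulative Euclidean inter-node distance scaled
by r/10 to cm. Before the RDI, each polyline is resampled by even
subdivision of every segment into `ceil(length)` pieces: vertices end up
≤ 1 voxel apart, original vertices are retained, and — the insertions
being collinear — the total length is exactly preserved. The RDI may be
negative if roots run above the base node; per-root means are averaged
as-is. CSVs print 6 significant digits; the per-root file carries
(root_id, method, theta_deg, length_cm), the summary
(n_roots, mean_theta_deg, total_length_cm, rdi_cm). Angles are stored in
radians and exported in degrees.

## Synthetic phantoms

The generator emulates what a root-segmentation step hands downstream:
bright tubes (default intensity 255, radius 3 voxels — a few-mm-thick
root at pot-scale resolution) over a dark background, with two noise
terms applied after rasterization from a single seed: salt voxels set
to 255 at a given fraction (speckle from voids in calcined-clay
substrate) and additive Gaussian intensity noise clipped to [0, 255].
Centerlines are straight lines, circular helices, sinusoids or cubic
Beziers; a voxel is root if its centre lies within the tube radius of
the centerline sampled at 0.25-voxel arc steps (KD-tree point-to-curve
distance). Helix and straight arc lengths are closed-form; other curves
use dense numeric integration (8001 samples). Phantoms in the tests are
64–160 voxels per side so the suite runs in seconds, and tube axes are
placed on voxel centres (half-integer coordinates) to avoid
discretization bias in voxel-count checks.

What the phantoms do *not* emulate: beam hardening, partial-volume
blur, root branching, touching or crossing roots, and spatially
correlated soil texture. Passing tests therefore demonstrate the
correctness of the geometry, tracking and trait arithmetic under
realistic noise levels, not segmentation robustness on real CT data.

## Numerical choices and degenerate inputs

* Ties for "farthest relay" resolve to the first occurrence in
  registration order.
* Coincident registered nodes are de-duplicated (straight/spline) with
  a warning; splines with < 4 distinct nodes lower their degree; two
  distinct nodes degenerate to the straight case.
* Serialization uses `json` float repr, so coordinates round-trip
  bit-exactly (tests assert ≤ 1e-9).
* An empty tree exports a summary row with `n_roots=0` and empty trait
  fields; trait aggregates over zero roots raise `"no roots"`.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 200 random polylines for
the formula cross-checks; a (144, 64, 64) two-turn helix phantom
(closed-form arc 156.5 voxels) for length recovery; a (64, 48, 48)
straight tube for centerline accuracy; 20 seeded sine-tube phantoms with
3–10% salt noise for the tracking-vs-chord comparison; and a
(96, 56, 56) three-root phantom (one straight radicle, two sinusoidal
crown roots, 3% salt) for the end-to-end RSA traits.

## Known limitations

* Single-curve roots only: no lateral-root hierarchy (tree depth is
  fixed at 2), no automatic node detection, no branch-point inference.
* COG tracking assumes the root is the dominant bright structure inside
  the cone; a brighter parallel root within the search radius can
  capture the tracker — registering more relay nodes is the remedy, as
  it is for human operators.
* Isotropic voxels are assumed throughout.
* The `.rinfo` schema is this package's own versioned format; it does
  not read other tools' annotation files.
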