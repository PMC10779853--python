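# Methods

## Problem and model

A multi-rooted tooth's pulp complex is a single connected cavity: a
coronal chamber that narrows apically into separate root canals.  The
protocol implemented here operationalises the transition as a
*plane-sweep merge analysis*: with the volume re-oriented so a
landmark-anchored cross-sectional plane is the sweep axis, the number of
2D pulp components as a function of depth is a step function whose jumps
are the furcation events.  The first jump is the depth at which the
slice "crosses the pulp floor for the first time"; each jump's location
on the pulp floor is the bifurcation/trifurcation zenith (a saddle of
the pulp–dentine interface).  The orifice of a canal is its
cross-section on the plane at the deepest split of its root-to-leaf path
in the resulting furcation tree.  This single rule reproduces the
per-morphology protocols without case analysis:

| morphology | events | orifices |
|---|---|---|
| two-rooted mandibular | 1 | M and D both at the event |
| Radix Entomolaris | 2 | M at the first; D, DL at the second |
| three-rooted maxillary | 2 | P at the trifurcation zenith; MB, DB deeper |
| apically displaced disto-palatal | 2 | MB first; DB, P at the deeper split |
| C-shaped (fused MB+DB ribbon) | 1 | one shared MB//DB orifice, P separate |
| taurodont | 2 | same rule, deeper floor — no special casing |
| single-rooted | 0 | orifice at the CEJ plane |

## Geometry stages

**CEJ extraction.** Enamel covers only the crown, so the CEJ is the
apical rim of the enamel label: voxels that are enamel touching
background (26-neighbourhood) with a background-touching dentine voxel
among their 26 neighbours.  Voxel centres sit half a voxel occlusal to
the material boundary; the extracted points are shifted apically by half
the voxel extent along the occlusal axis.

**Plane fits.** All reference planes are total-least-squares
(orthogonal-distance) fits — the landmarks ring the tooth, so no axis is
privileged and regressing z on (x, y) would bias the normal.  The
solution is the smallest singular direction of the centred points;
degenerate (collinear) inputs are rejected.  Normals are oriented
occlusally, away from the pulp centroid.  The anchor slice uses the
exact plane for 3 anchors and the TLS plane for 4; a CEJ that dips
apically on one surface is handled by paired anchors on either side of
the dip and shows up as a non-zero reported fit residual.

**Re-orientation.** Labels are categorical, so resampling is
nearest-neighbour only, onto a grid with the input spacing, padded so no
tissue is clipped (losing more than 5% of pulp voxels aborts with
advice to pad).  The pipeline re-orients by the *anchor* plane — it is
the sweep reference; the CEJ-fit plane is reported alongside, and
orifice depths are converted to millimetres below it (signed positive
apically).

## Sweep and event detection

The sweep step defaults to the axial voxel spacing (sub-voxel
refinement is out of scope; the depth of an event is the midpoint of
the two bracketing slices, halving the worst-case discretisation
error).  In-plane components use 8-connectivity and 3D checks use
26-connectivity — standard for thin anatomical structures.  Components
are linked across slices by maximal pixel overlap; a component
overlapping two predecessors is a merge, which ends the absorbed branch
but never creates an orifice (canals re-joining toward the apex are
below orifice level by definition).

Two noise guards, both configurable:

- `min_area` (default 4 voxels) drops tiny in-plane islands — pulp
  stones sitting in an orifice, segmentation specks.  Raising it can
  only remove events (tested property).
- `merge_guard` (default 0.2 mm) treats a split as real only if its
  children persist: children that re-merge within the guard window are
  voxelization flicker at the saddle; children that die out within the
  window while a sibling survives are resampling debris (rotated
  volumes shed one-to-two-slice boundary shards); a split so close to
  the sweep's apical end that persistence cannot be demonstrated ends
  the branch instead.  All suppressions are logged, never silent.

**Saddle convention.** The zenith's lateral position is not fully
determined by "maximum convexity" when the gap is degenerate — in a
near-symmetric trifurcation the palatal canal is almost equidistant
from both buccal canals, and the *shortest* gap flips sides under
one-voxel jitter.  The package therefore defines the saddle as the
weighted mean midpoint of boundary-point pairs between the two closest
children, each pair down-weighted exponentially by its excess over the
minimal gap (length scale: two in-plane voxels, both query directions
accumulated).  The phantom generator's ground truth uses the same
definition, and the detector additionally verifies the point falls on
dentine (flagged if not).  Detected saddles agree with ground truth to
well under a voxel and move with a rigid rotation of the volume to
within two voxels.

## Anatomical naming

The frame is built from the occlusal axis (sweep normal), a buccal axis
(lingual/palatal anchor centroid toward the buccal anchor centroid),
and a mesial axis as the right-handed completion whose sign is fixed by
arch and side (+1 for mandibular-right and maxillary-left), so
left/right mirror images get mirrored names.  Maxillary: the most
palatal orifice centroid is P; the remaining two, ordered mesially, are
MB and DB; a single remaining branch is the confluent MB//DB ribbon.
Mandibular: mesial order gives M and D; a second distal branch lying
lingually is DL.  Ties break by larger area.  Branch counts
incompatible with the arch fall back to generic C1..Cn with a warning.

## Phantom generator

The generator renders the study conditions; its defaults are fixed and
are not tuned per experiment.  The pulp is a superellipse-prism chamber
(exponent 2.5) joined to straight tapered circular canals starting on
the chamber floor; canals that separate deeper than the floor remain
connected through stadium-shaped bridges until their declared split
depth; the C-shaped ribbon is a crescent (a thickened two-segment
polyline bowed buccally) that never splits.  Dentine is an
equal-thickness shell of the pulp from a 3D Euclidean distance
transform (0.6 mm; +30% for fused-root phantoms so the root envelopes
merge), and enamel a second shell (0.35 mm) restricted occlusally of
the CEJ plane, optionally with a parabolic apical dip sector on the
palatal side.  The build asserts, independently of the downstream
detector, that the rendered pulp is a single 26-connected component and
that every slice's 2D component count matches the declared split plan;
geometrically inconsistent specs (tubes merging below their declared
split) are rejected naming the offending pair.

Default dimensions are plausible literature-scale values for first
permanent molars (not measurements): 6 × 6 × 8 mm grid at 0.05 mm
isotropic spacing (120 × 120 × 160 voxels), chamber half-widths
1.4–1.8 mm, first/second split depths 1.6–2.0 / 2.4–2.8 mm below the
CEJ (3.6 / 4.2 mm for the taurodont, whose floor is apically
displaced), canal radii 0.3–0.45 mm tapering to 0.18–0.28 mm at apices
4.0–4.8 mm deep.  Presets jitter depths and radii by ±10% under their
seed; builds are bit-deterministic for a fixed spec.

Ground truth carries the CEJ plane, the noise-free landmark set (16
CEJ-ring points plus the 3–4 anchors), every split event with its
saddle, each canal's true orifice depth, and exact per-region voxel
counts.  `render_landmarks` can add Gaussian placement noise (σ in mm)
to the anchors for robustness experiments.

**What the phantoms do not emulate** — grayscale reconstruction and
segmentation error, curved canals, accessory/lateral canals and apical
deltas, rough natural CEJ curvature, anisotropic scan artefacts.
Passing tests therefore demonstrate correctness of the geometry and
topology pipeline on clean labels, not robustness to segmentation
quality; on real scans the quality of the watershed segmentation and of
anchor placement dominates.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate on the full preset
catalogue at the default 0.05 mm spacing: the acceptance tests use 20
jittered seeds per preset (and the same grid again at 0.1 mm anchor
noise); the standalone script uses 10 seeds per preset per condition,
100 random point clouds for the plane-fit oracle, and three 15°-rotated
re-runs for equivariance.  These sizes give stable rates while keeping
a full re-run in the minutes range on one CPU.

## Known limitations

- Axis-aligned grids only; oblique direction matrices are rejected
  rather than silently composed.
- The sweep plane stays parallel to the anchor plane while moving
  apically (re-levelling during the manual "scroll" is not modelled).
- Anchor noise tilts the anchor plane by roughly 2–3° at σ = 0.1 mm for
  a 2–3 mm anchor ring; event *detection* is robust to this, but
  reported depths then mix a cosine error of the same order.
- A canal that genuinely enters within 0.2 mm of the pulp's apical end
  is treated as below orifice level (merge-guard persistence).
- Fusion phantoms model external root fusion only via a thicker dentine
  envelope; no formal fusion-ratio classification is attempted.
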