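# Methods

## The measurement problem

A cranial endocast over-estimates the brain it housed wherever meninges,
vasculature or perilymphatic spaces intervene, and the mismatch varies
regionally. `endodisp` treats the question as a surface-comparison problem:
given co-registered triangle meshes of brain and endocast from one
specimen, how far apart are the two surfaces, how much of the cavity does
the brain occupy, and how does that relate to cross-sectional areas of the
adjacent jaw musculature?

All coordinates are interpreted as millimetres throughout; no unit
conversion is attempted.

## Mesh input

STL stores each facet's corners independently, so reading welds duplicate
vertices on a grid of pitch 1e-8 × the bounding-box diagonal. The
tolerance is relative because specimens span four orders of magnitude in
size (a newt endocast is a few mm, a coelacanth's hundreds); it is small
enough that welding is idempotent and moves no vertex perceptibly.
Watertightness is defined combinatorially (every undirected edge shared by
exactly two faces) and degeneracy by triangle area < 1e-12 mm² or a
repeated index. Input meshes are used as-is: no smoothing, decimation or
repair beyond orientation fixing (below).

## Rigid superposition (ICP)

Brain and endocast originate from the same scan, so they are nearly
aligned already; ICP refines that alignment. Each iteration (a) takes a
seeded sample of source vertices without replacement (default 5000, all if
fewer), (b) finds each sample's exact nearest point on the *target
surface* — not the nearest vertex, which biases distances toward coarse
regions — (c) optionally discards a trimmed fraction of the worst pairs,
(d) solves the Kabsch least-squares rotation (SVD with sign correction of
the smallest singular direction, so reflections are impossible), and (e)
composes. Iteration stops when the relative change of the RMS
correspondence distance drops below 1e-6, when the RMS falls below
1e-12 × the target diagonal (floating-point noise), or at 100 iterations;
non-convergence is reported, not raised. The superposition is rigid only —
no scale — and defaults to brain → endocast with a centroid start;
`register=False` (CLI `--no-register`) keeps the identity for meshes
already in a common frame, which is also how phantom pairs are analysed.

A caveat worth knowing: on surfaces with a continuous rotational symmetry
(spheres, capsules about their axis) the rotation component is not
observable by any surface-distance criterion — closest-point
correspondences are radial, so every rotation scores alike and ICP cannot
be expected to recover a rotational offset there. On asymmetric shapes
(e.g. a three-axis ellipsoid) the same code path recovers seeded 5°
perturbations to ~1e-8.

## Surface distances

The primitive is the exact point-to-triangle distance (Ericson's region
decomposition: face, edge and vertex regions handled explicitly),
vectorized over pairs. Whole-mesh queries go through a KD-tree over
triangle centroids; oversized triangles are subdivided into a uniform
cover so the pruning radius stays tight. The pruning bound — a triangle
beyond the k-th nearest cover centroid can hide nothing closer than that
centroid distance minus the largest cover radius — is lossless, so
accelerated results are bit-identical to exhaustive search (asserted in
tests).

Conventions:

- distances are unsigned; no inside/outside signing is attempted;
- the **symmetric mean** is the arithmetic mean of the two directed mean
  distances (the pooled-sample mean is also reported for transparency);
- the **maximum absolute distance** is the symmetric Hausdorff distance,
  the larger of the two directed maxima; both directed maxima are kept so
  either directed convention is recoverable;
- default sampling is mesh vertices (distance maps color endocast
  vertices); seeded area-weighted surface sampling is available because
  vertex density is an artefact of segmentation, not anatomy.

The distance map assigns each endocast vertex its distance to the brain
surface and is exported as PLY with 8-bit vertex colors; values are
clipped to the color range and the range + colormap (default viridis, a
perceptually uniform ramp) go to a CSV sidecar so color scales are
reproducible across figures.

## Volumes, Dice and percent occupancy

Mesh volume is the signed-tetrahedron (divergence-theorem) sum, taken on a
coherently oriented copy (orientation repaired when a coherent one exists,
via directed-edge parity) and returned as an absolute value, so winding
direction cannot flip the sign. Exact for polyhedra: the unit cube gives
1.0 to machine precision.

Dice needs a common discretization, so both meshes are voxelized on the
endocast's grid: the grid covers the bounding box plus one voxel of
padding, and a voxel is occupied iff its center lies inside the surface.
Occupancy is decided by z-column ray-crossing parity, vectorized per
triangle; column coordinates carry a sub-femtometre irrational jitter so
rays never pass exactly through edges or vertices. The center-inside
convention is unbiased for volume and makes axis-aligned cases exactly
countable (a unit cube at voxel 0.1 occupies exactly 1000 voxels). The
default voxel size is the endocast bounding-box diagonal / 200 — about
0.03 mm for a newt-sized phantom — chosen to scale across specimens; it is
recorded in every report so Dice values are qualified by their
resolution. For nested solids Dice converges to 2·V_in/(V_in+V_out) as the
voxel shrinks, which the tests check at two resolutions.

Percent occupancy rounds 100 × brain/endocast volume to the nearest
integer, half away from zero — the convention consistent with every row of
the published six-specimen table (40.7 → 41, 41.65 → 42), all of which are
reproduced exactly by the tests. A brain volume exceeding its cavity is
physically impossible and warns rather than errors, since it usually
signals a segmentation or registration fault worth inspecting.

## Cross-sectional areas

ACSA is measured on labeled voxel volumes with anisotropic spacing
(z-spacing commonly about twice the in-plane spacing in downsampled
stacks, e.g. 0.015868 × 0.015868 × 0.031727 mm for a newt). A slice's area
is the labeled-voxel count times the two in-plane spacings for the chosen
axis; the section axis defaults to the stack's z (transverse) axis as an
approximation of "perpendicular to the muscle's long axis" and is
configurable. The regional mean cycles through the region's slices until
the requested number of measurements accumulates (10 over 5 slices = each
slice twice), reporting mean and sample SD. Voxel counting is
deterministic, so the SD reflects between-slice variation only — unlike
manual tracing, where repeat measurements of one slice also carry tracing
error; the repeats parameter exists for protocol parity, not statistics.
Slice areas integrate exactly: Σ_z area(z) · dz equals the labeled voxel
count times the voxel volume.

## Phantoms: what they do and do not show

Generators are deliberately schematic — the acceptance surface is
geometric correctness, not anatomical realism:

- **nested icospheres** (brain of radius r offset inside an endocast of
  radius R): volumes 4πr³/3 exactly, every directed distance R − r when
  concentric, symmetric Hausdorff R − r + |offset| when offset, Dice
  2·V_in/(V_in+V_out);
- **shrunken capsule** (long axis x): the brain is the endocast with the
  radial component about the core segment scaled by a shrink factor,
  optionally only anterior/posterior of the bounding-box x-midplane
  (the simplest reproducible regionalization), plus seeded Gaussian noise
  along the outward radial direction to mimic segmentation roughness
  without changing topology; expected gap (1 − s)·radius per region;
- **label phantoms**: block (constant area), digitized cylinder (pixel
  count → πr²), linear taper (exact ramp by construction).

All generators are deterministic given a seed. Passing on phantoms
establishes that the geometry, not the anatomy, is handled correctly; real
scans add segmentation error, non-manifold patches and regionally varying
mesh density that phantoms do not emulate. Specimen-level published values
(maximum distances of metres-scale coelacanth endocasts, muscle ACSAs)
require the original segmentations, which are not redistributed; the
phantoms exercise the identical code paths at desk scale.

## Numerical choices and edge cases

- Weld pitch 1e-8 × diagonal; degenerate-face area threshold 1e-12 mm².
- Kabsch refuses < 3 pairs or collinear sources (rotation undetermined).
- ICP defaults: 100 iterations, relative tolerance 1e-6, 5000 samples,
  no trimming, centroid start; the whole run is deterministic given the
  seed.
- Distance queries: first pass k = 16 cover candidates, k quadrupled for
  points the pruning bound fails to settle; exactness is guaranteed, the
  schedule only affects speed.
- Constant scalar fields color-map over [0, max(value, 1)] so exports are
  always defined.
- Dice on two empty grids is a contract error, not 0/0 = 0.
- Report formatting: volumes to 1 decimal, distances and Dice to 3.
- Batch exit codes: 0 success, 1 hard failure, 2 partial/degraded (a
  non-watertight mesh downgrades Dice/volumes to missing but distances
  are still reported).

## Known limitations

- No mesh repair beyond orientation fixing; holed segmentations must be
  closed upstream before volumes/Dice are meaningful.
- Point-to-point ICP only; no global initialization, so grossly
  misaligned inputs (beyond what a centroid start absorbs) need manual
  pre-alignment — and rotationally symmetric geometry leaves the rotation
  undetermined, as noted above.
- Voxel occupancy is binary; partial-volume effects at the surface shrink
  only with voxel size.
- ACSA uses the scan axis, not the muscle fiber axis; true physiological
  cross-sections would need fiber-direction estimation, which is out of
  scope.
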