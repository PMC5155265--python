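# Methods

splintforge designs orthognathic dental splints from triangle meshes of the
maxilla and mandible. The pipeline has three computational stages: a
ruled-surface construction of the initial splint blank, a
signed-distance-field Boolean that molds the blank onto the dentition, and
a swept-silhouette reconstruction that removes undercuts so the finished
splint can seat and unseat along a straight path. All geometry is in
millimetres; STL input and output are treated as millimetres.

## Initial splint from landmark lines

The input is a *landmark plan*: two ordered lists of lines (one following
the maxillary arch, one the mandibular), each line given by an anchor
point, a unit lateral (bucco-lingual) direction, and inner/outer extents.
The inner endpoints of each list are interpolated with one spline, the
outer endpoints with another, and each spline is densely resampled at
`(n_lines − 1) · samples_per_span + 1` parameter values (default
`samples_per_span = 10`).

The spline is a chord-length-parameterized Catmull–Rom (Barry–Goldman
evaluation), chosen because it interpolates the picked points exactly —
the operator's landmarks must not be smoothed away. End spans use virtual
control points from quadratic extrapolation through the first/last three
points; plain reflection would flatten the end spans noticeably (on an
arch-like circular arc sampled at eight points, reflection leaves ≈1.5 mm
of radial error at the ends versus ≈0.03 mm with quadratic ends). With two
lines the spline degenerates to a straight segment.

Four ruled sheets connect the four resampled rails pairwise around the
square-tube cross-section (occlusal top and bottom sheets, lingual and
buccal walls), each quad split along a fixed diagonal for determinism; two
planar end caps close the tube. All sheets index one shared vertex array,
so the solid is watertight by construction (verified, along with an
Euler-characteristic and self-intersection scan, on every build). A
closed solid is required because the next stage is a volumetric Boolean;
the sheet construction alone would leave an open surface.

Note one geometric subtlety covered by the tests: the ruled strip's
full-height triangles over a *twisted* (skew-rail) patch converge to the
quadrature of `(|(B−A)×A′| + |(B−A)×B′|)/2`, which exceeds the smooth
bilinear-patch area (a Schwarz-lantern-type effect). For the nearly
untwisted sheets of a dental splint the two agree to well under a percent.

## Signed-distance-field Boolean

Difference, union and intersection of watertight solids proceed in three
stages:

1. **Split.** All pairwise triangle–triangle intersection segments are
   computed (Möller interval method, KD-tree/AABB broad phase), chained
   into seam polylines, and every intersected face is retriangulated so
   the seam is embedded as mesh edges. Retriangulation projects the face
   to 2D, forms the arrangement with shapely (`polygonize`), and
   triangulates each arrangement face with an in-package ear clipper that
   supports holes (bridged by the max-x construction). Three numerical
   details matter:
   - every distinct 3D point is projected to 2D exactly once, because GEOS
     nodes linework by exact coordinate equality and a one-ulp mismatch
     leaves the seam dangling;
   - segment endpoints that land on the face boundary are extended past it
     so the crossing is combinatorially real, and the outside slivers are
     discarded by a representative-point test;
   - zero-area (collinear-chain) ear triangles are emitted, not skipped;
     dropping them would delete boundary vertices and create T-junctions.
2. **Classify.** Each split cell is kept or dropped by the signed distance
   of a probe point to the other solid: the centroid for ordinary cells
   (strictly off-seam by construction), the host arrangement polygon's
   representative point for zero-area pieces. Signs come from the
   generalized winding number (threshold 0.5), which is robust near edges
   and vertices where single-ray parity tests fail; distance magnitudes
   come from exact point–triangle tests with KD-tree candidate pruning
   (numba kernels).
3. **Extract.** Difference keeps A-cells at non-negative distance from B
   plus B-cells at non-positive distance from A with the B patch flipped;
   union keeps non-negative/non-negative; intersection
   non-positive/non-positive. Seam vertices are welded (union-find
   clustering), duplicate opposite faces cancel, and a short fixpoint loop
   of sliver removal, T-junction repair (edge splitting through near-lying
   vertices), conflict-face removal (a face with two or more unbalanced
   edges is a redundant lens left by grazing contact) and small-hole
   fan-filling restores watertightness at tolerance scale.

**Degenerate contact.** Exactly coplanar face overlap — and, more
generally, tangential contact where surfaces touch along edges or
vertices without crossing — leaves the split without intersection
segments and the classification inconsistent. Both are resolved the same
way: B is translated by a deterministic random vector of magnitude
`1e-9 ×` the joint bounding-box diagonal (seed 0) and the Boolean is
retried once. The tolerances are ordered so each regime is clean:
seam-weld and classification tolerances are `1e-12 ×` diagonal, far below
the perturbation scale, so the thin slabs the perturbation legitimately
creates survive as valid (volume ≈ 1e-9 mm³) geometry instead of being
half-crushed by welding. Self-difference (A − A) is the extreme case: it
returns near-zero volume but possibly degenerate scrap, which callers
should treat as empty.

## Swept-silhouette undercut removal

A splint molded onto big-end-up teeth cannot slide off: the cavity is
wider away from the insertion path than at its mouth. The remedy
subtracts not the teeth but their *swept silhouette* — the union of every
cross-section the teeth present while translating along the removal
direction `d`:

1. `slice_contours`: planes orthogonal to `d` at fixed spacing (default
   0.5 mm), placed at half-spacing offsets inside the extent so tangent
   cuts at the extreme faces are avoided; contour rings are nested into
   material-with-holes polygons by even-odd XOR.
2. `accumulate_sweep`: cumulative union of the slices starting from the
   far end along `d`; once a cross-section is occupied it stays occupied
   at every level below. A big-end-up frustum thereby becomes the
   constant-radius cylinder of its first contour.
3. `rasterize_stack`: boundary-inclusive point-in-polygon fill at voxel
   centers (default 0.25 mm isotropic), one-voxel zero padding, nearest
   slice per voxel layer.
4. `close_volume`: one morphological closing (dilate→erode, 6-connected);
   the paper-level choice of operator order and element was open, closing
   with the face-adjacent element is the conservative reading.
5. `marching_cubes` (scikit-image): closed isosurface at 0.5, oriented
   outward.
6. Boolean difference of the splint and the swept model.

An `extension` prolongs the swept solid opposite `d` (default: the teeth
model's own extent) so the cavity opens fully. `eliminate_interference`
additionally buffers the silhouette outward by a `clearance` (default one
voxel): the marching-cubes surface wobbles up to half a voxel about the
true silhouette, and without the margin the de-undercut splint could
still graze the teeth. `sweep_model` itself defaults to zero clearance so
the reconstruction accuracy can be measured unbiased.

Validation mirrors the canonical test: sweeping a big-end-up frustum
(8 mm base, 12 mm top, 20 mm high) along +z and comparing with the
analytic cylinder at the first-contour radius gives a mean symmetric
surface distance of ≈0.09 mm at the default 0.5/0.25 mm spacings
(`scripts/acceptance.py` recomputes this). The error floor is set by the
slicing discretization (the first contour sits half a slice below the
top, radius 11.95 mm instead of 12 mm), so convergence tests refine slice
and voxel spacing together; halving both roughly halves the error.

A memory guard rejects occupancy grids beyond 512³ voxels with an
explicit message, since the temporary model's resolution — not the input
mesh — dominates memory.

## Surface-distance metric

`mean_surface_distance` is the *symmetric* mean: the average unsigned
distance of `n_samples` (default 20 000) area-uniform samples on A to
surface B, averaged with the same from B to A, deterministic for a fixed
seed. The directionality of the published figure this mirrors is not
stated anywhere we could find; the symmetric form is the conservative
choice and is what the validation bound is checked against.

## Synthetic phantoms

Patient CT-derived meshes are replaced by two generators:

- **Cone frustum** — the canonical undercut shape, with the analytic
  standard swept model (cylinder at first-contour radius) as ground
  truth.
- **Dental arch** — per jaw, a curved ridge block along a circular arch
  (default radius 25 mm, 150° span) carrying six frustum teeth whose
  crowns (3.0 mm) are wider than their necks (2.2 mm), so every tooth is
  undercut; jaws mirrored about the occlusal plane with a 4 mm gap. The
  jaws are built by implicit voxelization plus marching cubes — like real
  CT segmentations — at 0.6 mm default resolution, and are byte-identical
  for equal parameters. The auto-generated landmark plan places one line
  pair per tooth plus two overhang pairs past the end teeth (so the end
  caps clear the last crowns), at a depth chosen off the jaws' voxel
  planes (an exactly grid-aligned occlusal sheet would touch the
  marching-cubes tooth walls tangentially instead of crossing them).

What the phantoms do *not* emulate: anatomical crown shapes, occlusal
fissures, scan noise, or segmentation artifacts. Passing tests therefore
demonstrate the geometric pipeline — watertight molding, undercut
removal, removability — not robustness to imaging defects.

## Problem sizes and defaults

The test suite runs the full pipeline on a reduced arch (4 teeth, 100°
span, 0.8 mm phantom voxels) with a coarsened sweep (1.0 mm slices,
0.5 mm voxels), which keeps the end-to-end run to about a minute while
exercising every stage; the cone validation always runs at the standard
0.5/0.25 mm spacings. Removability is verified by translating the
finished splint 0.5–5 mm along the removal direction and checking, with
the Boolean engine itself, that the intersection with the dentition has
zero volume.

## Known limitations

- No exact-arithmetic kernel: near-degenerate input (long slivers,
  grazing contacts at scales between 1e-12 and 1e-9 of the model size)
  can defeat the perturbation/repair machinery.
- Open surfaces and self-intersecting operands are rejected, not
  repaired.
- The swept (temporary) model is not decimated; at 0.25 mm voxels it can
  dominate runtime and memory of the final Boolean.
- The removal direction is user input; no insertion-axis optimization is
  attempted.
- Splint edges are left sharp (no filleting).
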