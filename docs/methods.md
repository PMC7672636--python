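# Methods

## Data model

A scene is a 3D integer label grid indexed `(z, y, x)` — z the section
index, y the apical→basal in-slice axis, x the lateral in-slice axis —
with an explicit anisotropic voxel spacing in nm and an external JSON
table mapping every positive label to `(cell_id, compartment)`. Label 0 is
background; one label per voxel (no overlaps); several labels may map to
the same cell/compartment pair (e.g. the two nuclei of a bi-nucleate
cell), and compartment masks are unions over matching labels. Orientation
is a contract, not a guess: microvilli and outer segments (OS) face −y,
Bruch's membrane (BrM) lies at +y. Spacing is always supplied by the
caller or the JSON table and never read from TIFF tags, because
acquisition-time pixel sizes stop being valid after the downsampling that
segmented exports typically undergo.

## Estimators

**Volume** is voxel count × dx·dy·dz (µm³; mitochondria reported in nm³).
Under the voxel-centre rasterisation rule this is an unbiased estimator of
solid volume with fluctuation set by the surface-to-volume ratio of the
object; for the default phantom all compartments recover within ≈1%.

**Surface area** is voxel-face counting: every face between a mask voxel
and a non-mask voxel contributes dy·dz, dx·dz or dx·dy according to its
orientation. Exact for axis-aligned surfaces, it over-estimates smooth
oblique surfaces by up to √3 in the worst orientation. It is used because
it is parameter-free and exactly reproducible; all output tables carry an
`area_method = voxel_face` provenance column so a mesh-based estimator can
be added later without ambiguity.

**Shared area, slice-wise (dilate-AND).** Per slice, object A's binary
mask is dilated once with a 3×3 all-ones (8-connected) structuring
element and intersected with object B's undilated mask; the overlap pixel
count gives `junctionLength = count · dx` and `junctionArea =
junctionLength · dz`, summed over slices. Two loop bounds are exposed:
`fidelity` reproduces the original 1-based loop (`for i = 1; i < nSlices`)
which provably skips the final slice, `corrected` processes all slices;
the mode is recorded in every output. Conventions fixed here: the
structuring element (the reference platform's default binary dilate,
count 1) is the single largest unstated parameter of the original
procedure; thresholding generalises from the original's hard-coded label
values to arbitrary ids; the original's `> 254` test after ANDing two
255-masks is an exact binary AND; the commented-out dilation of object 2
is treated as disabled. Only A is dilated, so the estimate is mildly
asymmetric on rough interfaces; cell-pair reporting dilates the
lexicographically lower cell id, and the asymmetry can be measured by
swapping arguments (it vanishes on flat interfaces).

**Shared area, voxel faces (oracle).** Counts 6-connected voxel face
pairs between the labels, weighted by face area, with per-orientation
subtotals. On a flat x-facing interface the corrected slice-wise estimate
equals the x-orientation subtotal exactly, because dilating a half-space
advances exactly one pixel column — this identity is the cross-check
between the two estimators. The slice-wise procedure acts in-plane only
and is therefore blind to z-facing (across-section) interfaces, which the
face oracle sees; cell-contact tables report both numbers, adjacency is
decided by the face oracle, and z-neighbour pairs legitimately carry
slice-wise area 0.

**Photoreceptor support.** An OS is supported by a cell iff its label
shares ≥1 voxel face (6-connectivity) with the cell's microvilli. An OS
touching two cells' microvilli is counted for both and flagged.
Microvilli–OS contact area is the voxel-face area between the cell's
microvilli mask and the union of OS labels.

**Mitochondria.** Connected components of the cell's mitochondrion
compartment define organelles; connectivity is configurable (6 | 18 | 26)
and defaults to 26 because a manual tracer merges diagonal touches. Two
blobs meeting only at a corner voxel are one organelle under 26 and two
under 6 — documented, tested behaviour. The basal fraction uses the basal
third of the cell body's global y-extent; for sheared cells this global
split differs from a per-column (surface-relative) split, so on slanted
phantoms the measured basal fraction under-states the generative basal
clustering. The mitochondrial volume fraction takes its denominator as an
explicit argument, because published fractions of this kind are ambiguous
about whether nuclei or microvilli are included; no default is imposed.

**Linear measurements** follow the serial-stack protocol: every
`slice_interval`-th slice (default 50), `measurements_per_slice` (default
10) seeded-random measurements per slice; fixed seed gives identical
sample sets. Microvillus segments are in-plane 8-connected components of
the cell's microvilli mask; fragments under 25 pixels (near-tangent rod
sections) are not measured. Length is the geodesic along the 2D skeleton
from the root (the endpoint at largest y, i.e. the apical end) to the
farthest endpoint; the raw 8-connected pixel chain over-states oblique
straight lengths by up to ~8% (staircase), so the chain is resampled into
5-pixel chords before summation, bringing the bias below ~1%. The angle
is the root→tip chord measured from the +x direction in the slice plane,
range (0°, 180°): a rod perpendicular to the apical plane reads 90°, and
an apical surface tangent of +x is assumed (the published angle exceeds
90°, implying measurement from the surface tangent; the chord mirrors a
manual two-point protractor reading and is robust at 50 nm resolution).
Cell-body height is the y-extent of the body mask per sampled x-column
times dy — organelle labels carved out of the body do not interrupt the
extent, and the vertical-shear cell shape preserves column height
exactly. The combined epithelium height is the explicit sum of mean body
height and mean microvillus length. BrM thickness is the contiguous BrM
run along y at seeded-random columns under the cell footprints, in nm;
columns without BrM are skipped and logged, never zero-filled. Thickness
is measured along y only (no surface-normal estimation) — adequate for
flat or gently curved BrM, biased high on strongly curved BrM.

All summaries are mean ± sample SD (n−1), formatted in the
`mean units ± sd SD` convention; single samples carry SD 0 plus a flag.

## The synthetic phantom

The phantom emulates the segmented outer-retina scene with every quantity
known in closed form before rasterisation.

*Scene.* A grid of `n_cells_x × n_cells_z` rhomboid cells. The rhomboid
cross-section is realised as a vertical-displacement shear: apical and
basal surfaces are planes tilted by `shear_angle` about z
(`y_apical(x) = y0 + tan(shear)·x`, continuous across the monolayer) with
vertical lateral walls. This choice (rather than leaning side walls)
keeps every column's y-extent equal to `cell_body_height` and keeps
cell–cell interfaces planar with closed-form areas (h·w for both x- and
z-neighbours). Nuclei are axis-aligned ellipsoids placed deterministically
(centred; side by side for bi-nucleate cells). Basal infold pockets are
spheres in the basal third. Mitochondria are ellipsoids with semi-axes
jittered ±30% (a heterogeneous population), placed by rejection sampling
with `mito_basal_fraction` of them in the basal third. All carved objects
keep ≥1 voxel of mutual clearance — enforced by collision-testing a
one-voxel-diagonal-inflated envelope against an occupancy grid — so
26-connected component counting recovers the seeded count exactly.
Microvilli and OS are capsules (cylinder + hemispherical caps) with axes
in the slice plane at `tilt_angle` from +x. Each OS is paired with one
microvillus at parallel axes a perpendicular distance
`r_mv + r_os − 1.5 voxels` apart: the ~1.5-voxel designed overlap (the OS
wins precedence) guarantees 6-connected face contact after rasterisation,
while lattice pitches and placement margins keep every *other* rod pair
≥2 voxels apart, so the support counts are exact by construction. Root
positions are jittered ±0.02 µm (pairs move rigidly) to decorrelate
sub-voxel phases, which is what makes summed rod volumes average to their
analytic values.

*Truth.* Volumes are analytic: prisms, ellipsoids, spheres, capsules
(π r² L + 4/3 π r³). The microvillus volume carved away by its paired OS
is computed by 1D quadrature of the circle–circle lens area along the
common axis direction — exact up to quadrature tolerance and independent
of the grid. Rasterisation uses the voxel-centre-in-solid rule with
stamping precedence BrM < cell body < pocket < nucleus < mitochondrion <
microvilli < OS. BrM is a slab of per-column thickness drawn i.i.d. from
N(`brm_mean_thickness`, `brm_thickness_sd`) truncated below at one voxel
and above at +5σ; truth records the drawn values.

*Randomness.* One seed; independent child streams (spawned in a fixed
order: BrM, then per cell pockets / mitochondria / rod jitter) keep
partial scenes reproducible when object counts change.

*Defaults.* Chosen once to reproduce the reconstructed tissue's
magnitudes at a desk-scale footprint: 2×2 cells of 18 µm width and 6.7 µm
body height, 10° shear; nucleus semi-axes (4.2, 2.5, 3.2) µm (≈141 µm³);
microvilli 5.5 µm at 143.0°; 90 OS per cell (the low end of the observed
90–216 range, which the generator treats as a direct count parameter, not
a distribution); BrM 524.4 ± 200.5 nm; 16 pockets of 0.8 µm radius; 422
mitochondria per cell with mean volume ≈2.8×10⁸ nm³, 80% basal; 50 nm
isotropic spacing. Acquisition-fidelity spacing (8×8×50 nm) would put a
single cell near 10⁹ voxels, so spacing stays a spec field for fidelity
runs while the default validates the estimators at 50 nm. Two deliberate
departures from tissue realism: microvillus radius is coarsened to
0.15 µm (real microvilli, ~50 nm across, are not resolvable as rods at
50 nm voxels), and rod packing is far sparser than the near-close-packed
interdigitation of real OS — the phantom validates estimator correctness
on resolvable geometry, not segmentation difficulty. Consequently,
passing recovery tests demonstrates that the measurement chain is
unbiased on known geometry; it does not certify performance on dense,
noisy, curved real tissue.

## Derived-quantity conventions

"Cell cytoplasm volume" includes nuclei and interior organelles
(mitochondria) and excludes microvilli and basal infold spaces — the
convention forced by the published per-cell subtraction being exact. The
nucleus-excluded volume is exact arithmetic on those volumes.
Photoreceptor density (supported count / cytoplasm volume) is reported at
two significant figures, full precision retained internally. One known
source-table inconsistency is deliberately not forced: 132 photoreceptors
over 2360 µm³ gives 0.056 at 2 s.f. where the source prints 0.059; the
package reports the computed value. Published per-cell mitochondria
statistics are likewise not mutually consistent (count × mean ≠ total for
the bi-nucleate cell), so the package only ever reports self-consistent
statistics computed from components.

## Numerical choices

* Rasterisation: voxel-centre-in-solid; unbiased, so per-object volume
  errors are zero-mean across sub-voxel phases (an axis-aligned rod
  repeats one phase on every slice and fluctuates a few percent; tilted
  or jittered rods average out).
* Capsule–capsule carve: `scipy.integrate.quad` with breakpoints at shaft
  and cap boundaries.
* BrM thickness field: truncation at one voxel guards degenerate draws;
  at the default µ/σ ≈ 2.6 the truncation shifts the mean by < 0.5%.
* Degenerate inputs: single-slice stacks are an error in fidelity mode
  (the original loop would process zero slices); empty masks give zero
  volume/area; a missing compartment yields an empty mask with a warning
  (a cell may genuinely lack basal infolds); absent labels are errors.
* Tie-breaks: the dilated object in canonical cell-pair reporting is the
  lexicographically lower cell id; the microvillus root is the skeleton
  endpoint with the largest y, ties broken by x.

## Known limitations

* Voxel-face areas over-state oblique smooth surfaces; no mesh estimator
  yet (`area_method` field reserves the extension point).
* The slice-wise shared-area procedure cannot see z-facing interfaces;
  use the voxel-face oracle for across-section adjacency.
* BrM thickness is a y-run, not a surface-normal distance.
* The basal-third split is global in y; on strongly sheared cells it
  blurs surface-relative basal clustering.
* The phantom's flat monolayer, sparse rods and coarsened microvilli mean
  recovery results bound estimator bias, not real-tissue segmentation
  accuracy.
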