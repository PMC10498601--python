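# Methods

## Pipeline overview

`voxflap` converts a CT-angiography-like scalar volume into a set of
watertight, per-material triangle meshes plus a print manifest, via six
stages: Hounsfield-window segmentation, scripted mask repair, voxel
compositing, containment classification, measured-grid overlay, and
isosurface export. Every stage is a pure function of its inputs and the
config, so a fixed config + seed reproduces byte-identical STL output.

## Segmentation

Structures are segmented by an **inclusive** HU window (`hu_lo ≤ v ≤
hu_hi`); the muscle default is 180–230 HU. The vessel window is not fixed a
priori: contrast saturation varies, so the pipeline samples a spherical
reference ROI placed in a large contrast-filled vessel (the descending
aorta in clinical data; the vessel trunk in the phantom) and takes
`mean ± half_width`. The default half-width of 100 HU maps a ~1000 HU
aortic sample onto the standard 900–1100 HU window.

Post-processing is deliberately minimal: an optional Gaussian smoothing of
the binary mask (sigma in mm, re-binarized at 0.5) and removal of connected
components (6-connectivity) below a voxel count. Full curvature-driven
level-set evolution is out of scope; the windows plus smoothing capture the
effective behavior. Interactive mask repair is replaced by **scripted brush
strokes** — capsules swept along polylines, fill or erase — recorded in the
config so every manual edit is replayable. Fill is monotone non-decreasing
and erase non-increasing on the mask support.

## Compositing grid

`GridSpec` defines isotropic voxels over the padded bounding box of the
input; voxel centers lie at `(bounds_lo − padding) + i · voxel_size`, so a
grid built at the source resolution aligns exactly with the image's voxel
centers. The 2 mm default padding leaves empty border voxels so isosurfaces
cap cleanly. The type default voxel size is 0.5 mm (a 2 mm grid band spans
four voxels; ≥1 mm vessels stay representable); the reference pipeline's
config default is 1.0 mm, the phantom's source resolution, so exported
meshes inherit the image voxel resolution.

The shape channel is a density in [0, 1], but boolean layers binarize their
input at 0.5: subtraction and addition are saturating per-voxel arithmetic
on occupancy. Material channels are fractions that always sum to ≤ 1 per
voxel and are forced to zero wherever shape is zero. `material_add` has two
modes: `add` (saturating addition, the default) and `max` (supersede,
idempotent); when a write would push the per-voxel sum past 1, competing
materials are scaled down proportionally, so a full-weight write supersedes
whatever was there. The grid overlay uses supersede semantics — repeated
application is a no-op, and the shape channel is bit-identical (verified by
SHA-256) under any sequence of material operations.

Mesh voxelization uses parity ray casting along +x: per-triangle projected
barycentric tests collect crossing positions per (y, z) column, and voxel
centers between successive crossing pairs are inside. Rays carry a fixed
deterministic sub-voxel lateral offset (~10⁻³ voxel) so they never pass
exactly through vertices or edges; non-watertight meshes are rejected up
front with an open-edge count. Anti-aliased (soft) voxelization is not
implemented — soft shape values can be supplied directly as arrays when
needed.

## Containment classification

The HU-segmented muscle cannot contain the vessel lumina (lumen HU sits in
the contrast window), so "is this vessel voxel inside the muscle?" is asked
of a reconstructed **solid** muscle: enclosed holes are filled slice-wise
(2D `binary_fill_holes`) along the slab-normal axis, the direction
perforators travel. A perforator tunnel is an enclosed disk in every slice
it crosses and fills exactly; vessel segments outside the muscle touch the
slice background and stay open. Morphological ball closing is available as
an optional extra but is *not* exact at tunnel mouths (erosion-of-dilation
cannot recover the first/last slice of a through-tunnel), which is why
slice-wise filling is the default. Intra = vessel ∧ solid-muscle, extra =
the rest; the two masks partition the vessel support by construction.

## Measured grid

Two orthogonal plane families (default normals: patient left–right and
superior–inferior), spacing 10 mm, anchored so one plane of each family
passes through the umbilicus centroid. Each plane radiates a linear halo
`strength · max(0, 1 − d/falloff)`; families combine by maximum so band
crossings never exceed the strength. The linear profile with support radius
equal to the falloff is the unique simple profile for which a 1 mm falloff
yields 2 mm-wide bands between zero crossings, independent of spacing and
strength. Planes are flat world-space planes (the printed bands are
straight rulings, not surface geodesics); `spacing > 2·falloff` is enforced
so bands never merge. Perforator points map to half-open anchor-centered
cells `floor(offset/spacing)` with offsets also reported in cm to one
decimal.

## Meshing and export

Surfaces are extracted with scikit-image marching cubes at level 0.5 — the
midpoint of the material gradient — after zero-padding the channel by one
voxel so parts touching the grid border are capped. An optional Gaussian
pre-smoothing (default sigma 0.5 voxel for standalone parts; the reference
pipeline runs with 0 so voxel-exact checks hold) softens faceting at a
small volume cost. The material split quantizes voxels by material fraction
above/below the threshold *within the binarized shape support* ("trimmed by
the shape channel"), then meshes both binary fields; with smoothing off the
shared interface coincides exactly and re-voxelizing the two meshes
partitions the support voxel-for-voxel.

`check_watertight` counts open edges, non-manifold edges and flipped-winding
pairs and computes the signed volume; `write_stl` refuses any mesh that
fails. STL carries no color, so mixtures, opacity and finish live in the
JSON manifest: clear muscle, 80 % cyan / 20 % clear grid bands, 100 %
magenta extra-muscular vessels, equal magenta/cyan intra-muscular vessels,
and a distinct opaque color for umbilicus and struts. Struts are capsules
(default radius 1.5 mm) between config-listed anchor pairs; automatic
placement is a non-goal.

## Phantom

The synthetic abdomen is rasterized from analytic templates so ground truth
is exact: a gently curved slab (100 × 100 × 10 mm) with HU ~ U(185, 225)
inside the muscle window; a 3 mm-radius trunk under the slab feeding 2 mm
perforators that pierce it, HU ~ U(950, 1050); an umbilicus cone on the
slab surface at HU ~ U(60, 80); fat background ~ N(−75, 10) HU (the
literature gives no canonical window for fat here; a clearly negative
distribution guarantees separation from both printed tissue windows);
optional additive Gaussian noise, applied last. Vessels win overlap
priority (contrast-filled lumen), the slab's surfaces are kept off the
voxel-center planes (generic position — a surface exactly tangent to a
voxel plane is a rasterization degeneracy real anatomy never exhibits), and
perforator exit points are solved by bisection of the centerline against
the slab's top surface. The default 128 × 128 × 96 volume at 1 mm keeps the
full pipeline at a few seconds on one CPU; tests use a 64 × 64 × 48 variant
with the same tissue statistics.

What passing on the phantom shows — and what it does not: the phantom's
tissues are disjoint in HU, so noise-free Dice = 1.0 demonstrates that the
machinery (windowing, resampling, classification, meshing) is exact, not
that real CTA segments trivially. Real data adds partial-volume boundaries,
contrast gradients along vessels, scar tissue and imaging artifacts; those
require the reference-ROI windowing, smoothing, component filtering and
scripted brush repairs that the config exposes. Under synthetic noise the
muscle Dice (with 1 mm smoothing and a 64-voxel component filter) degrades
monotonically: ≈0.99 at σ = 0–10 HU, ≈0.90 at σ = 20, collapsing by σ = 40,
which matches the windowing arithmetic (at σ = 20, boundary-window voxels
have order-40 % misclassification probability before smoothing).

## Numerical choices

- World units are mm everywhere; voxel-center convention
  `world = origin + index · spacing`.
- HU windows are inclusive at both ends ("between 180–230" read
  inclusively).
- Nearest-neighbour resampling uses `floor(x + 0.5)`, so exact half-way
  ties resolve upward (deterministic half-open cells; a 1 mm voxel refines
  to exactly eight 0.5 mm voxels).
- Parity ray tie-breaking by fixed sub-voxel ray offset, seeded
  deterministically; columns with odd crossing counts (only possible for
  degenerate input) drop the last crossing and log a warning.
- Materials renormalize proportionally on overflow; equality comparisons on
  channels use exact float equality — operations are constructed to be
  exact on binary inputs.
- Marching-cubes meshes are re-indexed by trimesh (duplicate vertex
  merging) and inverted if the signed volume is negative, so exports are
  consistently outward-facing.

## Known limitations

- Orientation handling is deliberately narrow: axis-aligned NIfTI affines
  and axial, axis-aligned DICOM series only. Registration, multi-phase
  fusion and MRA are out of scope.
- The slice-wise lumen fill assumes perforators travel roughly along one
  axis (the slab normal); a vessel running parallel to the slicing plane
  through the muscle would need the optional ball closing instead.
- Vessel diameters near the voxel size are inflated by binarization; the
  phantom therefore enforces radii ≥ 2× the voxel spacing.
- The grid is a flat-plane ruling, not a geodesic surface
  parameterization; on strongly curved muscle the printed cm cells are
  chord distances.
- Printing itself (slicer control, support post-processing, coatings) is
  outside the package; the manifest is the hand-off artifact.
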