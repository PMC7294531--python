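# Methods

## Problem and model

A contrast-enhanced CT angiogram shows the vessel lumen as a bright region
(several hundred HU) over soft tissue near 80 HU. A printed hollow model is
obtained by segmenting that lumen, inverting the binary mask into a bounded
solid, and surfacing the result. The scientific content is in two numbers:
the segmentation threshold and the iso-level.

**Threshold.** Voxels straddling the wall average lumen and tissue
intensities (partial volume). Model the wall as a step edge of height
`peak − background` convolved with the scanner PSF: the blurred profile
crosses the midpoint intensity `(peak + background)/2` exactly where the
step was. Thresholding at

```
T = (peak + background)/2,   background = 80 HU
```

therefore reconstructs the wall position to first order in the blur width,
independent of the (unknown) PSF scale. `peak` is the mode of the CT-value
histogram over the aneurysm; `background` is an assumed tissue constant,
not estimated per scan.

**Iso-level.** The segmented mask is binarized to {0, 255}; marching cubes
at level 128 places the printed surface halfway along every 0–255 voxel
edge, i.e. at the same midpoint convention in mask space. Any level in
(0, 255) gives the same topology; shifting the level moves the surface by
`(0.5 − level/255)` voxel (volume change ≈ area × shift), which the test
suite checks as a first-order prediction. 128 is the canonical midpoint.

## Pipeline conventions

- Grid axes are (slice z, row y, column x); spacing and origin in mm;
  physical position of voxel (i, j, k) is `origin + (i,j,k)·spacing`.
  DICOM slices are ordered by Image Position (Patient) projected on the
  slice normal; slice-gap non-uniformity beyond 1% is an error, never
  silently resampled — the printed geometry must be faithful.
- Threshold comparison is inclusive (`HU ≥ T` is lumen) and histogram-peak
  ties break toward the lowest HU bin. Both are arbitrary at the precision
  of real data; they are fixed for bit-reproducibility and documented
  rather than claimed to match any particular workstation.
- Histogram bins are 1 HU wide by default (HU are integer-like; this is the
  finest stable resolution) and centred on integer multiples of the width.
  The histogram region is a user-placed sphere or box over the aneurysm;
  no automatic aneurysm detection is attempted.
- Component selection uses 26-connectivity, which tracks thin oblique
  vessels better than 6-connectivity.
- No resampling to isotropic voxels before segmentation: interpolation in
  HU space would perturb the histogram. Meshing handles anisotropy by
  scaling vertex coordinates with the per-axis spacing.
- Hollowing default is the block complement (margin 5 mm): the literal
  "invert the binarized mask" reading, bounded to a printable brick. If the
  margin exceeds the grid, the grid is padded, never truncated. The shell
  mode dilates by a Euclidean-distance-transform threshold with the voxel
  spacing as sampling, so anisotropic voxels still give a physically
  uniform wall. Ports are axis-aligned extrusions of the local lumen
  cross-section to the outer face — the simplest geometry that mates with a
  cylindrical sheath; at least one port is required because a sealed
  channel can be neither cleaned nor connected. Exterior connectivity of
  the cavity is verified by flood fill after opening.
- The mask is padded by one background voxel before marching cubes so
  surfaces touching the grid edge close; watertightness is non-negotiable
  for printing. Smoothing is off by default (layer steps are accepted, as
  in the original fabrication practice) with optional Taubin smoothing.
- STL output is binary by default (compact, universally consumed); vertex
  units are millimetres, the de-facto slicer convention.

## Synthetic phantoms

`generate_phantom` rasterizes an analytic lumen — finite cylinders along a
polyline centerline (spheres at interior joints keep bends continuous; the
cut ends are flat), a saccular aneurysm sphere, optional small branch
cylinders — by the voxel-centre-inside rule, paints it `lumen_peak_hu` over
`background_hu`, convolves with a Gaussian of `blur_fwhm_mm` (converted to
per-axis sigma via the spacing) and adds Gaussian noise of `noise_sigma_hu`
after the blur, approximating reconstruction noise on top of the system
PSF. The pre-blur occupancy is returned as exact ground truth together with
analytic tube/sphere volumes.

Preset parameters: lumen peaks 336/406/218/306 HU are back-solved from the
four published thresholds via `peak = 2T − 80`; aneurysm diameters
25/10/15/15 mm match the four treated aneurysms; voxel spacing
(0.8, 0.586, 0.586) mm sits at the clinical acquisition geometry. Parent
vessel radii (2.5 mm splenic, 1.5 mm pancreaticoduodenal) and the 1 mm
branch radius are schematic values typical of those arteries. Presets are
noiseless and blur-free by default — an idealized uniform contrast fill
whose histogram mode is exactly the lumen peak, which is what makes the
threshold worked examples exact; recovery tests opt into blur (1 mm FWHM)
and noise (σ up to 20 HU, a realistic CTA level).

What the phantom does **not** emulate: beam hardening and streaks,
flowing-contrast inhomogeneity, neighbouring enhancing organs, torso
anatomy, and non-Gaussian reconstruction noise. Passing the recovery tests
shows the pipeline machinery is correct under the stated image model, not
that the threshold formula is optimal on arbitrary clinical data — there
the histogram region placement and the 80 HU assumption carry real
uncertainty.

## Problem sizes and numerics

The test suite and the acceptance script run phantoms of roughly
40–100 voxels per axis (10⁵–10⁶ voxels), which resolves the preset
geometries at the clinical voxel size; generation and meshing take seconds
per case. Mesh volume is the divergence-theorem signed volume; agreement
with the voxel-count × voxel-volume oracle within 5% is expected for
convex solids a few voxels in radius and degrades for thin structures.
`mesh_summary`'s inscribed diameter voxelizes the watertight mesh
(default pitch = max extent / 64) and takes twice the maximum interior
distance; it is an estimate with pitch-level resolution. Degenerate inputs
(empty masks, empty meshes, empty ROIs, inverted crop boxes, seeds on
background) raise explicit errors rather than producing empty artifacts.

## Reproducibility

A single seed in the pipeline configuration drives phantom generation (the
only randomness); no global RNG state is used. All artifacts are
deterministic functions of config + seed, so repeated runs are
byte-identical and staged execution through lossless MetaImage
intermediates equals the single-shot pipeline bit for bit — both are
asserted in the test suite. Logging goes to stderr; no network access is
ever required.

## Known limitations

- DICOM support covers axial, identity-orientation series with uniform
  gaps; oblique NIfTI affines are rejected rather than resampled.
- The block is opened by straight axis-aligned ports; angled or threaded
  sheath connectors are out of scope.
- Physical printing concerns (material, layer thickness, supports,
  slicing) are out of scope; the deliverable is the validated STL.
- Per-point vessel radius tapering is approximated segment-wise by the
  larger end radius.
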