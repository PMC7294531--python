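# vesselforge

Turn a contrast-enhanced CT angiography volume into a printable hollow
vascular model: an STL file whose internal cavity reproduces the vessel and
aneurysm lumen, so real catheters, guidewires and embolic agents can be
rehearsed on the printed block before an endovascular procedure.

It is aimed at interventional radiology and medical 3D-printing groups who
want the classic workstation workflow — lumen thresholding, mask inversion,
surface rendering — as scripted, reproducible, testable code, with a
synthetic phantom generator standing in for patient scans.

## The method

Contrast makes the lumen bright (hundreds of HU) against soft tissue near
80 HU, but voxels straddling the vessel wall mix the two intensities — the
partial-volume effect. The segmentation threshold is therefore placed midway
between the lumen histogram peak and the assumed tissue level:

    T = (peak + 80) / 2      [HU]

where *peak* is the mode of the CT-value histogram computed over the
aneurysm. A blurred lumen/tissue edge crosses this half-way intensity at
the true wall to first order, so the binary boundary lands where the vessel
actually is. The pipeline is then:

1. **Segment** — histogram the aneurysm region, take the mode, threshold at
   `T` (inclusive, `HU >= T`), keep the 26-connected component holding a
   seed point, optionally crop; emit a {0, 255} mask.
2. **Hollow** — invert the binarized lumen into a bounded solid block
   (default: lumen bounding box + 5 mm margin) whose cavity is the lumen;
   open one or more ports so the cavity reaches the exterior for sheath
   connection. A thin-shell mode (distance-transform wall of fixed physical
   thickness) is available as an alternative.
3. **Mesh** — marching cubes on the {0, 255} mask at iso-level 128 (the
   midpoint), vertices scaled by the per-axis voxel spacing into
   millimetres, watertightness and manifoldness validated, STL written.

Synthetic phantoms (tube + saccular aneurysm sphere + optional small
branches, Gaussian PSF blur, Gaussian noise) come with exact ground-truth
lumen masks, so segmentation quality is scored with Dice overlap and signed
volume error instead of requiring patient data. Four presets, `patient1` …
`patient4`, emulate the four clinical cases the workflow was built around:
lumen peaks 336/406/218/306 HU and aneurysm diameters 25/10/15/15 mm.

## Worked example

```sh
vesselforge run --preset patient1 --seed 7 --output demo
```

prints

```
peak 336 HU, threshold 208 HU, model volume 136819.3 mm^3 -> demo/model.stl
```

and writes `phantom.mha`, `ground_truth_lumen.mha`, `lumen_mask.mha`,
`hollow_mask.mha`, `model.stl` and `report.json`. Reading the report:

- `peak_hu: 336` — mode of the histogram over the aneurysm sac; the phantom
  emulates the splenic-artery case whose lumen enhances to 336 HU.
- `threshold_hu: 208` — `(336 + 80) / 2`; the published threshold for that
  case.
- `lumen_voxel_count: 36825` — segmented lumen voxels (vessel + 25 mm sac).
- mesh report: `watertight: true`, `manifold: true`,
  `enclosed_volume_mm3: 136819` — the printable block (bounding box + 5 mm
  margin) minus the internal vascular cavity, with two open ports at the
  vessel ends.

The same run can be executed stage by stage (`vesselforge phantom`,
`segment`, `hollow`, `mesh`) through lossless MetaImage intermediates; the
artifacts are byte-identical to the single-shot run. A YAML config file
(`vesselforge run --config demo.yaml`) carries all parameters; see
`vesselforge.pipeline.PipelineConfig`.

As a library:

```python
from vesselforge import (preset_spec, generate_phantom, sphere_roi,
                         compute_histogram, histogram_peak, threshold_from_peak)

spec = preset_spec("patient3")
vol, truth = generate_phantom(spec)
roi = sphere_roi(vol, spec.aneurysm_center, 0.4 * spec.aneurysm_diameter_mm)
peak = histogram_peak(compute_histogram(vol, roi=roi))
print(peak, threshold_from_peak(peak))   # 218.0 149.0
```

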