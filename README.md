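# rpe3d — 3D morphometry of segmented outer-retina label volumes

The retinal pigment epithelium (RPE) is the support monolayer between the
photoreceptors and the choroid. Serial block-face scanning electron
microscopy (SBF-SEM) reconstructions of the mouse outer retina yield 3D
segmentations — integer label stacks in which every voxel is assigned to a
cell compartment (cell body, nucleus, apical microvilli, basal infold
spaces, mitochondria), a photoreceptor outer segment (OS), or Bruch's
membrane (BrM). `rpe3d` turns such label stacks into quantitative anatomy:

* **compartment volumes and surface areas** per cell, on anisotropic voxels
  (volume = voxel count × dx·dy·dz; area by voxel-face counting);
* **shared surface area between adjacent objects**, with two estimators:
  the slice-wise dilate-AND procedure used on the original reconstructions
  (per slice: dilate object 1 once with a 3×3 all-ones element, intersect
  with object 2, then `junctionLength = count · dx` and
  `junctionArea = junctionLength · dz`, summed over slices), and an
  independent voxel-face oracle (6-connected face pairs weighted by face
  area). The slice-wise estimator runs in a `fidelity` mode that replicates
  the original loop bound (which skips the final slice) and a `corrected`
  mode that processes all slices;
* **photoreceptor support**: an OS is supported by a cell iff it shares a
  voxel face with that cell's microvilli; counts, per-cell densities
  (photoreceptors per µm³ of cytoplasm) and microvilli–OS contact areas;
* **mitochondria statistics** per cell via connected components
  (26-connectivity by default): count, mean ± SD, minimum and total volume
  in nm³, basal fraction;
* **linear measurements** with the serial-stack sampling protocol (every
  N-th slice, k seeded-random measurements per slice): microvillus length
  (skeleton geodesic) and tilt angle (root→tip chord against the +x apical
  tangent), cell-body height, combined epithelium height, and BrM
  thickness;
* a **synthetic outer-retina phantom** — rhomboid cell monolayer, 1–2
  ellipsoidal nuclei, slanted microvilli interdigitating with OS rods,
  basal infold pockets, basally clustered mitochondria, and a noisy BrM
  slab — with fully analytic ground truth, used to validate every
  estimator end to end.

## Worked example

```python
from rpe3d import (CellSummary, PhantomSpec, SamplingScheme, generate_phantom,
                   microvillus_geometry, brm_thickness)

# derived arithmetic on measured volumes (µm³)
cell = CellSummary.from_volumes("cell1", 2220.2, [141.0],
                                photoreceptors_supported=90)
print(cell.nucleus_excluded_volume_um3)   # 2079.2
print(cell.photoreceptor_density_2sf)     # 0.041

# synthetic validation scene with analytic ground truth
vol, truth = generate_phantom(PhantomSpec(seed=1))
scheme = SamplingScheme(slice_interval=25, measurements_per_slice=10, seed=1)
lengths, angles = microvillus_geometry(vol, "cell_0_0", scheme)
print(f"{lengths.mean:.2f} um ± {lengths.sd:.2f} SD")   # 5.41 um ± 0.09 SD
print(f"{angles.mean:.1f} deg")                          # 143.0 deg
brm = brm_thickness(vol, SamplingScheme(25, 25, seed=1))
print(f"{brm.mean:.0f} nm (truth {truth.brm_mean_nm:.0f} nm)")  # 535 nm (truth 525 nm)
```

The nucleus-excluded volume is the exact subtraction of nuclei from the
cytoplasm (cell body + nuclei + interior organelles, microvilli and infold
spaces excluded); the density is reported at two significant figures. The
phantom numbers are estimator recoveries of the generator's parameters
(microvilli 5.5 µm at 143°, BrM 524.4 ± 200.5 nm) from the rasterised
50 nm voxel scene.

A command-line interface mirrors the library:

```bash
rpe3d phantom --out stack.tif --truth truth.json --seed 1
rpe3d morphometry --stack stack.tif --table stack.tif.labels.json \
    --out morpho.csv --mito-out mito.csv
rpe3d contacts --stack stack.tif --table stack.tif.labels.json \
    --mode corrected --out contacts.csv
rpe3d run-all --seed 1 --out-dir out/
```

`run-all` writes morpho.csv, mito.csv, interfaces.csv, contacts.csv,
geometry.csv, summary.csv and a run.json manifest; the bundle is
byte-deterministic for a fixed config and seed.

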