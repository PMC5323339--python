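# spectseg

Semi-automatic tumour segmentation and activity-concentration quantification
for quantitative SPECT, aimed at radionuclide-therapy dosimetry workflows
(e.g. ¹⁷⁷Lu-DOTATATE therapy of neuroendocrine tumours), together with a
synthetic phantom simulator for validating the whole chain without access to
Monte Carlo photon-transport simulations or patient data.

## The problem

Mean absorbed dose to a tumour is, for ¹⁷⁷Lu, essentially proportional to
the activity concentration measured in a volume of interest (VOI) on the
SPECT image. Getting that number right requires (i) a segmentation that
follows the physical object boundary despite poor spatial resolution and
noise, and (ii) a correction for spill-out — the resolution-induced loss
of counts from small hot objects. `spectseg` implements three segmentation
methods that share a rough, operator-drawn initialization VOI:

- **FT** — fixed threshold at 42% of the maximum voxel value in the
  initialization VOI.
- **OM** — the Otsu method adapted to continuous (floating-point) voxel
  values: every unique value inside the VOI is a candidate threshold and
  the one maximizing the between-class variance
  `w0·w1·(μ0−μ1)²` is chosen, with no histogram binning.
- **FS** — a deformable closed surface parameterized by Fourier
  descriptors: each coordinate `q(u, v)` of the surface is a truncated
  double Fourier series in the surface coordinates `u ∈ [0, 2π)` and
  `v ∈ [0, π]`. The coefficients maximize an edge-strength objective

  `B = Σᵢⱼ [∇I·n(uᵢ, vⱼ)] δ(uᵢ, vⱼ, ∇I) / (Σᵢⱼ |n(uᵢ, vⱼ)|)^α`,

  the rectified flux of the image gradient through the surface divided by
  the surface area raised to `α` (default 0.7), optimized by downhill
  simplex with the Fourier order escalated 2 → 3 → 4. Low orders only admit
  slowly varying shapes, which makes the method robust at low counts.

Quantification uses recovery coefficients: sphere phantoms of known volume
calibrate `R(V) = 1/(1 + (a/V)^b)`, after which a tumour's activity
concentration is estimated as `C = n / (R(V_tum)·ε·v_vox)` with `n` the
mean count rate per voxel in the VOI, `ε` the system sensitivity and
`v_vox` the voxel volume. Evaluation metrics include relative mean error,
rSD and rRMSE of repeated estimates and a geometric Dice similarity
coefficient that treats voxels as rectangular cuboids, so masks on grids
with different voxel sizes can be compared exactly.

## Worked example

```python
import numpy as np
from spectseg import (
    PhantomSpec, TumourSpec, AcquisitionSpec, VoxelGrid,
    build_phantom, simulate_reconstruction, make_initialization_voi,
    fs_segment, otsu_segment, dice_cross_grid,
)

grid = VoxelGrid((48, 48, 48), (2.5, 2.5, 2.5))      # 2.5 mm voxels
centre = (2.5 * 47 / 2,) * 3
phantom = PhantomSpec(grid, background=0.1,
                      tumours=[TumourSpec(centre, 8.89)])  # 8.89 cm^3, 10:1
activity, truth = build_phantom(phantom)
acq = AcquisitionSpec(fwhm_mm=12.0, count_scale=40.0, seed=1)
image = simulate_reconstruction(activity, acq, realization_index=0)
voi = make_initialization_voi(truth.masks[0], margin_mm=10.0)

fs_mask = fs_segment(image, voi)
om_mask = otsu_segment(image, voi).mask
print(f"true volume: {truth.volumes_cm3[0]:.2f} cm^3")
print(f"FS: {fs_mask.volume_cm3:.2f} cm^3, "
      f"DSC {dice_cross_grid(fs_mask, truth.masks[0]).dsc:.3f}")
print(f"OM: {om_mask.volume_cm3:.2f} cm^3, "
      f"DSC {dice_cross_grid(om_mask, truth.masks[0]).dsc:.3f}")
```

Output:

```
true volume: 8.89 cm^3
FS: 7.38 cm^3, DSC 0.899
OM: 8.84 cm^3, DSC 0.832
```

The true volume is the rasterized tumour. In this single noisy
realization OM lands closer on volume while FS produces the better-shaped
mask (higher Dice); across repeated realizations the smoother FS surface
is the more stable of the two. At lower count levels (smaller `count_scale`)
FT degrades into scattered voxel islands while FS remains usable — the
simulation study (`spectseg run-study`) quantifies that contrast.

A command-line interface mirrors the library:

```sh
spectseg segment --method fs --image img.nii.gz --init-voi voi.nii.gz --out mask.nii.gz
spectseg calibrate-rc --table rc.csv --out curve.json
spectseg quantify --image img.nii.gz --voi mask.nii.gz --rc curve.json \
    --sensitivity 10.0 --out conc.json
spectseg run-study --out study/ --seed 0
spectseg compare-masks a.nii.gz b.nii.gz
```

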