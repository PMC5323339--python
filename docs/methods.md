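# Methods

This note documents the models implemented in `spectseg`, the parameter
choices that matter, and what the synthetic phantom generator does and does
not emulate.

## Coordinate and data model

All images and masks live on axis-aligned voxel lattices: voxel `(i, j, k)`
has its centre at `origin + (i·sx, j·sy, k·sz)` in world millimetres, with
0-based indices. Rotated or oblique orientations are rejected at load time
(NIfTI and MetaImage readers check the direction matrix); supporting
rotation would complicate every downstream geometric operation for little
benefit in this context, where reconstructed emission images and phantom
grids differ in spacing and origin but not orientation. Masks are written
as unsigned 8-bit {0, 1}; on reading, any nonzero value counts as
membership.

Interpolation is trilinear, returning 0 outside the voxel-centre hull —
emission images are count maps whose background tends to zero, so this is
the least surprising extrapolation. Image gradients are computed by
3×3×3 Prewitt-style convolutions: a central difference along the target
axis (one-sided at the two boundary slabs) averaged over the 3×3 transverse
neighbourhood, normalized so a unit slope per millimetre yields a component
of exactly 1. Any antisymmetric smoothing-difference kernel would serve;
this one is standard, separable and cheap.

Binary morphology uses a full 3×3×3 cube (26-neighbourhood) for closing and
6-connectivity for component labelling and the background flood fill in
`solidify`. The 6-connected background definition is the conservative
choice: a cavity must be sealed on faces, not merely corners, to count as
a hole.

## Threshold segmentation

**FT** thresholds at a fixed fraction (default 0.42) of the maximum voxel
value inside the initialization VOI; voxels with value ≥ threshold are
object. The equality case is included in the object so that a uniform VOI
is classified entirely as object rather than entirely as background.

**OM** adapts the Otsu criterion to continuous values. Because
reconstructed SPECT voxel values are floating point, binning a histogram
would introduce an arbitrary bin width; instead every unique value in the
VOI is a candidate threshold `t`, classifying values ≤ t as background and
> t as object, and the candidate maximizing `w0·w1·(μ0−μ1)²` is selected.
Any real threshold strictly between two consecutive unique values produces
the same classification, so the unique values exhaust all possible splits.
When several candidates tie, the lowest is returned (larger object class —
conservative against under-segmentation). Both methods classify only
voxels inside the initialization VOI and apply no connectivity repair, so
at low counts FT can and does produce scattered voxel islands; that
failure mode is part of what the simulation study measures.

## Fourier-surface segmentation

A closed surface is parameterized per coordinate `q ∈ {x, y, z}` as

```
q(u,v) = a_{q,0,0} + 2 a_{q,0,1} cos v
       + 2 Σ_{l=1}^{K-1} c_{q,0,l} sin(lv)
       + 4 Σ_{m=1}^{K-1} Σ_{l=1}^{K-1} [c_{q,m,l} cos(mu) sin(lv)
                                        + d_{q,m,l} sin(mu) sin(lv)]
```

with `u ∈ [0, 2π)`, `v ∈ [0, π]` and `K` Fourier orders in both directions
(2 + (K−1) + 2(K−1)² coefficients per coordinate). All `sin(lv)` terms
vanish at the poles, so the surface closes by construction. This basis is
deliberately reduced relative to the full classical double-Fourier-series
surface family (no `cos(lv)` terms beyond l = 1 and no cos·cos/sin·cos
cross terms); the reduced basis is what is implemented and tested here.

**Initialization.** The VOI is Otsu-thresholded, closed morphologically,
and the largest 6-connected component kept. Its centre of mass gives the
ellipsoid centre; the principal components (Hotelling transform) of the
member-voxel world coordinates give the axis directions (with half a
voxel of positional variance added per axis so flat objects stay
non-degenerate); the semi-axis lengths maximize (object voxels inside −
non-object VOI voxels inside), scanned over a common scale factor and then
refined by Nelder–Mead on the log-axes. For a uniform solid ellipsoid the
coordinate variance along a principal axis is `r²/5`, which provides the
starting lengths. The ellipsoid maps exactly onto an order-2 surface:
in the ellipsoid frame `c_{x,1,1} = r₁/4`, `d_{y,1,1} = r₂/4`,
`a_{z,0,1} = r₃/2`, and because the basis is linear in the coefficients a
rotation acts coefficient-wise across the x/y/z families.

**Objective.** Edge strength is the rectified flux of the image gradient
through the surface divided by the surface area raised to `α`:

```
B = Σ w_ij [∇I(p_ij) · n(u_i, v_j)] δ_ij / (Σ w_ij |n(u_i, v_j)|)^α
```

Normals are the analytic `∂r/∂u × ∂r/∂v`, oriented outward (flipped where
they point toward the surface centre point `a_{·,0,0}`). For a hot object
the intensity decreases outward, so δ = −1 where `∇I·n_out < 0` (making
the contribution positive) and δ = 0 for wrong-way gradients; a cold
polarity flag inverts this, and `polarity="none"` disables both the
rectification and the orientation fix, leaving the raw signed flux — in
that mode the discrete flux of a constant field through any closed surface
vanishes identically, a property the tests exploit. Sampling uses N₁ = 36
uniform nodes in `u` (trigonometric exactness) and N₂ = 36 Gauss–Legendre
nodes in `v` (pole-free, spectrally accurate), with the associated
quadrature weights `w_ij`, so both sums are genuine surface integrals and
the denominator base is the surface area in mm². The exponent α (default
0.7) weakens the area penalty enough that the weak gradients of
low-resolution emission images can balance the surface against shrinking;
α = 1 is direct area normalization, α = 0 none.

**Optimization.** Downhill simplex (Nelder–Mead) over all coefficients,
maximizing B. The order escalates 2 → 3 → 4, appending zero-valued
coefficients at each promotion. Within an order, the simplex restarts from
the incumbent until the relative objective change falls below 10⁻³ or five
restarts are reached; a single simplex run converges when coefficient and
objective spreads fall below 10⁻³ (relative, scaled by the mean initial
semi-axis). The initial simplex perturbs existing coefficients by 5% of
the mean semi-axis and appended (zero) coefficients by 2%. The incumbent
is tracked across stages, so the returned surface never scores below the
initialization. The default iteration cap is 120·n_parameters per simplex
run; the study harness uses a lighter budget (25·n, two restarts) chosen
to keep the 30-realization benchmark tractable on a single core — the
measured segmentation quality is essentially unchanged, because most of
the objective gain occurs early in each stage.

**Voxelization.** Candidate voxels (the padded bounding box of a dense
144×72 surface sampling) are classified by the sign of
`(voxel centre − nearest surface sample) · n_out`: negative means inside.
The nearest sample is found with a k-d tree; at this sampling density the
classification boundary is accurate to a few hundredths of a millimetre
for object-scale curvature, which the ellipsoid volume tests confirm
(within 2% at semi-axes ≥ 5 voxels). Folds in the surface flip the local
normal and can misclassify voxels, so the mask is repaired with
`solidify`: the exterior is flood-filled from the grid border
(6-connected), enclosed cavities become object, and only the component
containing the surface centre point is kept. A surface smaller than one
voxel yields the single voxel containing its centre point.

## Phantom simulation

The generator replaces a Monte Carlo projection / iterative reconstruction
pipeline with a phenomenological model on the reconstruction grid:

1. **Activity map** — piecewise constant: uniform background plus tumours
   of prescribed volume. A tumour is rasterized by taking the `n` voxels
   closest in normalized radius, `n = round(V/v_vox)`, so the rasterized
   volume matches the target within half a voxel regardless of lattice
   degeneracies. Shapes are spheres, ellipsoids (volume-preserving axis
   ratios) or "lumpy" spheres whose radius is modulated by seeded
   low-order angular harmonics (relative amplitude < 1), giving relatively
   round but non-spherical objects; high-frequency shape detail would not
   survive the SPECT point-spread function anyway.
2. **Expected image** — Gaussian blur of the activity map (FWHM in mm,
   default 12, resolving the anisotropic voxel case per axis) times a
   count scale (expected counts per unit concentration per voxel, folding
   in sensitivity, acquisition duration and decay). An optional
   edge-enhancement term adds unsharp-mask overshoot — the difference
   between the expected image and a 2× broader blur, scaled by an
   amplitude — emulating the rim artefacts of resolution-compensated
   reconstructions (ASR-like); amplitude 0 is the plain (AS-like) case.
   Negative values from the overshoot are clipped at zero.
3. **Noise** — each voxel is replaced by a Poisson draw with the expected
   value as mean, deterministic given (seed, realization index).

Two named count-scale presets mimic an early and a late imaging time
point: "early" puts ≈10⁵ expected counts in a 40 cm³ tumour of unit
concentration, "late" is 1/50 of that, reproducing the early/late noise
contrast of a multi-time-point dosimetry protocol. These are working
points, not claims of physical fidelity.

What the emulation reproduces: spill-out from small hot objects, noise
jaggedness at low counts, edge overshoot under resolution compensation,
and the interplay of all three with the segmentation methods. What it does
not reproduce: attenuation and scatter physics, collimator response,
reconstruction convergence behaviour, anatomical background structure,
intra-tumour heterogeneity, or patient motion. Conclusions from passing
tests therefore concern the algorithmic behaviour of the methods under
controlled degradation, not their clinical accuracy.

The recovery-coefficient calibration phantom places a uniform sphere at
the centre of a cold elliptical-cylinder field of view with 20 cm and
10 cm semi-axes; one phantom per requested volume. By default the grid is
sized to the sphere plus 60 mm for the PSF tails, which keeps border
losses negligible.

## Quantification

The recovery curve `R(V) = 1/(1+(a/V)^b)` is fitted to (volume, RC) pairs
by unweighted least squares on the RC values, with positivity of `a` and
`b` enforced by optimizing their logarithms (Levenberg–Marquardt; initial
`a` is the volume whose RC is nearest 0.5, initial `b` = 1). The curve is
strictly increasing with `R(a) = 0.5` for any admissible parameters. No
weighting scheme is applied because the calibration RCs here are
noise-free by construction; with noisy calibration data a user may prefer
weighted residuals.

Concentration estimation evaluates `R` at the estimated VOI volume, not
the true one — the same VOI supplies the mean count rate `n` and the
volume — so segmentation volume errors propagate into the concentration
exactly as they would in practice. In synthetic studies the calibration is
derived from the count scale: `ε = count_scale / v_vox`. For real planar
calibration data, `sensitivity_from_planar` computes total counts over
activity. VOI/image combinations (e.g. AS/ASR) apply the mask segmented on
one image type to measurements on another.

## Evaluation

Relative mean error uses the mean of N estimates over the reference minus
one; rSD uses the N−1 (sample) denominator; rRMSE the N denominator. They
satisfy `rRMSE² = Ē² + rSD²·(N−1)/N` exactly, which the tests assert to
1e−12. A single estimate yields NaN rSD (flagged undefined).

The cross-grid Dice coefficient treats voxels as rectangular cuboids and
accumulates the exact intersection volume of the two cuboid sets via
per-axis interval-overlap matrices contracted over the mask bounding
boxes. This is exact (no resampling error) and reduces to voxel-count
Dice on identical grids. Masks on mutually rotated grids are rejected,
consistent with the package-wide axis-aligned contract. Two empty masks
give DSC 0 with a degeneracy flag. Percentiles of DSC distributions use
linear interpolation between order statistics.

## Study harness

`run_study` wires the pieces together: build phantom → one initialization
VOI per tumour (truth dilated by the margin, default 10 mm, shared across
all realizations, time points and methods) → per time point and image
type, N noise realizations, segmentation by each configured method,
recovery calibration from noise-free sphere phantoms at matched
acquisition settings, concentration estimation for each VOI/image
combination → error statistics and DSC percentiles per (time point, image
type, tumour, method). Per-case failures (e.g. an empty mask from a
collapsed segmentation at low counts) are recorded and the study
continues; the report flags groups whose median DSC falls below a
threshold (default 0.2) as cases where evaluation is not meaningful.
Outputs are a pure function of (config, seed); the CSVs are
byte-reproducible.

The default benchmark uses three lumpy tumours of 2.75, 8.89 and 40.0 cm³
at 10:1 tumour-to-background contrast on a 72×72×48 grid of 2.5 mm voxels,
30 realizations per time point, early and late presets. The acceptance
script runs the same design at 10 realizations per time point — a
problem size chosen so the full recomputation stays comfortable on a
single core while leaving the metric medians stable.

## Known limitations

- The image-formation model is stationary Gaussian blur; real
  reconstructed SPECT has spatially varying resolution and correlated
  noise, so absolute error magnitudes here do not transfer to clinical
  images.
- The δ rectification resolves the sign ambiguity of the gradient flux by
  explicit outward orientation of the normals; other consistent
  conventions exist for handling the surface handedness.
- The optimizer is a local search from the ellipsoid initialization;
  objects with strong nearby confounders (adjacent hot structures) can
  capture the surface, which is why the initialization VOI remains an
  operator responsibility.
- Quantification assumes the calibration sphere geometry is representative
  of the measured object; deviations in contrast or shape affect recovery
  beyond the volume dependence modelled by `R(V)`.
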