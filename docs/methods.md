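# Methods

This note documents the models, parameter choices, numerical decisions, and
known limitations of the `imsar` pipeline.

## Physical model

All volumes live on a common regular grid in (x, y, z) index order with
spacing in mm; differential operators convert spacing to meters internally,
so every physical quantity is SI (σ in S/m, SAR in W/kg, Laplacians in
rad/m²). The pipeline assumes inputs are already co-oriented; only
grid/spacing resampling (trilinear for images, nearest for labels) is
performed, with out-of-support voxels filled with 0 and treated as
background everywhere downstream.

### Conductivity

Phase-based Helmholtz-EPT: σ = ∇²φ_tr / (2 μ₀ ω), valid where tissue is
locally homogeneous and the transceive phase assumption holds (quadrature
volume coil; φ_tr ≈ 2·arg B1+). The working frequency defaults to
f₀ = 128 MHz (3 T) and is a mandatory, logged config item, because a
scanner's true operating frequency can differ by a few percent and ω enters
σ linearly.

The Laplacian comes from a weighted least-squares degree-2 polynomial fit
over a local footprint (3D Savitzky–Golay). Degree 2 is the minimum that
exposes a Laplacian and is used for every kernel. Footprint conventions:

| filter | shape | convention | footprint |
|---|---|---|---|
| EPT Laplacian | cuboid, size 5 | half-extent = size // 2 | 5×5×5 |
| postprocessing | cube, size 10 | symmetric, half-extent 5 | 11×11×11 |
| B1+ gradient | ellipsoid, size 4 | semi-axes = 4 voxels | 9³ box masked to the ellipsoid (257 voxels) |

Sizes of even extent are made symmetric (10 → 11³) so the estimate stays
centered. The fit is performed in voxel-offset coordinates for conditioning
and the coefficients rescaled by the voxel size, so a globally quadratic
phase is reproduced to machine precision.

**Anatomical adaptation.** Footprint voxel j is weighted
`exp(−(R_j − R₀)² / (2 (w ΔR)²))`, where R is a reference image (T1-like),
R₀ its value at the center voxel, ΔR its range over the foreground, and w a
dimensionless width (0.05 for the Laplacian/gradient kernels, 0.1 for the
postprocessing filter). Background voxels always weigh 0. This is one
concrete reading of "reference image with a weight parameter"; it is
isolated behind `sg_fit_weights` so an alternative semantics can be swapped
in without touching the solver.

A voxel whose footprint retains ≤ 10 usable voxels (fewer than the number
of monomials), or whose normal matrix is singular, is marked
unreconstructable (NaN) rather than raising; NaN propagates through every
downstream statistic. Negative σ voxels are retained in the raw map but
excluded from per-tissue means — they are noise artifacts, and clipping
them silently would bias the means upward.

### E-field

The measurable transmit field alone cannot determine E; the closure
B1− = 0, Bz = 0 (hence Bx = B1+, By = −i B1+) makes the time-harmonic
Ampère–Maxwell law solvable voxelwise:

```
Ex = ( i ∂z B1+) / (μ₀ τ)
Ey = (   ∂z B1+) / (μ₀ τ)
Ez = (−i ∂x B1+ − ∂y B1+) / (μ₀ τ),     τ = σ + i ω ε₀ εr
```

σ is the piecewise-mean EPT map; εr is a literature table expanded over the
labels (GM 73.5, WM 52.5, CSF 84.0 at 128 MHz, from the standard dielectric
tissue database parametrisation — the conductivities from the same source
are GM 0.59, WM 0.34, CSF 2.14 S/m). The closure systematically
underestimates |E|; the tissue-specific correction factors applied at the
SAR stage (derived externally from anatomical-model ensembles and applied
here as constants) compensate in the mean. Component signs are not
observable downstream — only |E| enters SAR.

The time-harmonic sign convention (+iωt vs −iωt) conjugates every phasor,
the closure, and the admittance at once, so the −iωt result is exactly the
conjugate of the +iωt result; |E| and SAR are invariant, which the tests
assert numerically.

### SAR chain

`SAR = σ |E|² / (2ρ)` with stored amplitudes treated as peak values (the
factor 2 is the harmonic time average) and ρ = 1000 kg/m³. The processing
order is fixed and logged: pointwise SAR → Gaussian smoothing → outlier
removal → correction. Smoothing uses σ_g = 0.4 in voxel units (a bare
filter width below the voxel pitch only makes sense on the voxel lattice)
via normalised convolution — the volume with undefined voxels zeroed and
the defined-voxel indicator are smoothed separately and divided, so
background never bleeds in and constants are preserved exactly. Outlier
removal computes mean + 9·SD once (not iterated) over defined foreground
voxels and sets strictly-exceeding voxels to undefined rather than clamping
them; a uniform map therefore loses nothing (SD = 0, strict comparison).

### 10-g SAR

For each tissue voxel an axis-aligned cube grows in whole-voxel shells
(half-width h = 0, 1, 2, …), counting only tissue voxels' mass
(density × voxel volume), and stops at the smallest h reaching 10 g; the
output is the mean SAR over the cube's defined tissue voxels. Near
tissue–air boundaries the cube grows larger than the interior h because air
contributes no mass. Whole-voxel growth means the achieved mass overshoots
by up to one shell (no IEC-style fractional-shell weighting); the per-voxel
kernel-mass map makes the overshoot auditable, and the tests verify both
the mass guarantee (≥ 10 g everywhere) and minimality (h−1 held < 10 g).
Cubes are axis-aligned in voxel space despite anisotropic voxels. Averaging
runs on the uncorrected SAR; the dedicated 10-g factors are applied
afterwards, keyed by the center voxel's tissue. At (2.3, 2.3, 2.5) mm and
1000 kg/m³ a voxel weighs 13.225 mg, so an interior voxel needs 757 voxels
→ h = 5 (11³ = 1331).

## Synthetic phantoms

The generator's purpose is forward/inverse consistency, not electromagnetic
realism. Within each homogeneous region the transceive phase is the
quadratic `(μ₀ ω σ/3)·|r − c|² + 0.1·label`, whose analytic Laplacian is
exactly 2 μ₀ ω σ — so a noiseless phantom is recovered exactly by the
implemented inverse, and any discrepancy in tests is attributable to noise
or boundaries, not model mismatch. Phase continuity across region
boundaries is deliberately not enforced; boundary layers (within two kernel
half-widths) are excluded from recovery statistics, mirroring the
boundary-error behaviour of real reconstructions.

Defaults are the validation conditions: six 16-mm-radius saline vials
(0.16, 0.32, 0.39, 0.46, 0.56, 0.75 S/m) on a 38-mm ring inside a 60-mm
water cylinder, on a 128×128×35 grid at (2.3, 2.3, 2.5) mm; phase noise SD
0.01 rad, 1% relative magnitude noise, seed 1234. The sphere phantom is
distilled water (0.01 S/m, εr 80). The brain-like phantom is concentric
ellipsoids (CSF rim, GM shell, WM core, two CSF ventricles) on a
64×64×32 grid — a small head-like FOV chosen once so the full pipeline runs
in minutes. B1+ magnitude is a center-bright Gaussian profile (birdcage-like
center brightening), amplitude 2 µT — a typical 3 T transmit level that
puts phantom SAR on the in vivo W/kg scale.

The synthetic anatomical reference is a T1-like piecewise-constant image
with well-separated intensities for spatially adjacent compartments (vials
alternate two levels around the ring). Raw label codes are unsuitable as a
reference: codes that happen to be numerically adjacent (vial 6 vs water 7)
look similar to the Gaussian weight and cause cross-compartment leakage
that is purely an artifact of code ordering.

What the phantoms do **not** emulate: full-wave field curvature (the B1+
phase of a real coil is not piecewise quadratic), B0-related phase
contamination, receive-field residuals after intensity correction, Gibbs
ringing, partial-volume boundary voxels, or motion. Passing the phantom
tests therefore demonstrates correctness of the implemented operators and
their noise behaviour — not accuracy on scanner data, where the transceive
assumption and segmentation quality dominate.

## Numerical choices

- Batched weighted least squares: per-voxel normal equations assembled with
  BLAS over chunks of ~4×10⁶ gathered footprint elements, solved with a
  batched 10×10 solve; a rank-deficient chunk falls back to a pseudo-inverse.
- NIfTI-1 is the on-disk format; complex maps are stored as
  magnitude/phase pairs with a JSON sidecar, keeping every file a plain
  scalar volume. Outputs are written uncompressed so identical runs produce
  byte-identical files.
- The 10-g box sums use exact integer integral images, so the mass
  comparison has no floating-point slack.
- Quartiles use linear interpolation; skewness is the adjusted
  Fisher–Pearson estimator; Pearson r comes with a two-sided p-value.
- Concentric evaluation regions are equal-width thirds of the normalised
  distance (in mm) to the foreground centroid.
- Peak lookup breaks ties at the lowest linear (C-order) index.

## Problem sizes

The shipped validation and tests run at the native 128×128×35 grid for the
six-vial recovery (~66 k foreground voxels, seconds per reconstruction) and
64×64×32 or smaller for full-pipeline and property tests; these sizes are
the package's reference configurations for reproducibility.

## Known limitations

- Phase-based EPT is biased at tissue boundaries and for small
  high-contrast structures (CSF is recovered low in the brain-like phantom
  because its thin shell is boundary-dominated).
- The correction factors are population-level constants; they repair the
  B1+-only closure in the mean, not per subject.
- Permittivity is not reconstructed — it is a literature table over the
  labels.
- No affine registration, bias-field correction, or segmentation: labels
  and co-oriented volumes are inputs.
- Whole-voxel 10-g cube growth overshoots the target mass by up to one
  shell; fractional-mass and non-cubic averaging variants are out of scope.
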