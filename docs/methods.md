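# Methods

This note documents the models, numerical choices and known limitations of
the mr2pet pipeline: what each stage assumes, which parameters matter, what
the digital phantoms do and do not emulate, and therefore what a passing
test suite does and does not demonstrate about real PET/MRI data.

## Digital phantoms

Each case is an elliptical body on a configurable grid (default 96×96×48
voxels at 2 mm; tests use 32³–64³ at 3–4 mm) containing:

* ≥5 ellipsoidal organs placed by rejection sampling (non-overlapping,
  inside the body, clear of bone and lung). Four "anchor" organs carry
  uptake levels 2.5, 6.5, 14 and 26 SUV (±4% jitter) so the default
  histogram bins `[0,1), [1,4), [4,10), [10,20), [20,∞)` are always
  populated — near-zero background, moderate organs, and a hot
  brain/bladder-like structure above 20 SUV. One organ per case draws its
  uptake independently of its MR intensity (uniform on [1.5, 28] SUV),
  emulating variable-uptake organs such as heart and bladder.
* A spine-like bone ellipsoid (high attenuation) and two lung-like
  low-attenuation ellipsoids.
* Soft tissue background at 0.35 SUV, lung 0.20, bone 0.55; uptake is
  exactly zero outside the body.

MRI is an affine function of the tissue label, multiplied by a smooth bias
field (Gaussian-filtered noise, ~12 mm correlation length, ±15%
amplitude) plus i.i.d. Gaussian noise (σ=0.02 by default): structurally
informative but not a deterministic proxy for uptake.

Attenuation coefficients at 511 keV (per mm): air 0, lung 0.0030, soft
tissue 0.0096, bone 0.0150 — literature-scale constants, configurable; the
degraded MR-based map (`mu_mrac`) replaces the bone coefficient with the
soft-tissue value and changes nothing else, the characteristic failure of
2-point Dixon segmentation (bone is invisible at MR echo times). By
construction `mu_mrac ≤ mu_ct` voxel-wise.

What the phantoms do **not** emulate: realistic anatomy beyond piecewise
ellipsoids, textured or heterogeneous uptake, respiratory/cardiac motion,
Monte-Carlo photon transport, and count statistics (see Tomography). A
passing suite therefore certifies the *mechanics* of the pipeline —
operators, objectives, reconstruction, bookkeeping — not clinical-grade
image realism.

## Preprocessing

SUV conversion uses the body-weight convention with decay applied to the
injected dose: `SUV = activity · (weight·1000 g) / (dose · 2^(−Δt/T½))`.
Counts-mode inputs are divided by the positron fraction and a single
scanner calibration factor (exposed as configuration, since the
counts→Bq/mL chain is scanner-specific). CLAHE runs on 3-D tiles of
`round(kernel_mm / spacing)` voxels (defaults 100 mm, clip limit 0.05)
with trilinear blending between tile mappings; a constant volume is passed
through as a constant (equalization of a zero-range image is undefined).
Resampling to isotropic grids uses trilinear interpolation for intensities
and nearest-neighbour for masks/labels, preserving world extent to within
one voxel.

## Network and objective

The residual UNet uses conv3–ReLU–conv3 blocks with identity (or
1×1×1-projected) shortcuts, 2×2×2 max pooling, transposed-convolution
upsampling, concatenation skip connections, and a softplus output head
(SUV is physically nonnegative). With five encoder stages there are four
poolings, so the network itself requires input dimensions divisible by
2⁴=16; the patch-inference layer keeps the stricter divisible-by-32
contract of the default 128-voxel patches and is responsible for padding
(reflect; edge-padding only when a patch exceeds twice the volume).

The engine is a self-contained numpy implementation (float32, one BLAS
call per kernel tap, analytic backward passes verified against finite
differences in the suite). Adam adds L2 weight decay to the gradient
(classic convention, biases excluded). Everything is seeded; training is
bit-reproducible on a given machine.

The balanced loss is read as *per-bin means*: `Σ_j α_j · mean(E | h_j) +
Σ_k β_k · mean(E/(y+ε) | h_k)` with target-defined bins (bins of `y`, not
of the prediction) and empty bins contributing zero. This is the reading
under which a single all-encompassing bin with α=1, β=0 reduces exactly to
MAE — cross-checked in the tests. ε=1e-3 stabilizes the relative term.
Default bin edges `[0,1,4,10,20,∞)` give B=5 to match the five-element
weight vectors; both edges and weights are configurable.

The LOR loss applies a parallel line-integration operator `R_{θ,φ}` (full
3-D line integrals along oblique directions; half-voxel marching steps,
trilinear interpolation, 1-voxel detector pitch, built once per direction
as a sparse matrix and cached) to the relative-error volume and returns
the L2 norm of the projected values, averaged over the sampled directions.
λ defaults to 1.0 and the number of directions per step to 4, drawn from a
seeded pool of 8 uniform-on-the-sphere directions (the pool keeps the
per-direction sparse operators cacheable). The loss operates in voxel
units, which is exact for the isotropic patches used in training.

**Smoke-scale training dynamics.** With λ=1 and ε=1e-3, zero-activity
voxels carry relative weight 1/ε=1000 in `J_LOR`, so early optimization is
dominated by suppressing background to zero; at the suite's smoke scale
(200 steps, 1-patch batches, 32³ patches, 8 cases) predictions remain
near zero everywhere while `J_total` falls by ~99.9% and test MRAE drops
roughly 40-fold relative to the untrained network (whose softplus
initialization outputs ≈0.7 SUV everywhere). Recovering organ-level uptake
requires training far beyond smoke scale. The smoke tests therefore
certify gradient correctness, optimization descent and reproducibility —
not translation quality.

The phenotype sampler catalogs all non-overlapping (end-aligned) patches,
featurizes each by a 16-bin normalized SUV histogram over [0, 32] SUV, and
clusters with seeded k-means (K=10, reduced with a warning when patches
are scarce). Draws cycle the non-empty clusters; within a cluster, patches
are drawn without replacement in seeded random order and reshuffled on
exhaustion, so per-cluster draw counts never differ by more than one.

## Tomography

The projector is a per-slice parallel-beam stand-in for a vendor system
matrix: time-of-flight bins, PSF modeling and detector-efficiency
normalization are collapsed (the quantification experiment measures
attenuation-map effects, which a non-ToF projector exercises at desk
scale), and scatter/randoms are excluded (the background term `b` defaults
to zero). Optional Poisson resampling of sinograms is provided for users
but off by default — the noiseless pipeline is deliberately deterministic.

Line integrals march with a step of half the in-plane voxel size and
bilinear interpolation; the attenuation integral covers the full chord
(both annihilation photons). The operator is materialized once per
(grid, geometry) pair as a sparse matrix, so: the backprojector is the
exact adjoint by construction (inner-product identity holds to ~1e-16);
forward projection is exactly linear in activity; and OSEM updates are
sparse matrix products applied to all slices at once. Angle subsets are
interleaved modularly (`s, s+S, s+2S, …`), with unequal sizes allowed when
the subset count does not divide the angle count. OSEM initializes to a
uniform positive image, freezes zero-sensitivity voxels at 0 (never NaN),
and post-filters with a separable Gaussian (σ = FWHM/2.3548; 0 = identity).

Because simulation and reconstruction share the same discretized operator,
noiseless recovery is an inverse-crime setting: the measured ~4% body
MRAE after 8 subsets × 20 iterations quantifies iteration convergence and
attenuation handling, not real-scanner accuracy.

The CT-number conversion is bilinear: `μ = μ_water·(1+HU/1000)` below
0 HU (clamped at zero), and a bone segment above 0 HU mapping 1000 HU to
the default cortical-bone coefficient. At 511 keV the bone segment is
shallower than a water-scaled extrapolation, as in standard conversion
curves.

## Lesions and quantification

Lesions are spheres rasterized by the voxel-centre-in-sphere rule
(overlaps take the maximum) into a zero-filled volume, forward projected
with the CT attenuation map, and *added* to the source sinogram — nothing
in the source volume is replaced, so insertion is exactly linear and
order-independent. Default placement is programmatic on the phantom's
label volume: one sphere adjacent to bone, one inside bone, one in deep
soft tissue, one near the body edge — stressing MR-based attenuation
correction where activity borders bone, without a human annotator.

Metrics: MAE over all voxels; MRAE over voxels of at least 0.1 SUV (an
explicit error if no voxel qualifies); 3-D SSIM with uniform sliding
windows and constants `c1=(0.01·L)²`, `c2=(0.03·L)²` proportional to the
dynamic range L. Peak-SUV is not universally standardized; the
conventional definition adopted here is the maximum, over in-mask
positions, of the mean uptake within a 1 cm³ spherical neighbourhood
(radius 6.2 mm, clipped at the volume border via a normalized
convolution).

The experiment driver supports three source volumes — the live phantom
(OSEM/CTAC reconstruction of the simulated measured sinogram), a uniform
SUV-1 body (Otsu threshold of the MRI, configurable), and the synthetic
translation — because measured list-mode data cannot exist for digital
phantoms. Δ_true always comes from the live source. γ is reported as NaN
(undefined, not infinite) when Δ_true = 0, and never for the background
VOI, where near-zero activity voxels would positively skew relative error;
background error there is better inspected through per-slice error maps.
The driver is noiseless and fully seeded, so reports reproduce
byte-for-byte.

## Problem sizes

Package defaults follow clinical-style settings: 96×96×48 phantoms at
2 mm, 180 views, 28 subsets × 2 iterations with 2.0/4.0 mm filters,
128-voxel training patches, effective batch 16. The test suite and the
acceptance script run the same code at smoke scale — 32³–64³ phantoms at
3–4 mm, 12–96 views, 8 subsets, 200 training steps with 32³ patches —
sizes chosen so the full pipeline (including training) completes in
minutes on one CPU while still exercising every contract.

## Known limitations

* No scatter, randoms, ToF, PSF or detector normalization; sinograms are
  noiseless unless Poisson resampling is requested.
* Shared projector between simulation and reconstruction (inverse crime):
  recovery numbers are optimistic relative to real scanners.
* Phantom anatomy is piecewise-ellipsoid; organ uptake is piecewise
  constant.
* Smoke-scale training does not produce clinically meaningful synthetic
  uptake; it verifies optimization mechanics only.
* Training determinism is guaranteed per machine/BLAS build, not across
  different BLAS implementations.
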