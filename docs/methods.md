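# Methods

## Problem

Sparse-view CT acquires far fewer projection angles than an exact
reconstruction requires. Filtered back-projection (FBP) of such data
produces directional, globally distributed streaking artifacts. This
package implements a dual-domain learned reconstruction: a sinogram
completion network in the radon domain (RDNet), a differentiable FBP
bridge, and an image restoration network in the image domain (IDNet),
trained end-to-end; plus the simulation, classical baselines (FBP,
linear-interpolation + FBP, SART, SART-TV) and metrics (PSNR, SSIM)
needed to compare and ablate it on synthetic phantoms.

## Simulation model

Parallel-beam geometry with `n_views` uniform angles over [0°, 360°) and
`n_detectors` equal to the image side at one-pixel spacing. The forward
projector marches each ray in unit steps and spreads samples over the
four neighbouring pixels with bilinear weights; the discretization is
assembled into a sparse matrix `A`, so the backprojection `A^T` is the
*exact* adjoint — the property that SART and backpropagation through FBP
rely on. Because the sample lattice is a unit-spaced rotated grid and
bilinear weights sum to one, detector sums per view conserve total pixel
mass to well under 0.5 % for objects inside the inscribed circle, and
phantoms are generated with support inside that circle.

FBP applies the standard discrete ramp kernel (h[0] = 1/4,
h[odd n] = −1/(πn)², zero-padded to a power of two; Shepp–Logan and Hann
apodization optional) along the detector axis and scales the
backprojection by half the view spacing in radians, so intensity is
comparable across subsampling factors. The ramp circulant is symmetric,
hence the FBP map `scale · A^T F` has adjoint `scale · F A` — used
directly as the analytic backward pass of the differentiable FBP bridge.
360° coverage is kept although parallel-beam data is 180°-redundant,
matching the simulated acquisition the package emulates; the redundancy
is absorbed by the factor ½ in the scale.

Angular subsampling keeps every k-th view starting at view 0 (k ∈ {3, 4,
6, 12} gives 120/90/60/30 views from 360). Sinogram completion starts
from per-detector-row linear interpolation over angle with circular wrap
across the 360°/0° seam; measured views are preserved exactly.

## Wavelet transforms

The one-level 2D Haar transform uses the unnormalized ±1 filters: each
disjoint 2×2 block [[a, b], [c, d]] maps to CA = a+b+c+d,
CDh = −a−b+c+d, CDv = −a+b−c+d, CDd = a−b−c+d, and the inverse divides
by 4. No orthonormal rescaling is applied, so subband energy is exactly
4× image energy per level (the per-block analysis matrix M satisfies
M Mᵀ = 4I). The wavelet-packet transform recurses into all four subbands,
giving 4^L leaves. The channel-stacked variants transform each feature
channel independently and concatenate subbands along the channel axis in
the frozen order [CA | CDh | CDv | CDd] (trained weights depend on this
order). Since M⁻¹ = Mᵀ/4, the adjoints used by backpropagation are
adjoint(DWT) = 4·IWT and adjoint(IWT) = DWT/4 — exact, no numerical
differentiation anywhere.

## Networks

All three builders produce residual predictors: the network estimates the
artifact map and the restored image is input − prediction. Artifacts of
angular undersampling are structurally simpler than anatomy, which makes
the residual easier to learn than the clean image.

* **MWCNN** (default): encoder of CNN blocks (four 3×3 conv + BN + ReLU
  layers each) separated by channel-stacked DWTs; a bottleneck block; a
  decoder of stacked IWTs, element-sum skip connections with the matching
  encoder feature, and CNN blocks; a bare (no BN/ReLU) output conv. With
  3 levels and 4-conv blocks the total conv count is
  2 + 4·(2·3+1) = 30 — input lift, 12 encoder, 4 bottleneck, 12 decoder,
  output — asserted at build time.
* **U-Net ablation**: identical block topology with 2×2 max-pooling down
  and 2×2 transposed-convolution up (transposed convs are upsamplers and
  not counted as conv layers, keeping the conv budget equal).
* **WCNN ablation**: a single one-level DWT front end and a plain
  convolutional trunk at that one (half) resolution, trunk depth chosen
  so the total conv count matches the other two.

The output conv of every residual branch is zero-initialised, so a fresh
model is exactly the identity map and the untrained dual pipeline
coincides with the Linear+FBP baseline; training can only improve on it.
3×3 convs use one-pixel reflective padding (avoids border artifacts in
restoration); inputs whose spatial dims are not divisible by 2^levels are
reflectively padded and the residual cropped back (e.g. 90 views → 96).

The networks run on a small reverse-mode autodiff engine written on
numpy (`sparsect.autodiff`): convolution as nine offset-slice batched
matmuls, batch normalization with running statistics, and the wavelet /
FBP operators with their analytic adjoints as backward passes. Adam
follows the training recipe below.

## Dual-domain training

Inputs are (sparse sinogram, full sinogram, reference image) triplets.
Sinograms are min-max normalized per dataset (not per sample) so batch
normalization sees a fixed physical scale; the FBP bridge un-normalizes.
The joint loss is L_total = L_radon + L_image with both terms
(1/2N) Σ‖·‖²: L_radon compares the RDNet-completed sinogram with the true
full-view sinogram; L_image compares the IDNet-restored image with the
image-domain target. Gradients of L_image reach RDNet through the FBP
bridge, so both networks train in the same cycle.

The image-domain target defaults to the *reference image*. The strict
alternative — the FBP of the true full-view sinogram — is available
(`image_target="fbp_full"` in `train_dual`, and it is the default of the
standalone `joint_loss`): in the dense-view limit the two coincide, but
at desk scale (64², 90 full views) the full-view FBP is itself
artifact-limited (≈ 26 dB) and would cap what the model can learn.

Optimization: Adam with α = 1e-4, β₁ = 0.9, β₂ = 0.999, mini-batch 4,
learning rate ×0.9 every 20 epochs. One master seed derives the
parameter-init and shuffling streams; training is bit-reproducible.
Measured views are *not* re-imposed on the RDNet output by default
(`data_consistency=True` in `reconstruct_dual` enables the hard
projection).

RDNet is residual like IDNet: it predicts the error of the linearly
interpolated sinogram rather than the completed sinogram itself, which
both matches the residual framing of the image network and gives the
exact Linear+FBP starting point described above.

## Classical baselines

SART uses simultaneous all-view updates with ray- and pixel-weight
normalization from the same system matrix, relaxation 1.5, optional
non-negativity. SART-TV alternates one SART pass with 20 steepest-descent
steps on isotropic TV (ε = 1e-8 smoothing); the *total* TV displacement
per outer iteration is 0.2× the data-update magnitude, split evenly over
the descent steps — a fixed-schedule variant of the ASD-POCS alternation
(the fully adaptive parameter schedule is deliberately not replicated;
a fixed schedule suffices for a baseline). Defaults (100 outer
iterations) were frozen from a sweep that maximised the baseline's own
PSNR on held-out phantoms, i.e. tuned in the baseline's favour.

## Metrics

PSNR = 10 log₁₀(MAX²/MSE) with MAX defaulting to 1.0 for [0, 1] images
(255 configurable). SSIM multiplies luminance, contrast and structure
terms with exponents 1; the windowed default follows the community
protocol (11×11 Gaussian window, σ = 1.5, C1 = (0.01 L)², C2 = (0.03 L)²,
C3 = C2/2, mean-pooled, half-window border cropped). A "global"
single-window mode evaluates the raw formula once, which is what the
algebraic tests exercise. Windowed values are cross-checked against
scikit-image's implementation in the test suite.

## Synthetic data: what it does and does not show

The random-ellipse phantoms emulate overlapping soft-tissue densities:
5–12 anti-aliased ellipses (4×4 area-fraction supersampling — hard edges
would add gridding artifacts unrelated to angular undersampling), summed
intensities clipped to [0, 1], support inside the inscribed circle,
fully seed-deterministic. They share with real CT slices the piecewise-
smooth structure and the streak statistics of sparse-view FBP, but have
no anatomical texture, no noise model (projections are noiseless by
design), and no 3D context. Passing tests therefore demonstrate the
correctness of the operators and the direction and ordering of the
method comparisons — not clinical-scale image quality.

## Desk-scale study conditions

Defaults used by the training-based tests: 64² phantoms, 90 full views,
subsampling factor 6 (15 measured views), channel widths (8, 16, 32),
batch 4. The main comparison trains 20 epochs on 100 phantoms and
evaluates on 20 held-out phantoms; the architecture comparison trains
8 epochs on 48 phantoms for each of the three dual variants and the
image-domain-only baseline, with two seeds. Channel widths are
config-exposed; wider settings (e.g. 64/128/256 at 512²/360 views) are
available but are multi-hour CPU jobs.

## Known limitations

* At 15 views on piecewise-constant phantoms, SART-TV is an unusually
  strong baseline (~30 dB): TV is exactly the right prior for this image
  class. The desk-scale trained dual model (~24 dB after 500 optimizer
  steps) clearly beats FBP and Linear+FBP but does not overtake SART-TV;
  at dense-training scale on natural images the expected ordering
  reverses, which this package does not attempt to demonstrate.
* At 64², 120 uniform views already exceed the angular Nyquist rate, so
  dense-view FBP improves only marginally between 120 and 360 views.
* The numpy engine is single-threaded and CPU-bound; it exists for exact
  adjoints and reproducibility, not throughput.
* DICOM input is min-max normalized per slice; this is a pragmatic
  stand-in, not a validated HU calibration.
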