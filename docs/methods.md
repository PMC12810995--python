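# Methods

`needletrack` models a specific interventional-MRI measurement problem:
during an in-bore transrectal prostate biopsy, a plastic needle guide is
advanced under dynamic 2D balanced-SSFP imaging, and the guide's tip must
be localized in every frame even when the acquisition is heavily
undersampled to reach real-time frame rates. The package implements the
full measurement chain — k-space undersampling, learned dynamic
reconstruction, segmentation, principal-axis tip localization, and
feasibility statistics — driven by a synthetic dynamic phantom that
stands in for clinical raw data, which are not publicly available.

## Synthetic dynamic phantom

One sample mimics one tracking acquisition: a fully sampled pre-movement
scan, `n_frames` dynamic multi-coil k-space frames during which the guide
moves, and a fully sampled post-movement scan, with complete ground truth
(per-frame tip positions and rasterized guide masks).

**Anatomy.** The background is procedural: a bright body ellipse
(signal ≈ 0.75 of unit scale) containing a central "prostate" ellipse and
two lateral structures, modulated by a smooth Gaussian-filtered random
texture field (amplitude 0.12, correlation length 12 mm by default) and a
smooth random phase map; the exterior is zero-signal air. This is
deliberately not an anatomically realistic pelvis — the tracking task
needs only guide/background contrast and realistic noise statistics.

**Needle guide.** A cylinder of radius `guide_radius_mm` (default 3 mm;
the physical radius is a free parameter of the simulation) rendered as a
signal void: intensities inside the rasterized rod are multiplied by
`1 − guide_contrast` (default 0.15 remaining signal), matching the dark
appearance of the plastic guide on bSSFP. Rasterization includes every
pixel whose centre lies within one radius of the base–tip segment (a
disc-swept capsule, the same rule used to convert line annotations to
masks). Because the capsule extends one radius beyond each segment
endpoint, the phantom renders the rod over a radius-shrunk segment so
that the **visible apex of the void coincides exactly with the stored
ground-truth tip**; without this, any tip estimator reading the mask
extremity would be biased by one radius.

**Motion.** Strictly in-plane and linear: the tip sits at `tip_start`
for frames up to the annotated window start, at `tip_end` from the window
end onward, and interpolates linearly in between. The evaluation's
reference trajectory makes the same linearity assumption, so ground
truth and evaluation model coincide by construction.

**Coils and noise.** Coil sensitivities are broad Gaussian bumps centred
outside the field of view with mild linear phase, normalized so their
root sum of squares is exactly 1 at every pixel (RSS combination then
preserves magnitudes). Noise is i.i.d. complex Gaussian added in
k-space; with orthonormal transforms the image-domain noise level equals
`noise_sigma`, and magnitude images are Rician (Rayleigh at zero-signal
pixels — a property the test suite verifies by a Kolmogorov–Smirnov
test).

**Scale.** The default geometry matches the clinical protocol (256×256
grid, 1.094 mm spacing = 280 mm FOV / 256, 60 frames, 4 coils).
`PhantomConfig.desk()` is the 64-pixel configuration with proportionally
scaled guide geometry (length 22 mm, radius 2.2 mm, aspect 5:1) used by
the tests and example experiments. Pre/post scans are single-slice: all
tracking is 2D on the central slice, so the clinical 5-slice stack is
collapsed.

## Undersampling model

Cartesian acquisition with the phase-encoding direction along the stored
row axis; the frequency axis is always fully sampled. A sampling mask
retains one contiguous central block of `floor(n_phase / R)` lines — the
autocalibration (ACS) block of a GRAPPA-factor-R scan, which is the only
part of k-space the pipeline uses (no GRAPPA unaliasing is performed;
zero-filling the rest *is* the acquisition model). The block is centred
on the zero-frequency line: odd counts sit symmetrically, even counts
put the extra line on the lower-index side. Higher accelerations are
obtained by zeroing outer ACS lines symmetrically (e.g. 8 lines per edge
from 8× to 16× on a 256-line grid); escalation is algebraically
identical to building the fresh mask at the higher factor. Fourier
transforms are orthonormal and centred throughout, which makes
Parseval-based checks exact.

## Reconstruction network

A convolutional recurrent network unrolled over solver iterations, with
hidden states carried across both iterations and the frames of a
sliding temporal window (length 5, replicate-padded at sequence edges;
each output frame is the centre-frame result of its own window). Each
iteration applies one bidirectional time-recurrent unit (shared weights
for both directions, summed), three iteration-recurrent units, and one
output convolution (kernel 3 everywhere), adds the result to the current
estimate, and applies **hard data consistency**: the estimate's k-space
is overwritten with the measured values on every acquired line. Hard
(noiseless-limit) consistency was chosen because no noise-weighting
parameter is part of the protocol. Consequences used by the tests: at
R=1 the output equals the fully sampled RSS image regardless of weights,
and a zero-weight network is exactly the zero-filled reconstruction (the
output convolution is zero-initialized, so training starts from that
baseline).

Coil handling: the network operates on a single complex (2-channel)
coil-combined image. Single-coil data use plain virtual-coil
consistency; multi-coil data are configuration-gated and require the
coil sensitivities, with consistency applied per coil through the maps
(`F(S_c z)` overwritten on acquired lines, recombined with the conjugate
maps — an affine self-adjoint projection).

**Training.** Inputs are fully sampled magnitude sequences scaled to
[0, 1]; undersampling is synthesized on the fly at `train_R` (default
8×). Augmentation: random horizontal/vertical flips, rotations by
multiples of 90°, and Rician noise (complex Gaussian of σ ~ 0.02 added
before the magnitude). The loss is `1 − mean SSIM` between reconstructed
magnitude and target over all window frames; Adam (lr 2·10⁻³, batch 5
sequences), deterministic for a fixed seed. The loss SSIM uses the same
11-tap Gaussian window as the metric (below), evaluated on the interior
where the window fits.

The full-scale configuration (10 iterations, 128 filters) is retained as
a named preset; the `desk` configuration (2 iterations, 16 filters,
64-pixel frames) trains in about five minutes on one CPU and is the one
exercised end-to-end (50 epochs on 20 sequences in the learning study).

Because no deep-learning framework is part of the dependency set, the
networks run on a small numpy reverse-mode autodiff engine
(`needletrack.nn`): float32 channels-last tensors, convolution as
shifted GEMMs with BLAS in-place accumulation, differentiable
data-consistency layers with analytic adjoints (the projection is
self-adjoint), and Adam. Gradients are validated in the test suite
against float64 analytic references and finite differences. Training
raises glibc's mmap/trim thresholds (`mallopt`) so multi-megabyte
buffers are recycled by the allocator rather than returned to the kernel
on every free.

## SSIM

Structural similarity with the standard constants: 11×11 Gaussian window
(σ = 1.5), K₁ = 0.01, K₂ = 0.03, dynamic range 1.0 (intensities are
scaled to [0, 1] per sequence — global, not per frame, to preserve
temporal intensity dynamics). Local statistics use the population
covariance convention, and the mean is taken over the interior region
where the window fits entirely; under these conventions the
implementation agrees with `skimage.metrics.structural_similarity`
(gaussian weights, no sample covariance) to float precision, which the
tests use as an independent oracle.

## Segmentation

A fixed small 2D U-Net stands in for a self-configuring framework: the
self-configuration machinery is external tooling, while the pipeline
only needs the images→mask interface. Default: depth 3, 8 base filters
doubling per level, two 3×3 convolutions per level, 2× average pooling,
nearest-neighbour upsampling with skip concatenation, sigmoid head.
Loss is soft Dice plus foreground-weighted cross-entropy (weight 8): the
guide occupies ~2% of a frame and the unweighted loss has an
all-background local optimum that early training can collapse into.
Adam, lr 5·10⁻³, 60 epochs by default; deterministic per seed.
Inference thresholds the probability map at 0.5; largest-connected-
component filtering exists as a flag, off by default on the bare
operation. The training corpus mixes fully sampled frames with
zero-filled reconstructions at 8–16× so the segmenter tolerates
phase-direction blur, and every frame offered to the segmenter —
in the corpus and in the tracking pipeline — is min-max normalized
per frame: sequence-level scaling is kept for the reconstruction
model's temporal dynamics, but the segmenter sees single frames whose
dynamic range varies with acceleration, and matching the train/test
intensity distribution matters more there. The 80/20 split helper is
grouped by subject: all scans of one synthetic subject land on one
side.

In the tracking experiment the largest-component flag is enabled by
default: a handful of stray foreground pixels on dark anatomy is enough
to rotate the principal axis and flip the tip to the wrong end of the
guide (observed as reference tips ~18 mm off ground truth; with the
filter they sit within half a pixel). The bare segmentation operation
keeps the flag off so mask quality can be assessed unfiltered.

## Tip localization and reference trajectory

The tip estimator computes the centroid and 2×2 coordinate covariance of
the foreground pixels, takes the principal eigenvector as the guide
axis, forms the axis endpoints from the extreme scalar projections of
the foreground pixels (robust to ragged mask edges, unlike a bounding
box), and returns the endpoint closer to the image centre — the guide
always enters from the periphery, which also resolves the eigenvector
sign ambiguity without an orientation convention. Empty or isotropic
masks (eigenvalue gap < 10⁻⁹) yield an *invalid* estimate whose error is
+∞, so a dropout frame scores as a failure rather than aborting the
sample. Coordinates are 0-based pixel indices with the pixel centre at
`(i + 0.5)·spacing` mm and the image centre at `grid·spacing/2`.

The reference trajectory interpolates linearly between the PCA tips of
the pre- and post-movement segmentations across the annotated motion
window and is constant outside it. Frame exclusion is an input
annotation, not auto-detected.

## Statistics

Per frame, the instrument-tip-prediction (ITP) error is the Euclidean
distance in mm to the reference; a 5 mm threshold defines success
(strict: exactly 5 mm is a failure). Per sample, the success rate is
the proportion of non-excluded successful frames. Summaries per
acceleration level report the mean and sample (n−1) standard deviation
of per-sample rates plus a 95% Wilson score interval; the Wilson
operation is generic in (k, n), and the tabular report pools
non-excluded frames across samples at each level — one defensible
reading, recorded as such, since the clinical bounds are not
reproducible from any obvious (k, n) choice. The independent
segmentation validation uses a one-sided one-sample t-test of the mean
error against 5 mm (zero-variance samples are flagged with the sign of
the offset instead of producing a 0/0 statistic), a t-based confidence
interval, and a gamma fit by moment matching: with adjusted
Fisher–Pearson sample skewness g, shape α = 4/g² and scale θ = x̄/α
(the estimator is unspecified in the underlying protocol; the
bias-corrected form is the standard choice).

## What the phantom does and does not show

Passing tests on the phantom demonstrate the pipeline's internal
consistency: exact protocol arithmetic, correct mask algebra, a
reconstruction network that provably respects measured data and
measurably improves SSIM over zero-filling, a segmenter that finds a
dark rod under phase blur, and a tip estimator that is exact against
brute-force PCA and recovers ground truth to sub-pixel accuracy. They
do **not** establish clinical performance: the phantom has no
through-plane motion, no banding or eddy-current artifacts, no
anatomical variability between subjects, linear (not hesitant or
curved) instrument motion, and known coil maps. Clinical success-rate
tables are therefore outside what the synthetic benchmark can or does
claim; the package reproduces the qualitative ordering (learned
reconstruction remains viable at accelerations where zero-filling has
collapsed) rather than clinical percentages.

## Numerical choices and problem sizes

- Orthonormal FFTs; the user-facing k-space module is double precision
  (bit-exact data-consistency and mask tests); the network's internal
  consistency layers use single-precision FFTs (round-off ~10⁻⁷,
  checked to stay within the 10⁻⁶-relative full-sampling contract).
- Degenerate rules: constant sequences scale to all zeros; empty masks
  give invalid (not raising) tip estimates; a sub-pixel-radius point
  rasterization warns and returns an empty mask.
- Endpoint ties (both axis endpoints equidistant from the image centre)
  are broken toward the minimum-projection endpoint; the oracle tests
  accept either in the exact-tie case.
- Test and example sizes: 64-pixel phantoms, 60-frame samples, 20
  training sequences × 50 epochs for the reconstruction study, 64
  mixed frames × 60 epochs for the segmenter; the whole suite runs on
  one CPU in well under half an hour. The paper-scale preset (256 px,
  10 iterations, 128 filters) is functional but sized for offline use.
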