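# needletrack

Needle-guide tip tracking in accelerated dynamic MRI.

In-bore MR-guided prostate biopsy confirms the needle guide's position
with repeated 2D bSSFP scans, which makes the procedure slow. Faster
imaging requires undersampling k-space — here, retaining only the
central autocalibration (ACS) block of a Cartesian acquisition — and a
reconstruction that keeps the instrument localizable at high
acceleration. `needletrack` implements that measurement chain as a
tested Python package for researchers studying real-time instrument
tracking: a synthetic dynamic phantom (pre-movement scan, 60 dynamic
multi-coil frames with a moving guide, post-movement scan, full ground
truth), Cartesian undersampling and zero-filled reconstruction, a
temporally recurrent reconstruction network with hard data consistency,
a U-Net guide segmenter, PCA tip localization, and the tracking
statistics.

The core quantities, in the field's notation:

- **Undersampling.** At acceleration R, a mask retains the
  ⌊N/R⌋ central phase-encoding lines of an N-line grid (32 ACS lines at
  8× for N = 256); higher R zeroes outer ACS lines symmetrically.
- **Reconstruction.** An unrolled recurrent network x⁽ⁱ⁾ =
  DC(x⁽ⁱ⁻¹⁾ + f(x⁽ⁱ⁻¹⁾, h)), where h are hidden states recurrent over
  iterations and over a 5-frame sliding window, and DC overwrites
  predicted k-space with the measured values on every acquired line.
  Training minimizes 1 − SSIM (11×11 Gaussian window, σ = 1.5,
  K₁ = 0.01, K₂ = 0.03) against the fully sampled target.
- **Tip localization.** PCA of the segmentation mask: centroid c,
  principal eigenvector v of the coordinate covariance, axis endpoints
  c + t·v at the extreme projections t of the mask pixels; the tip is
  the endpoint nearer the image centre.
- **Evaluation.** Per-frame instrument-tip-prediction (ITP) error is
  the Euclidean distance in mm to a reference trajectory interpolated
  linearly between the pre- and post-movement tips across the annotated
  motion window; success means error < 5 mm. Success rates are
  summarized with mean ± SD and 95% Wilson score intervals; the
  independent segmentation validation uses a one-sided t-test against
  5 mm and a Gamma(α, θ) moment fit with α = 4/γ², θ = x̄/α.

The neural networks run on a small self-contained numpy autograd engine
(`needletrack.nn`), so the package has no deep-learning-framework
dependency; the desk-scale configuration (2 iterations, 16 filters,
64-pixel frames) trains in minutes on one CPU.

## Worked example

```python
import numpy as np
from needletrack import (PhantomConfig, generate_sample, ExperimentConfig,
                         run_tracking_experiment, summarize_experiment,
                         make_central_mask, escalate_mask)

# protocol arithmetic: ACS lines on the 256-line grid
print([make_central_mask(256, R).n_retained for R in (8, 10, 12, 16, 25)])

# a noiseless 64-pixel dynamic sample with ground truth
sample = generate_sample(PhantomConfig.desk(rng_seed=3))

# oracle segmentation isolates the tracking geometry from model quality
results = run_tracking_experiment(
    sample, ExperimentConfig(methods=("zero_filled",)),
    oracle_segmentation=True)
print(summarize_experiment(results)[["R", "n_klines", "mean_success_rate"]]
      .to_string(index=False))
errs = np.concatenate([r.errors_mm for r in results])
print(f"max ITP error: {errs.max():.3f} mm ({errs.max()/sample.spacing:.2f} px)")
```

prints

```
[32, 25, 21, 16, 10]
 R  n_klines  mean_success_rate
 8         8                1.0
10         6                1.0
12         5                1.0
14         4                1.0
16         4                1.0
18         3                1.0
20         3                1.0
25         2                1.0
max ITP error: 0.876 mm (0.80 px)
```

i.e. with ground-truth masks the PCA tip stays within one pixel of the
linear reference on every frame at every acceleration — the geometric
accuracy ceiling of the pipeline. Replacing the oracle with the trained
segmenter and reconstructions (`train_model`, `train_segmenter`) exposes
the actual degradation with R; the zero-filled baseline collapses at
moderate acceleration while the recurrent reconstruction keeps tracking
viable longer.

A command-line surface wraps the same steps:

```sh
needletrack simulate --out sample.h5 --seed 1
needletrack train-recon --out recon.npz --seed 0
needletrack train-seg --out seg.npz --seed 0
needletrack track sample.h5 --out track.csv \
    --recon-checkpoint recon.npz --seg-checkpoint seg.npz
needletrack report track.csv --out-dir report/
```

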