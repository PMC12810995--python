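"""End-to-end tracking experiment driver.

Ties the phantom generator, undersampling engine, reconstruction,
segmentation, tip localization and statistics together: for each
acceleration level and reconstruction method, the dynamic frames are
masked, reconstructed, segmented and localized, and per-frame tip errors
against the interpolated reference trajectory are collected.  Oracle
switches substitute ground-truth masks (isolating reconstruction
quality) or fully sampled reconstructions (isolating segmentation
quality), mirroring the independent-evaluation logic of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import (SUCCESS_THRESHOLD_MM, FrameResult, TrackingResult)
from .kspace import (centered_ifft2, escalate_mask, make_central_mask,
                     rss_combine, scale_intensities, zero_fill_reconstruct)
from .phantom import DynamicSample, PhantomConfig, generate_sample
from .recon import CRNNModel, reconstruct_sequence
from .segmentation import UNet, segment
from .tracking import itp_error, pca_tip, reference_trajectory

__all__ = ["ExperimentConfig", "run_tracking_experiment", "training_corpus",
           "segmentation_corpus", "DEFAULT_LADDER"]

DEFAULT_LADDER = (8, 10, 12, 14, 16, 18, 20, 25)


@dataclass(frozen=True)
class ExperimentConfig:
    """Acceleration ladder, methods and threshold of one experiment."""

    ladder: tuple = DEFAULT_LADDER
    methods: tuple = ("zero_filled", "crnn")
    success_threshold_mm: float = SUCCESS_THRESHOLD_MM
    largest_component: bool = True  # strays on dark anatomy wreck the PCA axis

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.ladder, self.ladder[1:])):
            raise ValueError("acceleration ladder must be strictly increasing")
        if self.success_threshold_mm <= 0:
            raise ValueError("success threshold must be positive")
        unknown = set(self.methods) - {"zero_filled", "crnn", "oracle"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _full_rss(kspace: np.ndarray) -> np.ndarray:
    """Fully sampled reconstruction: per-coil inverse FFT, then RSS."""
    return rss_combine(centered_ifft2(kspace))


def _norm_frame(image: np.ndarray) -> np.ndarray:
    """Per-frame min-max normalization applied before segmentation.

    Sequence-level scaling preserves temporal dynamics for the
    reconstruction model, but the segmenter sees single frames whose
    dynamic range varies with acceleration; normalizing each frame makes
    train and test intensity distributions match.
    """
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def run_tracking_experiment(sample: DynamicSample, cfg: ExperimentConfig,
                            recon_model: CRNNModel | None = None,
                            seg_model: UNet | None = None,
                            oracle_segmentation: bool = False,
                            oracle_reconstruction: bool = False,
                            ) -> list[TrackingResult]:
    """Track the needle guide in one sample at every ladder level.

    The pre- and post-movement scans are always reconstructed fully
    sampled (inverse FFT + RSS); their segmentations define the reference
    trajectory endpoints.  Per-frame failures (empty or degenerate
    segmentations) are recorded as infinite-error frames, never aborting
    the sample.
    """
    if not oracle_segmentation and seg_model is None:
        raise ValueError("need a segmentation model or oracle_segmentation")
    if "crnn" in cfg.methods and recon_model is None and not oracle_reconstruction:
        raise ValueError("method 'crnn' needs a trained reconstruction model")

    n = sample.grid_size
    spacing = sample.spacing

    # reference trajectory from the fully sampled pre/post scans
    if oracle_segmentation:
        pre_mask_seg = sample.truth_masks[0]
        post_mask_seg = sample.truth_masks[-1]
    else:
        lcc = cfg.largest_component
        pre_mask_seg = segment(_norm_frame(_full_rss(sample.pre_kspace)),
                               seg_model, largest_component=lcc)
        post_mask_seg = segment(_norm_frame(_full_rss(sample.post_kspace)),
                                seg_model, largest_component=lcc)
    pre_tip = pca_tip(pre_mask_seg, spacing)
    post_tip = pca_tip(post_mask_seg, spacing)
    if not (pre_tip.valid and post_tip.valid):
        raise ValueError("pre/post segmentation did not yield a valid tip; "
                         "cannot build a reference trajectory")
    reference = reference_trajectory(pre_tip.tip_mm, post_tip.tip_mm,
                                     sample.move_window, sample.n_frames)

    base_mask = make_central_mask(n, cfg.ladder[0])
    results: list[TrackingResult] = []
    for R in cfg.ladder:
        mask = escalate_mask(base_mask, R)
        for method in cfg.methods:
            if oracle_reconstruction or method == "oracle":
                frames = np.stack([_full_rss(k) for k in sample.dyn_kspace])
            elif method == "zero_filled":
                frames = np.stack([zero_fill_reconstruct(k, mask)
                                   for k in sample.dyn_kspace])
            else:  # crnn
                sens = sample.coil_sens if sample.dyn_kspace.shape[1] > 1 else None
                frames = reconstruct_sequence(sample.dyn_kspace, mask,
                                              recon_model, sens=sens)
            frames = scale_intensities(frames)
            frame_results = []
            for f in range(sample.n_frames):
                excluded = f in sample.excluded_frames
                if oracle_segmentation:
                    seg_mask = sample.truth_masks[f]
                else:
                    seg_mask = segment(_norm_frame(frames[f]), seg_model,
                                       largest_component=cfg.largest_component)
                tip = pca_tip(seg_mask, spacing)
                err = itp_error(tip, reference[f])
                frame_results.append(FrameResult(
                    frame_index=f, error_mm=err,
                    success=(not excluded) and err < cfg.success_threshold_mm,
                    excluded=excluded))
            results.append(TrackingResult(
                sample_id=sample.sample_id, R=R, method=method,
                frames=frame_results, n_klines=mask.n_retained,
                move_window=sample.move_window))
    return results


# ---------------------------------------------------------------------------
# Synthetic training corpora
# ---------------------------------------------------------------------------

def training_corpus(base_cfg: PhantomConfig, n_sequences: int,
                    window_length: int = 5, seed: int = 0,
                    motion_mm: tuple[float, float] = (6.0, 14.0),
                    ) -> list[np.ndarray]:
    """Fully sampled magnitude sequences for reconstruction training.

    Each sequence is a short dynamic sample (``window_length`` frames)
    with randomized background texture, guide pose and linear motion,
    rendered noiseless, reconstructed by RSS and scaled to [0, 1].
    """
    rng = np.random.default_rng(seed)
    fov = base_cfg.fov_mm
    seqs = []
    for _ in range(n_sequences):
        theta = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        tip_start = fov * (0.5 + rng.uniform(-0.08, 0.08, size=2))
        tip_end = tip_start + rng.uniform(*motion_mm) * u
        cfg = replace(base_cfg, n_frames=window_length,
                      move_window=(0, window_length - 1),
                      tip_start=tuple(tip_start), tip_end=tuple(tip_end),
                      rng_seed=int(rng.integers(2 ** 31)))
        sample = generate_sample(cfg)
        imgs = np.stack([_full_rss(k) for k in sample.dyn_kspace])
        seqs.append(scale_intensities(imgs))
    return seqs


def segmentation_corpus(base_cfg: PhantomConfig, n_samples: int = 12,
                        frames_per_sample: int = 8, seed: int = 0,
                        degrade_R: tuple = (8, 12, 16),
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Paired images and truth masks for segmentation training.

    Mixes fully sampled frames with zero-filled reconstructions at the
    listed accelerations so the segmenter tolerates the phase-direction
    blur it will see on undersampled reconstructions.
    """
    rng = np.random.default_rng(seed)
    fov = base_cfg.fov_mm
    images, masks = [], []
    for _ in range(n_samples):
        theta = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        tip_start = fov * (0.5 + rng.uniform(-0.08, 0.08, size=2))
        tip_end = tip_start + rng.uniform(6.0, 14.0) * u
        cfg = replace(base_cfg, n_frames=frames_per_sample,
                      move_window=(1, frames_per_sample - 2),
                      tip_start=tuple(tip_start), tip_end=tuple(tip_end),
                      rng_seed=int(rng.integers(2 ** 31)))
        sample = generate_sample(cfg)
        recon_modes = [None] + list(degrade_R)
        for f in range(frames_per_sample):
            mode = recon_modes[f % len(recon_modes)]
            if mode is None:
                img = _full_rss(sample.dyn_kspace[f])
            else:
                mask = make_central_mask(cfg.grid_size, mode)
                img = zero_fill_reconstruct(sample.dyn_kspace[f], mask)
            images.append(_norm_frame(img))
            masks.append(sample.truth_masks[f])
    return np.stack(images), np.stack(masks)
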