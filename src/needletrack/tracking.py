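"""Instrument-tip localization from segmentation masks.

The needle guide appears as an elongated region in each segmentation
mask.  Its main axis is the principal eigenvector of the covariance of
the foreground pixel coordinates; the tip is the axis endpoint closest to
the image centre (the guide always enters from the periphery).  A
reference trajectory is built by linearly interpolating the tip between
the pre- and post-movement positions across the annotated motion window.

Coordinates: 0-based (row, col) pixel indices; a pixel's centre in mm is
``(i + 0.5) * spacing``; the image centre in pixel coordinates is
``grid_size / 2 - 0.5``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = ["TipEstimate", "ReferenceTrajectory", "pca_tip",
           "reference_trajectory", "itp_error"]


@dataclass(frozen=True)
class TipEstimate:
    """Continuous in-plane tip position with principal-axis metadata.

    ``valid`` is False for empty or isotropic masks; such frames score as
    tracking failures downstream rather than raising.
    """

    tip_px: tuple[float, float] | None
    tip_mm: tuple[float, float] | None
    axis_unit_vector: tuple[float, float] | None
    eigenvalue_ratio: float
    valid: bool

    @classmethod
    def invalid(cls) -> "TipEstimate":
        return cls(None, None, None, float("nan"), False)


def pca_tip(mask: np.ndarray, spacing: float,
            image_center: tuple[float, float] | None = None) -> TipEstimate:
    """Estimate the guide tip from a binary mask by principal-axis analysis.

    The centroid and 2x2 covariance of the foreground pixel coordinates
    are computed; the principal eigenvector gives the guide axis.  The
    axis endpoints are the extreme scalar projections of the foreground
    pixels onto that axis, and the tip is the endpoint nearer
    ``image_center`` (pixel coordinates; defaults to the grid centre
    ``n/2 - 0.5``).  Empty masks and masks with (near-)equal eigenvalues
    yield an invalid estimate.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] < 2:
        return TipEstimate.invalid()
    if image_center is None:
        image_center = (mask.shape[0] / 2 - 0.5, mask.shape[1] / 2 - 0.5)
    center = np.asarray(image_center, dtype=float)

    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / (coords.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(eigvals[0]), float(eigvals[1])
    if lam1 - lam2 < 1e-9:
        return TipEstimate.invalid()
    axis = eigvecs[:, 1]

    t = centered @ axis
    endpoints = np.stack([centroid + t.min() * axis, centroid + t.max() * axis])
    dists = np.linalg.norm(endpoints - center, axis=1)
    tip = endpoints[int(np.argmin(dists))]
    ratio = lam1 / lam2 if lam2 > 0 else float("inf")
    tip_mm = tuple((tip + 0.5) * spacing)
    return TipEstimate(tip_px=tuple(tip), tip_mm=tip_mm,
                       axis_unit_vector=tuple(axis),
                       eigenvalue_ratio=ratio, valid=True)


@dataclass(frozen=True)
class ReferenceTrajectory:
    """Per-frame reference tip positions (mm), constant outside the window."""

    tips_mm: np.ndarray  # (n_frames, 2)
    move_window: tuple[int, int]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.tips_mm[frame]


def reference_trajectory(pre_tip_mm, post_tip_mm, move_window: tuple[int, int],
                         n_frames: int) -> ReferenceTrajectory:
    """Linear interpolation of the tip across the annotated motion window.

    Frames before the window start take the pre-movement tip, frames
    after the window end take the post-movement tip, and intermediate
    frames interpolate linearly in the frame index.
    """
    lo, hi = move_window
    if not (0 <= lo <= hi < n_frames):
        raise ValueError(f"move_window {move_window} invalid for "
                         f"{n_frames} frames")
    pre = np.asarray(pre_tip_mm, dtype=float)
    post = np.asarray(post_tip_mm, dtype=float)
    frames = np.arange(n_frames)
    if hi == lo:
        alpha = (frames >= lo).astype(float)
    else:
        alpha = np.clip((frames - lo) / (hi - lo), 0.0, 1.0)
    tips = pre[None, :] + alpha[:, None] * (post - pre)[None, :]
    return ReferenceTrajectory(tips_mm=tips, move_window=(lo, hi))


def itp_error(pred: TipEstimate, ref_mm, spacing: float | None = None) -> float:
    """Instrument-tip-prediction error: Euclidean distance in mm.

    An invalid estimate maps to ``+inf`` so the frame is guaranteed to
    score as a failure against any finite threshold.
    """
    if not pred.valid:
        return float("inf")
    ref = np.asarray(ref_mm, dtype=float)
    return float(np.hypot(*(np.asarray(pred.tip_mm) - ref)))


def save_tip_table_csv(rows: list[dict], path) -> None:
    """Per-frame tip table: frame, predicted and reference mm, error, success."""
    fields = ["frame", "pred_row_mm", "pred_col_mm", "ref_row_mm",
              "ref_col_mm", "error_mm", "success"]
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
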