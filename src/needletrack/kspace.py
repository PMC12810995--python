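"""Cartesian k-space machinery for accelerated dynamic MRI.

Centered orthonormal Fourier transforms, central-ACS-line sampling masks,
acceleration escalation, zero-filled reconstruction, root-sum-of-squares
coil combination, intensity scaling, and acquisition-protocol arithmetic.

Conventions
-----------
* Grids are indexed ``[row, col]``; the phase-encoding direction is the
  row axis (axis ``-2``).  The frequency-encoding (column) axis is always
  fully sampled, as in Cartesian parallel-imaging acquisitions.
* Fourier transforms are orthonormal (``norm="ortho"``) and centered: the
  zero-frequency line sits at index ``n // 2``.
* A :class:`SamplingMask` retains one contiguous central block of phase
  lines — the autocalibration (ACS) block of a GRAPPA-style acquisition.
  Retaining only the ACS block of an R-fold accelerated scan and
  zero-filling the rest is the undersampling model used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "ProtocolParams",
    "centered_fft2",
    "centered_ifft2",
    "make_central_mask",
    "escalate_mask",
    "apply_mask",
    "rss_combine",
    "zero_fill_reconstruct",
    "scale_intensities",
    "effective_undersampling",
    "scan_time",
]


# ---------------------------------------------------------------------------
# Fourier transforms
# ---------------------------------------------------------------------------

def centered_fft2(image: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2D FFT over the trailing two axes.

    The zero-frequency component lands at index ``(n//2, n//2)``.  With the
    orthonormal scaling, Parseval's identity holds exactly and
    :func:`centered_ifft2` is the exact inverse.
    """
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(image, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def centered_ifft2(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`centered_fft2`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(kspace, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


# ---------------------------------------------------------------------------
# Sampling masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingMask:
    """Per-phase-line retention pattern with nominal acceleration ``R``.

    Attributes
    ----------
    n_phase:
        Total number of phase-encoding lines.
    retained:
        Boolean array of length ``n_phase``; ``True`` lines are acquired.
        Retained lines always form one contiguous central block.
    nominal_R:
        The acceleration factor the mask was built for.
    """

    n_phase: int
    retained: np.ndarray
    nominal_R: float

    def __post_init__(self) -> None:
        retained = np.asarray(self.retained, dtype=bool)
        object.__setattr__(self, "retained", retained)
        if retained.shape != (self.n_phase,):
            raise ValueError("retained must have length n_phase")
        n = int(retained.sum())
        if n < 1:
            raise ValueError("a sampling mask must retain at least one line")
        idx = np.flatnonzero(retained)
        if idx[-1] - idx[0] + 1 != n:
            raise ValueError("retained lines must form one contiguous block")

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    def to_json(self) -> str:
        """Serialize as a JSON index list for bit-exact exchange."""
        return json.dumps(
            {
                "n_phase": self.n_phase,
                "nominal_R": self.nominal_R,
                "retained_indices": self.retained_indices.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SamplingMask":
        obj = json.loads(text)
        retained = np.zeros(obj["n_phase"], dtype=bool)
        retained[obj["retained_indices"]] = True
        return cls(obj["n_phase"], retained, obj["nominal_R"])


def make_central_mask(n_phase: int, R: float) -> SamplingMask:
    """Central ACS-block mask retaining ``floor(n_phase / R)`` lines.

    The block is centered on the zero-frequency line (index ``n_phase//2``):
    an odd retained count sits symmetrically around it, an even count puts
    the extra line on the lower-index side.  The floor rule reproduces the
    line counts of the acquisition protocol for every acceleration used
    here (e.g. 256 lines at 8x -> 32, at 10x -> 25, at 12x -> 21).
    """
    if R < 1:
        raise ValueError(f"acceleration must be >= 1, got {R}")
    if n_phase % 2 != 0:
        raise ValueError("n_phase must be even")
    n_ret = int(np.floor(n_phase / R))
    if n_ret < 1:
        raise ValueError(f"floor({n_phase}/{R}) < 1: no lines would be retained")
    center = n_phase // 2
    start = center - n_ret // 2
    retained = np.zeros(n_phase, dtype=bool)
    retained[start : start + n_ret] = True
    return SamplingMask(n_phase, retained, float(R))


def escalate_mask(mask: SamplingMask, target_R: float) -> SamplingMask:
    """Escalate acceleration by zeroing outer lines of the retained block.

    Removal is symmetric from both edges of the ACS block (up to the single
    odd line when the removed count is odd); the result is identical to
    building a fresh central mask at ``target_R``.
    """
    if target_R < mask.nominal_R:
        raise ValueError(
            f"cannot de-escalate: target {target_R}x < current {mask.nominal_R}x"
        )
    return make_central_mask(mask.n_phase, target_R)


def apply_mask(kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero all phase lines not retained by the mask.

    Retained lines are copied verbatim; the phase direction is axis ``-2``.
    """
    if kspace.shape[-2] != mask.n_phase:
        raise ValueError(
            f"phase dimension {kspace.shape[-2]} != mask n_phase {mask.n_phase}"
        )
    out = np.zeros_like(kspace)
    out[..., mask.retained, :] = kspace[..., mask.retained, :]
    return out


# ---------------------------------------------------------------------------
# Reconstruction primitives
# ---------------------------------------------------------------------------

def rss_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares combination over the leading coil axis."""
    coil_images = np.asarray(coil_images)
    if coil_images.ndim < 3:
        raise ValueError("expected a (n_coils, ..., rows, cols) stack")
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


def zero_fill_reconstruct(dyn_kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero-filled reconstruction of one multi-coil k-space frame.

    Applies the mask, inverse-transforms each coil and combines by root
    sum of squares.  ``dyn_kspace`` has shape ``(n_coils, n, n)``.
    """
    masked = apply_mask(dyn_kspace, mask)
    return rss_combine(centered_ifft2(masked))


def scale_intensities(images: np.ndarray) -> np.ndarray:
    """Affine rescale of a whole image sequence to the [0, 1] range.

    The minimum and maximum are global over the sequence (not per frame),
    preserving temporal intensity dynamics.  A constant sequence maps to
    all zeros.
    """
    images = np.asarray(images, dtype=float)
    if images.size == 0:
        raise ValueError("empty image sequence")
    lo, hi = images.min(), images.max()
    if hi == lo:
        return np.zeros_like(images)
    return (images - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Protocol arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolParams:
    """Acquisition-protocol parameters of a 2D Cartesian bSSFP scan."""

    tr_ms: float
    te_ms: float
    fov_mm: float
    matrix_encoded: tuple[int, int] = (256, 320)  # frequency x phase
    matrix_recon: int = 256
    n_slices: int = 1
    n_frames: int = 1
    acquired_lines: int = field(default=320)

    def __post_init__(self) -> None:
        if min(self.tr_ms, self.te_ms, self.fov_mm) <= 0:
            raise ValueError("timings and field of view must be positive")
        if self.matrix_recon > self.matrix_encoded[1]:
            raise ValueError("reconstructed matrix exceeds encoded phase count")

    @property
    def pixel_spacing_mm(self) -> float:
        """In-plane resolution: field of view over reconstructed matrix."""
        return round(self.fov_mm / self.matrix_recon, 3)


def effective_undersampling(encoded_lines: int, acquired_lines: int) -> float:
    """Effective undersampling rate: encoded / acquired phase lines.

    Reported rounded to one decimal, e.g. 320 encoded over 68 acquired
    lines is a 4.7x effective rate.
    """
    if encoded_lines <= 0 or acquired_lines <= 0:
        raise ValueError("line counts must be positive")
    return round(encoded_lines / acquired_lines, 1)


def scan_time(tr_ms: float, n_lines: int, n_units: int) -> float:
    """Scan time in seconds: TR x lines per unit x units (slices or frames).

    ``n_units = 0`` is allowed and yields 0 (no acquisition).
    """
    if tr_ms <= 0 or n_lines <= 0 or n_units < 0:
        raise ValueError("TR and line count must be positive, units non-negative")
    return round(tr_ms * n_lines * n_units / 1000.0, 2)
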