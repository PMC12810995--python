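"""Tracking-feasibility statistics and reporting.

Per-frame tip errors are thresholded at 5 mm (success strictly below,
failure at or above); per-sample success rates are summarized with their
mean, sample standard deviation and a 95% Wilson score interval; the
independent segmentation validation uses a one-sided one-sample t-test
against the 5 mm bound, a t-based confidence interval for the mean error,
and a gamma distribution fitted by matching the sample mean and skewness
(shape ``alpha = 4 / skew**2``, scale ``theta = mean / alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FrameResult", "TrackingResult", "WilsonInterval", "GammaFit",
           "TTestResult", "success_rate", "wilson_interval",
           "t_confidence_interval", "one_sample_t_test", "gamma_moment_fit",
           "summarize_experiment", "error_heatmap",
           "SUCCESS_THRESHOLD_MM"]

SUCCESS_THRESHOLD_MM = 5.0


@dataclass(frozen=True)
class FrameResult:
    frame_index: int
    error_mm: float
    success: bool
    excluded: bool = False


@dataclass
class TrackingResult:
    """Per-frame tracking outcome of one sample at one acceleration level."""

    sample_id: str
    R: float
    method: str
    frames: list[FrameResult]
    n_klines: int | None = None
    move_window: tuple[int, int] | None = None

    @property
    def success_rate(self) -> float:
        kept = [f for f in self.frames if not f.excluded]
        if not kept:
            raise ValueError("all frames excluded")
        return sum(f.success for f in kept) / len(kept)

    @property
    def errors_mm(self) -> np.ndarray:
        return np.array([f.error_mm for f in self.frames])


@dataclass(frozen=True)
class WilsonInterval:
    lo: float
    hi: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ValueError("Wilson bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class GammaFit:
    """Gamma(alpha, theta) by moment matching to mean and skewness."""

    alpha: float
    theta: float
    sample_mean: float
    sample_skewness: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.theta <= 0:
            raise ValueError("gamma parameters must be positive")

    @classmethod
    def from_mean_and_shape(cls, mean: float, alpha: float) -> "GammaFit":
        """Analytic fit given the mean and shape: theta = mean / alpha."""
        return cls(alpha=alpha, theta=mean / alpha, sample_mean=mean,
                   sample_skewness=float(np.sqrt(4.0 / alpha)))


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    significant: bool
    zero_variance: bool = False
    mean_offset_sign: int = 0


# ---------------------------------------------------------------------------
# Per-sample statistics
# ---------------------------------------------------------------------------

def success_rate(errors_mm, threshold: float = SUCCESS_THRESHOLD_MM,
                 excluded=()) -> float:
    """Proportion of non-excluded frames with error strictly below threshold.

    An error exactly at the threshold counts as a failure.  Excluded
    frames are omitted from numerator and denominator.
    """
    errors = np.asarray(errors_mm, dtype=float)
    keep = np.ones(len(errors), dtype=bool)
    keep[list(excluded)] = False
    if not keep.any():
        raise ValueError("all frames excluded")
    kept = errors[keep]
    return float(np.mean(kept < threshold))


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> WilsonInterval:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    z = stats.norm.ppf(0.5 + confidence / 2)
    p = k / n
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return WilsonInterval(lo=max(0.0, center - half),
                          hi=min(1.0, center + half),
                          confidence=confidence)


def t_confidence_interval(mean: float, sd: float, n: int,
                          confidence: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for a sample mean: mean +- t * sd / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    t_crit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
    half = t_crit * sd / np.sqrt(n)
    return (mean - half, mean + half)


def one_sample_t_test(errors_mm, mu0: float = SUCCESS_THRESHOLD_MM,
                      alpha: float = 0.05) -> TTestResult:
    """One-sided (less-than) one-sample t-test of the mean error against mu0.

    A zero-variance sample cannot support a t statistic: the result is
    flagged, with the sign of (mean - mu0) recorded; an all-equal sample
    at exactly mu0 degenerates to t = 0, p = 0.5.
    """
    x = np.asarray(errors_mm, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        sign = int(np.sign(mean - mu0))
        if sign == 0:
            return TTestResult(0.0, 0.5, False, zero_variance=True)
        p = 0.0 if sign < 0 else 1.0
        return TTestResult(float("-inf") if sign < 0 else float("inf"), p,
                           sign < 0, zero_variance=True,
                           mean_offset_sign=sign)
    res = stats.ttest_1samp(x, mu0, alternative="less")
    return TTestResult(float(res.statistic), float(res.pvalue),
                       res.pvalue < alpha)


def gamma_moment_fit(errors_mm) -> GammaFit:
    """Fit Gamma(alpha, theta) by matching sample mean and skewness.

    Uses the adjusted Fisher-Pearson (bias-corrected) skewness ``g``;
    ``alpha = 4 / g**2`` and ``theta = mean / alpha``.  Requires positive
    skewness and at least three observations.
    """
    x = np.asarray(errors_mm, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three observations")
    g = float(stats.skew(x, bias=False))
    if g <= 0:
        raise ValueError(f"sample skewness must be positive, got {g:.4f}")
    alpha = 4.0 / g ** 2
    return GammaFit(alpha=alpha, theta=float(x.mean()) / alpha,
                    sample_mean=float(x.mean()), sample_skewness=g)


# ---------------------------------------------------------------------------
# Experiment-level reporting
# ---------------------------------------------------------------------------

def summarize_experiment(results: list[TrackingResult],
                         confidence: float = 0.95) -> pd.DataFrame:
    """Success-rate summary per acceleration level and method.

    One row per (R, method): number of samples, retained-line count, mean
    and sample standard deviation of the per-sample success rates, and a
    Wilson interval on the pooled non-excluded frames of that group.
    """
    if not results:
        raise ValueError("no tracking results")
    rows = []
    keys = sorted({(r.R, r.method) for r in results})
    for R, method in keys:
        group = [r for r in results if r.R == R and r.method == method]
        rates = np.array([r.success_rate for r in group])
        kept = [f for r in group for f in r.frames if not f.excluded]
        k = sum(f.success for f in kept)
        wi = wilson_interval(k, len(kept), confidence)
        rows.append({
            "R": R,
            "n_klines": group[0].n_klines,
            "method": method,
            "n_samples": len(group),
            "mean_success_rate": rates.mean(),
            "sd_success_rate": rates.std(ddof=1) if len(rates) > 1 else 0.0,
            "wilson_lo": wi.lo,
            "wilson_hi": wi.hi,
        })
    return pd.DataFrame(rows)


def error_heatmap(results: list[TrackingResult], path,
                  threshold: float = SUCCESS_THRESHOLD_MM) -> None:
    """Samples x frames error heatmap in the style of a tracking report.

    Successful frames (< threshold) use a blue ramp, failures a red ramp,
    excluded frames are blanked, and each sample's annotated motion window
    is outlined.  Rendering is deterministic for fixed inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no tracking results")
    n_frames = max(len(r.frames) for r in results)
    err = np.full((len(results), n_frames), np.nan)
    for i, r in enumerate(results):
        for f in r.frames:
            if not f.excluded:
                err[i, f.frame_index] = f.error_mm

    success = np.where(err < threshold, err, np.nan)
    failure = np.where(err >= threshold, np.minimum(err, 4 * threshold), np.nan)

    fig, ax = plt.subplots(figsize=(10, 0.5 * len(results) + 1.5))
    ax.imshow(success, cmap="Blues", vmin=0, vmax=threshold,
              aspect="auto", interpolation="nearest")
    ax.imshow(failure, cmap="Reds", vmin=threshold, vmax=4 * threshold,
              aspect="auto", interpolation="nearest")
    for i, r in enumerate(results):
        if r.move_window is not None:
            lo, hi = r.move_window
            ax.add_patch(plt.Rectangle((lo - 0.5, i - 0.5), hi - lo + 1, 1,
                                       fill=False, edgecolor="white",
                                       linewidth=1.2))
    ax.set_xlabel("frame")
    ax.set_yticks(range(len(results)))
    ax.set_yticklabels([r.sample_id for r in results])
    ax.set_title("instrument tip prediction error (blue: success, red: failure)")
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
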