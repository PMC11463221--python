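"""Windowed adaptive smoothing and overlap reconciliation.

The noise variance of wrist-worn HR data drifts with activity, sweat and
movement, so a single global signal-to-noise ratio is unrealistic.  The
series is cut into overlapping windows (200 samples with 20-sample
overlaps by default); the self-tuning smoother re-estimates gamma — and
hence the noise variance — inside each window, and the overlapping
estimates are reconciled with a monotone Gaussian weight ramp so the
assembled trace has no seams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import estimate_gamma
from .types import ARNoiseModel, HeartRateSeries, WindowFit, as_values

__all__ = [
    "WindowPlan",
    "SmoothResult",
    "plan_windows",
    "gaussian_ramp",
    "blend_overlap",
    "adaptive_smooth",
]

DEFAULT_WINDOW_SIZE = 200
DEFAULT_OVERLAP = 20


@dataclass
class WindowPlan:
    """Half-open index ranges [start, end) covering a series."""

    ranges: List[Tuple[int, int]]
    window_size: int = DEFAULT_WINDOW_SIZE
    overlap: int = DEFAULT_OVERLAP

    def __len__(self) -> int:
        return len(self.ranges)


@dataclass
class SmoothResult:
    """Full-series smoothing outcome.

    ``noise_variance_trace`` is a per-sample step function: each window's
    sigma2_hat over its exclusive span, the mean of the two contributing
    windows over overlaps.
    """

    u_hat: np.ndarray
    ci_halfwidth: np.ndarray
    per_window: List[WindowFit]
    noise_variance_trace: np.ndarray
    window_id: np.ndarray
    plan: WindowPlan
    series: Optional[HeartRateSeries] = None

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: timestamp, hr_raw, hr_smoothed, ci_halfwidth,
        window_id, sigma2_hat, gamma."""
        n = self.u_hat.size
        gamma = np.full(n, np.nan)
        sigma2 = self.noise_variance_trace
        for wid, fit in enumerate(self.per_window):
            gamma[fit.start : fit.end] = fit.gamma
        data = {
            "hr_smoothed": self.u_hat,
            "ci_halfwidth": self.ci_halfwidth,
            "window_id": self.window_id,
            "sigma2_hat": sigma2,
            "gamma": gamma,
        }
        if self.series is not None:
            data = {"hr_raw": self.series.values, **data}
            ts = self.series.timestamps()
            if ts is not None:
                data = {"timestamp": ts, **data}
        return pd.DataFrame(data)


def plan_windows(
    n: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    overlap: int = DEFAULT_OVERLAP,
) -> WindowPlan:
    """Segment ``n`` samples into strided, overlapping windows.

    Stride is ``window_size - overlap``; each range is
    ``[i*stride, i*stride + window_size)`` clipped to ``n``, and the final
    range is extended backward so the tail is never a tiny fragment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < overlap < window_size):
        raise ValueError("need 0 < overlap < window_size")
    stride = window_size - overlap
    if n <= window_size:
        return WindowPlan([(0, n)], window_size, overlap)
    ranges: List[Tuple[int, int]] = []
    start = 0
    while start + window_size < n:
        ranges.append((start, start + window_size))
        start += stride
    # final window, extended backward to full size
    ranges.append((max(0, n - window_size), n))
    return WindowPlan(ranges, window_size, overlap)


def gaussian_ramp(m: int, sd_fraction: float = 0.25) -> np.ndarray:
    """Monotone blending weights w_0 ... w_{m-1} rising from ~0.02 to ~0.98.

    Built from the Gaussian CDF centered at the overlap midpoint with
    standard deviation ``sd_fraction * m``; the complementary pair
    ``(1 - w, w)`` sums to one by construction.
    """
    if m < 1:
        raise ValueError("overlap length must be >= 1")
    if m == 1:
        return np.array([0.5])
    j = np.arange(m, dtype=float)
    return norm.cdf((j - (m - 1) / 2.0) / (sd_fraction * m))


def blend_overlap(
    left_tail: np.ndarray, right_head: np.ndarray, sd_fraction: float = 0.25
) -> np.ndarray:
    """Convex blend of two overlapping window estimates.

    ``out[j] = (1 - w_j) left[j] + w_j right[j]`` with the Gaussian ramp
    weights, so the left window dominates the start of the overlap and the
    right window its end.
    """
    left = np.asarray(left_tail, dtype=float)
    right = np.asarray(right_head, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("overlap segments must be 1-D and of equal length")
    w = gaussian_ramp(left.size, sd_fraction)
    return (1.0 - w) * left + w * right


def adaptive_smooth(
    series: Union[HeartRateSeries, np.ndarray],
    model: ARNoiseModel,
    window_size: int = DEFAULT_WINDOW_SIZE,
    overlap: int = DEFAULT_OVERLAP,
    baseline: str = "first",
) -> SmoothResult:
    """Run the self-tuning smoother window by window and reconcile overlaps.

    The AR noise coefficients are global and held fixed; gamma (hence the
    noise variance sigma2_hat and signal variance lambda2_hat) is
    re-estimated inside every window, which is what lets the filter track
    a time-varying signal-to-noise ratio.  A window whose estimation fails
    falls back to identity smoothing on that span, flagged in its
    ``WindowFit.status``.
    """
    yv = as_values(series)
    if yv.size < 3:
        raise ValueError("series must hold at least 3 samples")
    plan = plan_windows(yv.size, window_size, overlap)
    n = yv.size

    fits: List[WindowFit] = []
    for start, end in plan.ranges:
        try:
            fit = estimate_gamma(yv[start:end], model, baseline=baseline)
        except Exception as exc:  # pragma: no cover - defensive per-window fallback
            warnings.warn(
                f"window [{start}, {end}) failed ({exc}); using raw samples",
                UserWarning,
                stacklevel=2,
            )
            seg = yv[start:end]
            fit = WindowFit(
                u_hat=seg.copy(),
                gamma=float("nan"),
                sigma2_hat=0.0,
                lambda2_hat=float("nan"),
                dof=float(seg.size),
                wrss=0.0,
                wess=0.0,
                ci_halfwidth=np.zeros(seg.size),
                status="failed",
            )
        fit.start, fit.end = start, end
        fits.append(fit)

    u_hat = np.zeros(n)
    ci = np.zeros(n)
    window_id = np.zeros(n, dtype=int)
    var_sum = np.zeros(n)
    var_count = np.zeros(n)

    prev_end = 0
    for wid, fit in enumerate(fits):
        start, end = fit.start, fit.end
        m = prev_end - start  # actual overlap with what is already assembled
        if m > 0:
            u_hat[start:prev_end] = blend_overlap(
                u_hat[start:prev_end], fit.u_hat[:m]
            )
            ci[start:prev_end] = blend_overlap(ci[start:prev_end], fit.ci_halfwidth[:m])
            w = gaussian_ramp(m)
            window_id[start:prev_end] = np.where(
                w >= 0.5, wid, window_id[start:prev_end]
            )
        u_hat[prev_end:end] = fit.u_hat[m if m > 0 else 0 :][: end - prev_end]
        ci[prev_end:end] = fit.ci_halfwidth[m if m > 0 else 0 :][: end - prev_end]
        window_id[prev_end:end] = wid
        var_sum[start:end] += fit.sigma2_hat
        var_count[start:end] += 1.0
        prev_end = end

    result = SmoothResult(
        u_hat=u_hat,
        ci_halfwidth=ci,
        per_window=fits,
        noise_variance_trace=var_sum / np.maximum(var_count, 1.0),
        window_id=window_id,
        plan=plan,
        series=series if isinstance(series, HeartRateSeries) else None,
    )
    return result
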