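"""Comparator smoothers: centered moving average and degree-2 LOESS.

Both are linear, non-adaptive operators used as reference points for the
Bayesian smoother.  The moving average runs over windows of 5-35 samples;
LOESS fits a local quadratic by tricube-weighted least squares over an
80-sample span.  The local-quadratic LOESS is implemented here directly
(classic formulation, no robustness iterations).
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .types import HeartRateSeries, as_values

__all__ = ["moving_average", "loess_smooth"]


def moving_average(
    y: Union[HeartRateSeries, np.ndarray], window: int
) -> np.ndarray:
    """Centered moving average with edge truncation.

    Each output sample averages up to ``window`` neighbours: ceil((w-1)/2)
    to the left and floor((w-1)/2) to the right, truncated where the
    series ends, so output length equals input length.
    """
    x = as_values(y)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = x.size
    left = (window - 1 + 1) // 2  # ceil((w-1)/2)
    right = (window - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def loess_smooth(
    y: Union[HeartRateSeries, np.ndarray],
    span: int = 80,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights on a uniform grid.

    For each sample the ``span`` nearest neighbours (a contiguous block on
    a uniform grid) are fitted with a degree-``degree`` polynomial by
    weighted least squares; weights are tricube in distance scaled by the
    span's maximum distance.  The fit is evaluated at the sample itself.
    """
    x = as_values(y)
    n = x.size
    if span < degree + 2:
        raise ValueError("span must be >= degree + 2")
    if span > n:
        raise ValueError("span exceeds series length")
    idx = np.arange(n, dtype=float)
    out = np.empty(n)
    half = span // 2
    for i in range(n):
        lo = min(max(i - half, 0), n - span)
        hi = lo + span
        d = idx[lo:hi] - i
        dmax = np.max(np.abs(d))
        if dmax == 0:
            out[i] = x[i]
            continue
        u = np.abs(d) / dmax
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        sw = np.sqrt(w)
        # Vandermonde in the centered coordinate: intercept = value at i
        V = np.vander(d, degree + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(V * sw[:, None], x[lo:hi] * sw, rcond=None)
        out[i] = beta[0]
    return out
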