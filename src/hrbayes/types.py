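"""Domain containers shared across the package.

The central objects are a uniformly sampled heart-rate series, a monic
autoregressive (AR) model of the measurement noise, and the per-window
result of the self-tuning Bayesian smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeartRateSeries",
    "ARNoiseModel",
    "IRWPrior",
    "WindowFit",
]


@dataclass
class HeartRateSeries:
    """Uniformly sampled heart-rate trace.

    Parameters
    ----------
    values : array-like
        HR samples in beats per minute (bpm).
    sampling_period : float
        Seconds between consecutive samples (30 s for the smartwatch data
        this package targets).
    start_time : pandas.Timestamp, optional
        Wall-clock time of the first sample. Needed only for day/night
        stratification and CSV export.
    """

    values: np.ndarray
    sampling_period: float = 30.0
    start_time: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")

    def __len__(self) -> int:
        return self.values.size

    def timestamps(self) -> Optional[pd.DatetimeIndex]:
        """Per-sample timestamps, or None if no start time is known."""
        if self.start_time is None:
            return None
        return pd.date_range(
            start=self.start_time,
            periods=len(self),
            freq=pd.Timedelta(seconds=self.sampling_period),
        )


@dataclass
class ARNoiseModel:
    """Stationary monic AR model of the measurement noise.

    The recursion uses the monic-polynomial sign convention

        w(k) = -sum_i a_i w(k-i) + eps(k),

    so that the lower-triangular Toeplitz matrix with first column
    ``[1, a_1, ..., a_p, 0, ...]`` whitens the noise: ``A w = eps``.

    Attributes
    ----------
    coefficients : ndarray, shape (order,)
        Monic coefficients a_1 ... a_p. Empty for white noise.
    sigma2 : float or None
        Innovation variance of the driving white noise; None before
        estimation.
    """

    coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2: Optional[float] = None

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(
            np.asarray(self.coefficients, dtype=float)
        )
        if self.coefficients.size and not np.all(np.isfinite(self.coefficients)):
            raise ValueError("AR coefficients must be finite")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive when set")
        if not self.is_stationary():
            raise ValueError(
                "AR polynomial has roots on or outside the unit circle"
            )

    @property
    def order(self) -> int:
        return int(self.coefficients.size)

    def poly_roots(self) -> np.ndarray:
        """Roots of z^p + a_1 z^(p-1) + ... + a_p (inside unit circle iff stationary)."""
        if self.order == 0:
            return np.empty(0, dtype=complex)
        return np.roots(np.concatenate(([1.0], self.coefficients)))

    def is_stationary(self, tol: float = 1e-10) -> bool:
        roots = self.poly_roots()
        return bool(roots.size == 0 or np.max(np.abs(roots)) < 1.0 - tol)

    @classmethod
    def white(cls, sigma2: Optional[float] = None) -> "ARNoiseModel":
        """Order-0 (white noise) model."""
        return cls(coefficients=np.empty(0), sigma2=sigma2)


@dataclass
class IRWPrior:
    """Integrated-random-walk prior u(k) = 2u(k-1) - u(k-2) + v(k).

    ``lambda2`` is the variance of the driving white noise v(k); it is
    usually unknown and absorbed into the regularization parameter
    gamma = sigma2 / lambda2.
    """

    n: int
    lambda2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("window length must be >= 1")
        if self.lambda2 is not None and self.lambda2 <= 0:
            raise ValueError("lambda2 must be positive when set")


@dataclass
class WindowFit:
    """Outcome of the self-tuning smoother on a single window.

    ``status`` is ``"ok"`` for a converged criterion root, ``"boundary"``
    when no sign change was found in the gamma bracket (the closer bracket
    end is returned), and ``"degenerate"`` for windows too short or too
    flat to support estimation (identity smoothing is applied).
    """

    u_hat: np.ndarray
    gamma: float
    sigma2_hat: float
    lambda2_hat: float
    dof: float
    wrss: float
    wess: float
    ci_halfwidth: np.ndarray
    status: str = "ok"
    start: int = 0
    end: Optional[int] = None

    @property
    def n(self) -> int:
        return int(self.u_hat.size)


def as_values(series: "HeartRateSeries | Sequence[float] | np.ndarray") -> np.ndarray:
    """Accept either a HeartRateSeries or a bare array and return 1-D float values."""
    if isinstance(series, HeartRateSeries):
        return series.values
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("expected a 1-D series")
    return arr
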