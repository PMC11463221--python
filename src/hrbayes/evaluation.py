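"""Accuracy metrics, day/night stratification and paired residual testing.

All method outputs are rounded to integers before scoring, matching the
integer bpm values a wrist sensor reports; the ground truth is left
unrounded.  Metrics are RMSE and MAE in bpm and MARD in percent.
Nighttime is the clock interval [00:00, 06:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import HeartRateSeries, as_values

__all__ = [
    "round_to_sensor",
    "compute_metrics",
    "stratify_day_night",
    "paired_residual_test",
    "EvalReport",
    "evaluate_methods",
    "DegenerateTestError",
]

STRATA = ("overall", "daytime", "nighttime")


class DegenerateTestError(ValueError):
    """Paired test undefined: the residual differences have zero variance."""


def round_to_sensor(values: Union[HeartRateSeries, np.ndarray]) -> np.ndarray:
    """Round to integers, halves away from zero (60.5 -> 61), like the
    integer bpm output of the sensor itself."""
    x = as_values(values)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def compute_metrics(
    estimate: Union[HeartRateSeries, np.ndarray],
    truth: Union[HeartRateSeries, np.ndarray],
    round_estimate: bool = True,
) -> Dict[str, float]:
    """RMSE (bpm), MAE (bpm) and MARD (%) of an estimate versus ground truth.

    The estimate is integer-rounded first (sensor convention); the truth
    is used as-is and must be nonzero for MARD to exist.
    """
    u_hat = as_values(estimate)
    u = as_values(truth)
    if u_hat.size != u.size:
        raise ValueError("estimate and truth must have equal length")
    if np.any(u == 0):
        raise ValueError("truth contains zero values: MARD undefined")
    if round_estimate:
        u_hat = round_to_sensor(u_hat)
    err = u_hat - u
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "mard": float(100.0 * np.mean(np.abs(err / u))),
    }


def stratify_day_night(
    timestamps: Optional[pd.DatetimeIndex],
    n: Optional[int] = None,
) -> Dict[str, np.ndarray]:
    """Index sets for daytime and nighttime ([00:00, 06:00), half-open).

    Without timestamps only the ``overall`` stratum is returned.
    """
    if timestamps is None:
        if n is None:
            raise ValueError("need timestamps or a series length")
        return {"overall": np.arange(n)}
    idx = np.arange(len(timestamps))
    hours = timestamps.hour + timestamps.minute / 60.0 + timestamps.second / 3600.0
    night = np.asarray(hours < 6.0)
    return {
        "overall": idx,
        "daytime": idx[~night],
        "nighttime": idx[night],
    }


def paired_residual_test(
    residuals_a: np.ndarray, residuals_b: np.ndarray
) -> float:
    """Two-sided paired t-test on per-sample absolute residuals.

    Returns the p-value; identical (or offset-identical) absolute
    residuals have zero difference variance and raise
    :class:`DegenerateTestError`.
    """
    a = np.abs(as_values(residuals_a))
    b = np.abs(as_values(residuals_b))
    if a.size != b.size:
        raise ValueError("residual vectors must be paired (equal length)")
    d = a - b
    if np.ptp(d) == 0.0:
        raise DegenerateTestError("residual differences have zero variance")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class EvalReport:
    """Per-method, per-stratum metrics plus paired tests vs a reference."""

    metrics: pd.DataFrame  # index: (method, stratum); columns rmse/mae/mard
    residuals: Dict[str, np.ndarray]
    p_values: Dict[str, float] = field(default_factory=dict)
    reference: Optional[str] = None
    empty_strata: List[str] = field(default_factory=list)

    def summary(self) -> str:
        """Plain-text table, methods x (stratum, metric)."""
        wide = self.metrics.unstack(level=1)
        lines = [wide.round(3).to_string()]
        if self.p_values:
            lines.append("")
            lines.append(f"paired t-test on |residuals| vs {self.reference}:")
            for m, p in self.p_values.items():
                lines.append(f"  {m}: p = {p:.3g}")
        if self.empty_strata:
            lines.append(f"empty strata: {', '.join(self.empty_strata)}")
        return "\n".join(lines)


def evaluate_methods(
    estimates: Dict[str, np.ndarray],
    truth: Union[HeartRateSeries, np.ndarray],
    timestamps: Optional[pd.DatetimeIndex] = None,
    reference: Optional[str] = None,
) -> EvalReport:
    """Score several method outputs against one ground truth.

    ``estimates`` maps method name -> estimated series.  When
    ``reference`` is given, each other method's absolute residuals are
    compared against it with a paired t-test.
    """
    u = as_values(truth)
    strata = stratify_day_night(timestamps, n=u.size)
    rows = []
    residuals: Dict[str, np.ndarray] = {}
    empty = []
    for method, est in estimates.items():
        est_r = round_to_sensor(est)
        residuals[method] = est_r - u
        for stratum in STRATA:
            if stratum not in strata:
                continue
            sel = strata[stratum]
            if sel.size == 0:
                if stratum not in empty:
                    empty.append(stratum)
                continue
            m = compute_metrics(est_r[sel], u[sel], round_estimate=False)
            rows.append({"method": method, "stratum": stratum, **m})
    metrics = pd.DataFrame(rows).set_index(["method", "stratum"])
    p_values: Dict[str, float] = {}
    if reference is not None:
        if reference not in estimates:
            raise ValueError(f"reference method {reference!r} not among estimates")
        for method in estimates:
            if method == reference:
                continue
            try:
                p_values[method] = paired_residual_test(
                    residuals[method], residuals[reference]
                )
            except DegenerateTestError:
                p_values[method] = float("nan")
    return EvalReport(
        metrics=metrics,
        residuals=residuals,
        p_values=p_values,
        reference=reference,
        empty_strata=empty,
    )
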