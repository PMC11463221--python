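"""File formats: HR CSV, AR model text files, benchmark bundles, configs.

Everything is plain text.  HR series travel as two-column CSV
(``timestamp``, ``hr_bpm``); AR models as a small key-value file;
benchmark bundles as a directory of CSVs plus a YAML manifest; run
configuration as YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .evaluation import EvalReport
from .synthetic import SigmaProfile, SyntheticBenchmark
from .types import ARNoiseModel, HeartRateSeries
from .windowing import SmoothResult

__all__ = [
    "RunConfig",
    "read_hr_csv",
    "write_hr_csv",
    "read_ar_model",
    "write_ar_model",
    "write_smooth_result",
    "write_benchmark_bundle",
    "read_benchmark_bundle",
    "write_eval_report",
]

JITTER_TOLERANCE = 0.01  # relative deviation allowed on the sampling grid


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the standard operating point."""

    window_size: int = 200
    overlap: int = 20
    ar_order: int = 20
    butterworth_order: int = 6
    butterworth_cutoff: float = 0.4  # fraction of Nyquist
    gamma_bracket: Tuple[float, float] = (1e-6, 1e8)
    gamma_log_tol: float = 1e-4
    ma_windows: List[int] = field(default_factory=lambda: [5, 15, 25, 35])
    loess_span: int = 80
    seed: int = 0

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        d["gamma_bracket"] = list(d["gamma_bracket"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "gamma_bracket" in d:
            d["gamma_bracket"] = tuple(d["gamma_bracket"])
        return cls(**d)


def read_hr_csv(path: Union[str, Path]) -> HeartRateSeries:
    """Read a heart-rate CSV (columns ``timestamp``, ``hr_bpm``).

    Timestamps must be strictly increasing and uniformly spaced to within
    1% relative jitter; the offending gap is named otherwise.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"timestamp", "hr_bpm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"])
    if len(df) == 0:
        raise ValueError(f"{path}: empty file")
    if len(df) == 1:
        return HeartRateSeries(df["hr_bpm"].to_numpy(float), 30.0, ts.iloc[0])
    deltas = ts.diff().dt.total_seconds().to_numpy()[1:]
    if np.any(deltas <= 0):
        bad = int(np.argmax(deltas <= 0))
        raise ValueError(
            f"{path}: timestamps not strictly increasing at row {bad + 1}"
        )
    period = float(np.median(deltas))
    off = np.abs(deltas - period) > JITTER_TOLERANCE * period
    if np.any(off):
        bad = np.flatnonzero(off)
        raise ValueError(
            f"{path}: non-uniform sampling grid (expected {period:.3g} s); "
            f"offending gap(s) after sample index {bad.tolist()[:10]}"
        )
    return HeartRateSeries(df["hr_bpm"].to_numpy(float), period, ts.iloc[0])


def write_hr_csv(path: Union[str, Path], series: HeartRateSeries) -> None:
    ts = series.timestamps()
    if ts is None:
        ts = pd.date_range(
            "2000-01-01", periods=len(series),
            freq=pd.Timedelta(seconds=series.sampling_period),
        )
    pd.DataFrame({"timestamp": ts, "hr_bpm": series.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_ar_model(path: Union[str, Path], model: ARNoiseModel) -> None:
    """Key-value text serialization (order, coefficients, sigma2)."""
    lines = [f"order = {model.order}"]
    coeffs = ", ".join(repr(float(c)) for c in model.coefficients)
    lines.append(f"coefficients = {coeffs}")
    lines.append(f"sigma2 = {'' if model.sigma2 is None else repr(float(model.sigma2))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ar_model(path: Union[str, Path]) -> ARNoiseModel:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"AR model file not found: {p}")
    fields: Dict[str, str] = {}
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    try:
        order = int(fields["order"])
        coeffs = (
            np.array([float(c) for c in fields["coefficients"].split(",") if c.strip()])
            if fields.get("coefficients")
            else np.empty(0)
        )
        sigma2 = float(fields["sigma2"]) if fields.get("sigma2") else None
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{p}: malformed AR model file ({exc})") from exc
    if coeffs.size != order:
        raise ValueError(f"{p}: order={order} but {coeffs.size} coefficients")
    return ARNoiseModel(coefficients=coeffs, sigma2=sigma2)


def write_smooth_result(path: Union[str, Path], result: SmoothResult) -> None:
    """SmoothResult as CSV: timestamp, hr_raw, hr_smoothed, ci_halfwidth,
    window_id, sigma2_hat, gamma."""
    result.to_frame().to_csv(path, index=False)


def write_benchmark_bundle(
    directory: Union[str, Path], benchmark: SyntheticBenchmark
) -> Path:
    """Benchmark as a directory of CSVs plus a manifest; re-loadable bit-exactly."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_hr_csv(d / "ground_truth.csv", benchmark.ground_truth)
    write_hr_csv(d / "noisy.csv", benchmark.noisy)
    pd.DataFrame({"sigma": benchmark.sigma_profile.values}).to_csv(
        d / "sigma_profile.csv", index=False,
        float_format="%.17g",
    )
    write_ar_model(d / "ar_model.txt", benchmark.ar_model)
    manifest = {
        "seed": benchmark.seed,
        "params": benchmark.params,
        "sigma_params": benchmark.sigma_profile.params,
        "sampling_period": benchmark.ground_truth.sampling_period,
        "n": len(benchmark.ground_truth),
    }
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    # noise is redundant (noisy - truth) but kept for exact round-trips
    np.savetxt(d / "noise.csv", benchmark.noise, header="noise", comments="")
    return d


def read_benchmark_bundle(directory: Union[str, Path]) -> SyntheticBenchmark:
    d = Path(directory)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    truth = read_hr_csv(d / "ground_truth.csv")
    noisy = read_hr_csv(d / "noisy.csv")
    sigma = pd.read_csv(
        d / "sigma_profile.csv", float_precision="round_trip"
    )["sigma"].to_numpy(float)
    noise = np.loadtxt(d / "noise.csv", skiprows=1)
    return SyntheticBenchmark(
        ground_truth=truth,
        noise=noise,
        noisy=noisy,
        sigma_profile=SigmaProfile(
            sigma, manifest.get("sigma_params", {}), manifest.get("seed")
        ),
        ar_model=read_ar_model(d / "ar_model.txt"),
        seed=manifest["seed"],
        params=manifest.get("params", {}),
    )


def write_eval_report(
    path: Union[str, Path], report: EvalReport, summary_path: Optional[Union[str, Path]] = None
) -> None:
    """Metrics table as CSV (rows method x stratum) and optional text summary."""
    report.metrics.reset_index().to_csv(path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(report.summary() + "\n")
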