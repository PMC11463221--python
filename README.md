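# hrbayes

Adaptive, self-tuning Bayesian smoothing for heart-rate series from
wearable devices.

Wrist-worn optical sensors report heart rate (HR) every ~30 s, but the
measurements are corrupted by correlated noise whose level drifts with
movement, sweat and skin contact — it is typically worst during sleep.
Fixed smoothers (moving averages, LOESS) apply one bandwidth everywhere
and therefore either under-smooth noisy stretches or blur genuine HR
dynamics. `hrbayes` instead *learns* the signal-to-noise ratio window by
window and smooths each window optimally, returning a denoised trace, a
per-sample confidence band, and a per-window noise-variance estimate that
is itself a useful signal-quality indicator.

## The model

Measurements are `y(k) = u(k) + w(k)` on a uniform grid. Two priors close
the problem:

- the true HR profile `u` is an integrated random walk,
  `u(k) = 2u(k-1) - u(k-2) + v(k)` with `v ~ N(0, λ²)`, giving prior
  covariance `Σ_u = λ² (FᵀF)⁻¹` where `F` is the lower-triangular
  Toeplitz second-difference operator (first column `[1, -2, 1, 0, …]`);
- the noise `w` is a stationary AR(p) process (p = 20 by default, fitted
  from data) driven by white noise of variance `σ²`, giving
  `Σ_w = σ² (AᵀA)⁻¹` where `A` is the Toeplitz whitening operator with
  first column `[1, a₁, …, a_p, 0, …]`.

The linear MMSE estimate is the regularized solve

    û = (AᵀA + γ FᵀF)⁻¹ AᵀA y,    γ = σ²/λ².

Both variances are unknown, so γ is chosen per 200-sample window as the
root of the maximum-likelihood consistency criterion

    WRSS(γ)/(n − q(γ)) = γ · WESS(γ)/q(γ),

with `WRSS = (y−û)ᵀAᵀA(y−û)`, `WESS = ûᵀFᵀFû` and
`q(γ) = tr[(AᵀA+γFᵀF)⁻¹AᵀA]` the smoother's degrees of freedom. At the
root, `σ̂² = WRSS/(n−q)` estimates the noise variance in that window, and
`σ̂²(AᵀA+γFᵀF)⁻¹` gives the error covariance behind the confidence band.
Overlapping windows (20 samples) are blended with a monotone Gaussian
weight ramp so the assembled trace has no seams.

## Worked example

Build a one-day synthetic benchmark (smooth circadian truth + AR(20)
noise with a time-varying level, ground truth known exactly) and smooth
it:

```python
import numpy as np
from hrbayes import (BayesianSmoother, build_benchmark, compute_metrics,
                     generate_raw_hr)

raw = generate_raw_hr(2880, seed=7)              # one day at one sample / 30 s
bench = build_benchmark(raw, seed=7)             # Butterworth truth + AR(20) noise
bf = BayesianSmoother(noise_model=bench.ar_model).fit(bench.noisy)

truth = bench.ground_truth.values
for name, est in [("noisy", bench.noisy.values), ("BF", bf.estimate_)]:
    m = compute_metrics(est, truth)
    print(f"{name:>5}: RMSE {m['rmse']:.2f} bpm  MAE {m['mae']:.2f} bpm  MARD {m['mard']:.2f} %")
w0, w8 = bf.window_fits_[0], bf.window_fits_[8]
print(f"window 0: gamma = {w0.gamma:.3g}, sigma2_hat = {w0.sigma2_hat:.3f}, dof = {w0.dof:.1f}")
print(f"window 8: gamma = {w8.gamma:.3g}, sigma2_hat = {w8.sigma2_hat:.3f}, dof = {w8.dof:.1f}")
print(f"CI half-width (median): {np.median(bf.ci_halfwidth_):.2f} bpm")
```

prints

```
noisy: RMSE 1.76 bpm  MAE 1.38 bpm  MARD 1.98 %
   BF: RMSE 0.47 bpm  MAE 0.37 bpm  MARD 0.53 %
window 0: gamma = 0.00487, sigma2_hat = 0.025, dof = 94.0
window 8: gamma = 0.00516, sigma2_hat = 0.020, dof = 93.2
CI half-width (median): 0.57 bpm
```

The filter removes roughly three quarters of the error of the raw noisy
trace. Each window reports its own regularization parameter γ (the
learned noise-to-signal variance ratio), its noise-variance estimate σ̂²
(the per-window signal-quality readout) and its effective degrees of
freedom; the confidence half-width is the one-standard-deviation band on
the estimation error.

The same pipeline is available from the shell:

```bash
hrbayes simulate --n 2880 --seed 7 --out bundle/
hrbayes evaluate --bundle bundle/ --out report.csv
hrbayes smooth --input hr.csv --model bundle/ar_model.txt --out smoothed.csv
```

`evaluate` scores the Bayesian filter against moving averages (windows
5–35) and degree-2 LOESS (span 80), overall and split into daytime vs
nighttime (00:00–06:00), with a paired t-test on absolute residuals.

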