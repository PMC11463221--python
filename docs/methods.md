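# Methods

## Measurement model and priors

A wrist-worn sensor reports heart rate `y(k)` in integer bpm on a uniform
grid (sampling period `Ts`, 30 s by default). We model
`y(k) = u(k) + w(k)`: `u` is the true HR profile and `w` additive
measurement noise, both treated as zero-mean (after baseline anchoring,
below) Gaussian vectors.

**Signal prior.** `u` is an integrated random walk (IRW):
`u(k) = 2u(k−1) − u(k−2) + v(k)`, `v ~ N(0, λ²)`. White noise through two
discrete integrators is the standard smoothness prior for slowly varying
physiological signals; its single free parameter λ² is what makes
criterion-based self-tuning possible. Writing the recursion in matrix
form, `F u = v` with `F` the unit-lower-triangular Toeplitz operator with
first column `[1, −2, 1, 0, …]`, so `Σ_u = λ² (FᵀF)⁻¹`. The first two
rows of `F` encode the initial conditions `u(1) = v(1)`,
`u(2) = 2u(1) + v(2)`: the prior believes the signal *starts near zero
with near-zero slope*.

**Noise prior.** `w` is a stationary monic AR(p) process,
`w(k) = −Σᵢ aᵢ w(k−i) + ε(k)`, `ε ~ N(0, σ²)`; the same Toeplitz
construction gives the whitening operator `A` (first column
`[1, a₁, …, a_p, 0, …]`, so `A w = ε` up to startup rows) and
`Σ_w = σ² (AᵀA)⁻¹`. HR residuals are strongly autocorrelated; p = 20
captures dependencies over ten minutes of data at 30-s sampling.

**Estimator.** The linear MMSE estimate
`û = (Σ_w⁻¹ + Σ_u⁻¹)⁻¹ Σ_w⁻¹ y` reduces to
`û = (AᵀA + γFᵀF)⁻¹ AᵀA y` with `γ = σ²/λ²`. The system is symmetric
positive definite for every γ ≥ 0 (A is unit-triangular, hence
invertible), and is solved by Cholesky factorization; no matrix is ever
inverted explicitly except in test oracles. γ = 0 returns the data
exactly; γ → ∞ shrinks the (anchored) estimate to zero.

## Baseline anchoring

The IRW prior's near-zero start is wildly wrong for a ~70 bpm signal: fed
raw values, the penalty term `WESS = ûᵀFᵀFû` is dominated by the two
startup rows (≈ 2·70²), the criterion below is forced toward tiny γ, and
the filter stops smoothing. Subtracting the *window mean* does not fix
this: an IRW wanders O(λ n^{3/2}) away from its own mean, so a large
start offset survives and biases γ̂ by more than a decade on correctly
specified simulations. Subtracting the *first sample* does fix it — it is
the unique shift that zeroes the first startup row exactly and leaves the
second at O(noise + local slope) — and is what `estimate_gamma` and the
windowed pipeline do by default (`baseline="first"`; the anchor is added
back to û). Measured on correctly specified simulations this leaves the
tuner essentially unbiased (median σ̂²/σ² = 0.99, median log₁₀ γ error
−0.03, band coverage 66.6% vs nominal 68.3%). `smooth_window` keeps the
raw equation (`baseline="none"`) as the documented primitive.

## Self-tuning criterion

γ is the root of the maximum-likelihood consistency condition

    WRSS(γ)/(n − q(γ)) = γ · WESS(γ)/q(γ),

`WRSS = (y−û)ᵀAᵀA(y−û)`, `WESS = ûᵀFᵀFû`,
`q(γ) = tr[(AᵀA+γFᵀF)⁻¹AᵀA]` (degrees of freedom: n at γ = 0,
monotonically decreasing). Root finding: a 29-point log₁₀-uniform scan
over γ ∈ [10⁻⁶, 10⁸] locates a sign change of the residual
`g(γ) = WRSS/(n−q) − γWESS/q`, refined by bisection on log₁₀ γ until
|Δlog₁₀ γ| < 10⁻⁴ or |g| < 10⁻⁶·WRSS/(n−q). At the root,
`σ̂² = WRSS/(n−q)` (the natural variance estimator — the left side of the
criterion), `λ̂² = σ̂²/γ̂`, and the error covariance is
`σ̂² (AᵀA+γ̂FᵀF)⁻¹`; the reported band is ±1 s.d.

When `g` never changes sign the root does not exist and the returned end
is chosen by direction: `g > 0` everywhere means every trial γ
undersmooths (flat truth, pure noise) so the stiff end 10⁸ is returned;
`g < 0` everywhere (noiseless smooth data) returns 10⁻⁶. Both are flagged
`"boundary"`. Comparing |g| at the two ends instead is meaningless — both
criterion terms vanish as γ → 0, so the soft end always "wins".
Windows with fewer than 10 samples or zero range skip estimation
entirely (`"degenerate"`, û = y, zero band).

## Windowing and reconciliation

Noise on real wrists is non-stationary, so the series is segmented into
200-sample windows overlapping by 20 samples (stride 180); the last
window is extended *backward* to full size so the tail is never a tiny
fragment. The AR coefficients are global and fixed; only γ — hence σ̂²
and λ̂² — is re-estimated per window, which is what tracks signal-to-noise
changes. Overlaps are blended with weights from the Gaussian CDF centered
at the overlap midpoint with s.d. = overlap/4 (w ranges ~0.02 → ~0.98;
the pair (1−w, w) sums to one), giving a convex, seam-free transition;
confidence bands are blended with the same weights. The per-sample noise
variance trace is a step function: each window's σ̂² over its exclusive
span, the mean of the two windows over overlaps.

## Noise-model estimation

`fit_ar` uses conditional least squares (no intercept) with a
Yule-Walker fallback for singular designs; σ̂² is the mean square of the
one-step in-sample prediction residuals. A non-stationary fit is
contracted (aᵢ ← aᵢ cⁱ, which scales all polynomial roots by c) to root
modulus 0.99, with a warning. Order selection fits orders 1…max_order,
computes AIC = n·ln σ̂² + 2(order+1), and applies an
autocorrelation-band whiteness test to the innovations: lags
1…min(n/4, 50) against ±z_{0.975}/√n. The pass rule is calibrated
binomially — a series passes if the out-of-band count does not exceed the
upper 95% quantile of Binomial(n_lags, 0.05) — because a fixed "95% of
lags inside" cutoff rejects ~46% of genuinely white series at 50 lags.
The smallest passing order wins; if none passes, the global AIC minimum
is returned with a flag.

## Synthetic benchmark

Real recordings have no ground truth, so benchmarks are built from the
data themselves: (1) a zero-phase (forward-backward) sixth-order
Butterworth low-pass at 0.4 × Nyquist extracts a smooth reference trace
— zero-phase so the reference stays aligned with the raw series, and the
cutoff expressed as a fraction of Nyquist because a 30-s grid leaves no
room for an absolute cutoff in Hz; (2) an AR(20) model is fitted to the
removed residuals; (3) a fresh noise realization is generated from that
model with a *time-varying* driving s.d. σ(t) and added back onto the
reference. The injected level is guided by the fit: σ(t) levels are
multipliers of the fitted innovation s.d. (day 0.5–1.5×, night 1.5–3×,
nights noisier to mimic degraded wrist contact during sleep), smoothed at
transitions and modulated by a smooth log-normal factor. Named presets
`constant` and `step` (exact doubling at n/2) support calibration
experiments. AR noise is simulated as an all-pole filter driven by
σ(k)·z(k) with a 200-sample burn-in discarded.

A fully synthetic raw-trace generator supplies the input when no real
recording is available: a circadian cosine (baseline 70 bpm, amplitude
8 bpm, minimum near 04:00), a slow smoothed random drift (s.d. 2 bpm),
Poisson-placed daytime activity bumps (~4/day, 15–45 bpm, 4–15 min), all
clipped to [40, 180] bpm, plus AR(2) noise (monic coefficients
[−1.0, 0.3]) under the default day/night σ profile. These defaults are
one scientist's notion of a plausible day of ambulatory HR; they emulate
diurnal structure and activity transients but *not* device dropouts,
quantization beyond final integer rounding, or posture artifacts — so
passing tests demonstrate correct behavior under the stated statistical
model, not under every failure mode of a real wrist sensor.

## Evaluation conventions

Method outputs are rounded to integers (halves away from zero) before
scoring, like the sensor's own output; the ground truth is not rounded
(it is not a method output). Metrics: RMSE, MAE (bpm), MARD (%).
Nighttime is the half-open clock interval [00:00, 06:00). Method
comparisons use a two-sided paired t-test on per-sample absolute
residuals; identical residual vectors have zero difference variance and
raise a degenerate-test error rather than fabricating p = 1.

## Problem sizes and numerical choices

Window solves are O(n³) dense Cholesky at n = 200 (~ms each; a full day
of data smooths in ~1 s). The validation suite uses two-day benchmarks
(n = 5760) for metric comparisons, 50 replicates at n = 200 for
parameter recovery and band calibration, and 50 runs at n = 1080 for
step-tracking — sizes at which every Monte-Carlo margin in the tests is
comfortably stable. Determinism: every stochastic routine takes an
explicit seed and uses `numpy.random.default_rng`; benchmark bundles
regenerate bit-identically from (seed, params) and round-trip exactly
through their CSV serialization (`%.17g` writes, round-trip float
parsing).

## Known limitations

- The batch matrix formulation is O(n³) per window; a state-space /
  Kalman reformulation would be O(n) but is deliberately out of scope.
- The AR noise model is global; only its driving variance adapts per
  window. Abrupt changes in noise *color* (not just level) within a
  window are mis-modelled.
- The IRW prior smooths through genuinely fast transients (exercise
  onset); in such stretches the filter attributes real dynamics to
  noise, inflating σ̂² locally.
- Boundary-flagged windows (criterion root outside [10⁻⁶, 10⁸]) return a
  bracket end; their σ̂² is a plug-in value, not a criterion root.
- MARD requires strictly positive truth values (always true for HR).
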