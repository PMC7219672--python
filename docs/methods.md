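# Methods

This note documents the models, estimators and conventions implemented in
`fracfall`, the design choices made where the design was genuinely open,
and what the synthetic benchmark does and does not establish.

## Signal model and preprocessing

The input is a triaxial accelerometer stream in units of g, nominally
32 Hz with a ±8 g full-scale range (values beyond ±8 g raise a warning,
not an error, since the range only describes the emulated sensor). The
orientation-free working signal is the per-sample sum vector
a′ = √(ax² + ay² + az²). Analysis windows are N = 128 samples with 50 %
overlap; the hop is floored to an integer and trailing samples that do not
fill a window are discarded — the pipeline processes fixed-length windows
only, and no padding of the stream is performed. Each window is
zero-meaned (a = a′ − μ_a′); all variances in the package use the unbiased
divisor N − 1.

## Wavelet transform

"Daubechies-4" is taken as the orthonormal 8-tap Daubechies filter with 4
vanishing moments (the filter whose implementation is an eight-term sum of
products), not the 4-tap D4 filter. The highpass is the quadrature mirror
g[k] = (−1)^k h[7−k]. Boundary handling is circular periodisation, so a
level halves the length exactly and a 128-sample window ends, after 4
levels, with 8 approximation and 8 detail coefficients.

The downsampling phase retains the odd-indexed circular-convolution
outputs, A[k] = y[2k+1]. The phase is a free convention; it is frozen
here and used identically by both implementations:

* **reference** — circular convolution with each filter followed by
  dyadic downsampling (the oracle);
* **fused** — only the retained outputs are computed, by striding two
  samples across the signal extended circularly on the left by
  `taps − 2` samples with the filter taps reversed.

The two agree to ≤ 1e−12 on random inputs, and the transform conserves
energy (Σa² = ΣA4² + Σ_i ΣD_i²) to 1e−9 relative, both asserted in tests.
Against PyWavelets' periodised DWT the coefficients agree after rolling
the input back one sample and the outputs by two, with the detail sign
flipped (pywt retains the even phase and uses the opposite highpass sign
convention); this fixed alignment is asserted once in the test suite.

## Wavelet-variance fractal dimension

For the zero-mean window a with variance σ²_a, the power-law spectrum
model S(ω) = σ²_a / ω^β identifies the per-level detail variance with the
spectrum at the dyadic scale 2^i:

    var(D_i) = σ²_a / (2^i)^β,
    β_i  = log2(σ²_a / var(D_i)) / i,
    H_i  = (β_i − 1)/2,
    fd_i = 2 − H_i.

Each level yields an independent feature fd1..fd4; no cross-level
regression is performed, matching the real-time formulation. Detail
variances subtract the level mean and use divisor len−1. fd is *not*
clamped to [1, 2]: it is used as an irregularity feature, not a geometric
dimension. A detail variance below 1e−24 makes the level undefined; the
feature assembly substitutes the sentinel 2.0 (the fd of an uncorrelated
signal) and flags the entry.

**Estimator scope.** The chain H = (β − 1)/2 is the non-stationary
(integrated-signal) relation: it is calibrated for windows whose energy is
concentrated at low frequency, as fall/ADL accelerometer windows are. On
a *stationary* input the per-level estimator is structurally offset — for
white noise an orthonormal transform gives var(D_i) ≈ σ²_a at every
level, hence β̂ ≈ 0 and fd ≈ 2.5, not the 1.5 of the stationary
convention — and the offset log2(σ²_a / C)/i of each level does not
vanish for fractional Gaussian noise either. The per-level fd values are
therefore *discriminative features*, not unbiased Hurst estimates; the
test suite asserts the discriminability (fall windows score systematically
lower fd than ADL windows) and documents, in a deliberately failing
recovery test, that unbiased recovery of H from stationary fGn is not a
property this estimator has.

## ARFIMA fractal analysis

The offline route first-differences the window (the stationarity battery
below justifies this), demeans it, and fits ARFIMA(r, d, q) models:

* **Fractional differencing.** (1 − L)^d is applied by the truncated
  binomial series with weights w0 = 1, w_l = w_{l−1}(l − 1 − d)/l
  (the recursive form of the Gamma-ratio coefficients); the truncation
  defaults to the series length, exact for a finite sample.
* **Estimation.** A two-stage profile likelihood: d is line-searched on
  [−0.49, 0.49] (bounded scalar minimisation, xatol 5e−3); at each
  candidate the fractionally differenced series is fitted with an exact
  maximum-likelihood ARMA(r, q) (statsmodels state-space ARIMA) and the
  profile log-likelihood is maximised. Simulation shows mean d̂ within
  ±0.1 of the truth for ARFIMA(1, 0.3, 1) at n = 2048 over 20 seeds.
* **Model selection.** The full grid r ∈ [0, 4] × q ∈ [0, 4] (25 models)
  is fitted; failed fits are dropped; the minimum-AIC model wins, ties
  broken by smaller r + q, then smaller r. The AIC parameter count is
  k = r + q + 2 (d and the innovation variance are counted).
* **Conversion.** d̃ = d + 1, β = 2d̃, H = (β − 1)/2 = d̃ − 0.5,
  fd = 2 − H; the chain is affine, fd = 1.5 − d, and is asserted to
  machine precision.

Fitted AR/MA polynomials with roots on or inside the unit circle emit a
warning (the optimiser can park at the admissibility boundary).

## Stationarity battery

* **ADF** is the constant-only, no-trend form. The maximum lag is
  Schwert's bound floor(12·(n/100)^¼). Two lag rules are provided: the
  sequential procedure (start at the bound, keep the lag when the last
  included lag's |t| exceeds 1.6, else decrement, floor at 0 — the
  default) and AIC selection; on canonical processes both give the same
  verdicts.
* **KPSS** is the level form with a Newey–West long-run variance. The
  maximum-lag bound is floor(√n); the *working* bandwidth defaults to the
  data-driven Hobijn bandwidth capped at that bound, because fixing the
  bandwidth at the bound itself visibly dilutes power on short series
  (random-walk rejection drops below 90 % at n = 512). A sensitivity mode
  re-runs at +2 and +4 lags.
* **Joint verdict.** "non-stationary" requires ADF fail-to-reject AND
  KPSS reject; "stationary" the converse; disagreement is
  "inconclusive". All decisions are pure functions of (p-value, α) with
  α = 0.05.

On 512-sample simulations, white noise is called stationary by ADF in
≥ 95/100 seeds and by KPSS in ≥ 90/100; random walks fail ADF rejection in
≥ 90/100 and are rejected by KPSS in ≥ 90/100; first differences of walks
are called stationary in ≥ 95/100. On 128-sample *spike* windows the KPSS
statistic is diluted by the impact transient (the spike inflates the
long-run variance), so the strict joint non-stationary verdict is rarely
reached even though ADF cannot reject the unit root on most raw windows;
the battery table reports both legs so this asymmetry is visible.

## Classification

The feature vector is, in fixed order, [A4(1..8), μ_a′, σ²_a′,
fd1..fd4] (14 features). The variance is used rather than the SD — the
algorithm's step list takes precedence over the feature-table caption —
with an SD toggle available. The classifier is the classical two-class
linear discriminant: pooled within-class covariance Σ (ridge-regularised
by 1e−6·trace(Σ)/dim·I when its condition number exceeds 1e10),
w = Σ⁻¹(μ_fall − μ_adl), bias −wᵀ(μ_fall + μ_adl)/2 + ln(π_fall/π_adl)
with empirical priors, and an *inclusive* boundary: wᵀx + b ≥ 0 declares
a fall. Predictions are invariant to common affine feature rescaling and
match scikit-learn's LDA on test problems. Models serialise to a
versioned JSON document (weights, bias, class means, covariance, priors,
feature order).

Evaluation reports the confusion counts and accuracy, sensitivity,
specificity and precision; ratios with zero denominators are reported as
missing rather than 0 or 1. Cross-validation is stratified 5-fold with a
fixed seed (the validation scheme of the original study is unspecified;
stratified k-fold is the conventional choice for a balanced two-class
problem).

## Synthetic data

The generators emulate a pelvis-worn 32 Hz, ±8 g sensor with optional
12-bit quantisation; all outputs are fully determined by the seed.

* **fGn** — exact fractional Gaussian noise by circulant embedding
  (Davies–Harte), falling back to the O(n³) Cholesky construction when an
  embedding eigenvalue is numerically negative. The closed-form
  autocovariance ½(|k+1|^2H − 2|k|^2H + |k−1|^2H) is matched within
  Monte-Carlo bands at small lags.
* **ARFIMA series** — Gaussian innovations, MA-filtered, fractionally
  integrated by the (1 − L)^{−d} binomial weights, AR-recursed; burn-in
  max(500, n/4) discarded; non-stationary AR specifications are rejected.
* **Fall windows** — gravity (1 g) on the vertical axis, per-axis noise
  SD 0.05 g, a slow postural-drift random walk (per-step SD 0.015 g) on
  the vertical axis, a free-fall dip of 0.5–0.9 g lasting 8–16 samples,
  and an impact half-sine of 3–7 g lasting 3–8 samples. The free-fall dip
  precedes the impact, the standard lower-threshold/upper-threshold fall
  signature; the drift is what makes windows read as unit-root processes
  in the battery, as real recordings do.
* **ADL windows** — 2–5 episodes of band-limited Gaussian noise bursts:
  centre frequency 0.5–3 Hz, band 0.5f to min(5f, 14) Hz (2nd-order
  Butterworth), RMS-scaled to 0.3–1.5 g, Hann-windowed, 16–48 samples,
  applied along a random direction with the vertical axis weighted
  double. The wide band gives ADL windows the broadband irregularity
  that distinguishes them from the smooth fall transient.

Morphology parameters were chosen once so that the two classes overlap
slightly: the default 500 + 500 dataset yields stratified 5-fold LDA
accuracy of roughly 0.95–0.98 depending on seed — deliberately short of
1.0 — with the feature-set ablation ordering (fractal-only <
fractal+A4 < full set) preserved.

**What the synthetic benchmark does not show.** The generator reproduces
the morphology classes, not the biomechanics: no orientation change after
impact, no subject variability, no gyroscope channel, no sensor drift or
calibration error, and falls always contain exactly one impact. Passing
the synthetic benchmark therefore demonstrates that the pipeline's
features separate transient-dominated from oscillation-dominated windows
as designed; it does not certify the headline accuracy achievable on
recorded human falls, which depends on an external dataset.

## Problem sizes and numerical choices

The test suite runs at desk scale: 200 random inputs for the
fused/reference equivalence, 100 windows for energy conservation, 100
seeds × n = 512 for the stationarity rates, 20 seeds × n = 2048 for
ARFIMA d recovery, and 500 + 500 windows for the classification
benchmark. Tolerances: 1e−12 absolute for transform equivalence, 1e−9
relative for energy and variance identities, ±0.1 for d recovery, and the
0.95 accuracy floor for the synthetic benchmark. Degenerate inputs are
handled explicitly: constant windows yield undefined fractal levels (and
sentinel features), constant series are rejected by both stationarity
tests, and zero-denominator metrics are reported as missing.

## Known limitations

* The per-level wavelet fd is biased as a Hurst estimator (see above);
  use the ARFIMA route when an unbiased fractal parameter is needed.
* The ARFIMA profile likelihood can be flat in d when AR roots approach
  the unit circle; the bounded search keeps d inside (−0.49, 0.49) and
  boundary fits emit warnings.
* KPSS has little power on short spike-dominated windows, so the strict
  joint non-stationary verdict under-fires there.
* The classifier is linear by design; the feature distributions are
  heavy-tailed (spike amplitudes), which costs a few points of accuracy
  relative to a nonlinear decision rule.
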