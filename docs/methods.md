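# Methods

This note documents the model, the estimators, the numerical choices
and the defaults implemented in `histdep`, and what the synthetic
benchmarks do and do not establish.

## Measures

All quantities are defined on the binarized spike train: the current
bin [t, t + Δt) contributes x = 1 iff it contains at least one spike.
The spiking entropy H(X) is always computed from the closed binary form
with p(spike) = (number of spike bins)/N; it is well sampled and needs
no regularization, so the estimation problem is concentrated entirely
in the conditional (joint and past-marginal) entropies.

* History dependence: R(T) = 1 − H(X | X⁻ᵀ)/H(X), with the past
  represented by a binary word of d bins covering [t − T, t).
* Total history dependence R_tot: the average of R̂(T) over the plateau
  of the estimated curve.  The plateau [T_D, T_max] is bounded by the
  first and last past ranges whose estimates lie within one bootstrap
  standard deviation of the highest estimate; T_D is the temporal
  depth.  (The average runs over all grid points inside the interval.)
* Information timescale: τ_R = Σ T̄ᵢ ΔR(Tᵢ)/Σ ΔR(Tⱼ) − T₀ on the
  monotonized curve.  Noisy estimates are first replaced by the largest
  previous estimate when they fall below it and capped at R̂_tot, so
  the gains are non-negative and vanish once the curve reaches R̂_tot.
  When the curve is already saturated at the first grid point every
  gain is zero and τ̂_R is reported as 0 (the timescale is below the
  grid start).  T₀ = 10 ms by default, excluding refractory and
  burst-mode contributions.
* Time-lagged references: autocorrelation C(T) of the binarized train
  with an exponential-plus-offset fit for τ_C (fitted only at lags
  above T₀; initial guesses from the first fitted coefficient, the
  1/e crossing and the tail quartile mean), and plugin lagged mutual
  information L(T) with the same generalized-timescale functional for
  τ_L.

## Past embedding

Bin widths grow exponentially with the bin index, τⱼ = τ₁·10^((j−1)κ),
with bin 1 adjacent to t (highest resolution on the most recent past)
and τ₁ = T(10^κ − 1)/(10^(dκ) − 1), evaluated in `expm1` form for small
κ.  All intervals are half-open [a, b).  Windows are slid in steps of
Δt starting at t_start + T; the final partial window is discarded
(N = ⌊(T_rec − T)/Δt⌋).  Each past bin's spike count is binarized by
"count strictly greater than that bin's median count over all N
windows"; medians are recomputed for every candidate embedding.  In
the packed word, bit j−1 corresponds to bin j (LSB = most recent).

Candidate grids: d ∈ {1, …, d_max} and n_kappa linearly spaced κ values
in [0, κ_max(d)], where κ_max solves τ₁ = τ₁_min by bisection on
κ ∈ [0, 10] (tolerance 1e−6 on τ₁).  Only κ = 0 is used when the
uniform embedding already has τ₁ ≤ τ₁_min, and κ values closer than
Δκ_min to the previously retained one are dropped.  Argmax ties break
toward the simplest embedding (smallest d, then smallest κ).

Defaults (`AnalysisConfig`): Δt = 5 ms, T grid of 61 log-spaced values
in [10 ms, 5 s], T₀ = 10 ms, n_kappa = 10, τ₁_min = 5 ms, Δκ_min =
0.01, BBC tolerance p = 0.05, 250 bootstrap samples for σ(R̂_max),
block length l = 1/(rΔt).  d_max defaults to 5 past bins — the
practical recommendation, which captures most of the history
dependence at a fraction of the cost — with d_max = 20 the exhaustive
setting.

## Estimators

* ML (plugin): relative frequencies of the observed joint words;
  positively biased for R when undersampled.
* NSB: posterior-mean entropy under a mixture of symmetric Dirichlet
  priors weighted uniformly in the a-priori expected entropy
  ξ(β) = ψ₀(Kβ + 1) − ψ₀(β + 1).  All posterior arithmetic is in nats
  and converted to bits at the boundary.  The 1-D evidence integral is
  evaluated in log-β space by adaptive quadrature on an interval from a
  Gaussian approximation around the integrand maximum (found by a
  coarse log-spaced scan plus bounded 1-D maximization), widened until
  the integrand at the bounds is below 1e−10 of its peak; a
  non-convergent quadrature raises rather than returning silently.
  Alphabet sizes include unobserved outcomes: K = 2^(d+1) for the
  joint, 2^d for the past marginal.
* BBC: the NSB estimate is accepted iff |R̂_NSB − R̂_ML| ≤ p·R̂_NSB,
  otherwise the estimate is 0 and flagged rejected.  If every candidate
  embedding for a past range is rejected, R̂(T) = 0 with an
  all-rejected flag.
* Shuffling: R̂ = [Ĥ_ML(past) − (Ĥ_ML(past|X) − ΔĤ)]/Ĥ(X), where ΔĤ
  is the plugin bias measured on one seeded surrogate obtained by
  permuting each past-bin column within the spike and no-spike classes
  (the number of shuffles is configurable; default 1).  Pairwise
  (x, bit_j) counts are preserved exactly, so for d = 1 the correction
  vanishes and the estimate equals the plugin estimate.  Estimates are
  never floored at 0: the lower-bound semantics are needed during
  maximization.
* GLM: Bernoulli spiking with rate λ = exp(μ + Σ hⱼ xⱼ) and
  p = λΔt/(1 + λΔt) is exactly a logistic regression with a log(Δt)
  offset; fitting delegates to statsmodels (Newton, BFGS fallback under
  separation, coefficients capped at |30| and flagged).  Embedding
  selection minimizes BIC = (d + 1)log₂N − 2L*, with κ set so that
  τ₁ = Δt; R̂_GLM = 1 − (−L*/N)/Ĥ(X).

## Uncertainty and cross-validation

Blocks-of-blocks bootstrap: ⌊N/l⌋ contiguous blocks of length
l = 1/(rΔt) steps are drawn with replacement from all N − l + 1
overlapping start positions.  Confidence intervals use the Gaussian
approximation R̂ ± 2σ̂.  The bias criterion is not re-applied on
resamples: for a BBC analysis the resampled statistic is the NSB
estimate.  σ̂ is computed for the argmax embedding (it defines the
plateau); per-T uncertainties are computed only where reported.

Cross-validation (for short recordings): embeddings are selected on the
first half of the recording and the estimate (NSB for BBC analyses) and
its bootstrap σ̂ are evaluated on the second half, removing the
overfitting that maximization over noisy candidate estimates induces.

## Benchmark simulators

* Binary autoregressive process: activation with probability
  h + (1 − h)·min(1, m·Σ past-l states).  For depth l = 1 the
  stationary activity h/(1 − m + mh), the transition probabilities and
  hence R_tot = I(X_t; X_{t−1})/H(X) are in closed form, and R(T)
  saturates after one step.  For l > 1 the reactivation contributions
  are additive with the probability clipped at 1.
* Subsampled branching process: population activity A_{t+1} ~
  Poisson(mA_t + a(1 − m)) with a = pop_rate·Δt (the drive keeps the
  process off the absorbing state); each event is observed with
  probability p_sub and jittered uniformly within its 4-ms step.
  Defaults m = 0.98, pop_rate = 500 Hz, p_sub = 0.01 give a ~5 Hz
  single train with analytic autocorrelation time −Δt/ln m = 198 ms.
* Adapting neuron (GLIF with spike-frequency adaptation): membrane
  V(t) = V_∞ + (V₀ − V_∞)e^(−γ(t − t̂₀)) between spikes (the exact
  solution of the linear membrane equation, evaluated on the 0.5-ms
  simulation grid — equivalent to and more stable than Runge-Kutta),
  spiking probability λδt per step with
  λ = λ₀ exp((V − V_T)/ΔV), and threshold
  V_T = V_T* + Σ ξ(t − t̂ⱼ) summed event-wise over past spikes using a
  kernel lookup table.  The kernel is constant (a_ξ) up to
  T_ξ = 8.3 ms, then decays as (s/T_ξ)^−0.93 until the cutoff (22 s;
  the 1-s variant uses a_ξ = 35.2 mV).  Parameters are the published
  somatosensory L5 pyramidal-cell fit; the first 100 s are discarded.
  The constant input current is not published and enters only through
  V_∞, so `tune_glif_rate` calibrates a V_∞ offset by bisection on a
  seeded 10-minute run until the firing rate matches the 4 Hz target
  within 1% (the printed V_∞ alone yields ~7–9 Hz under this
  discretization).
* Ground truth: the model's exact conditional spiking probability per
  analysis window, p(x = 0) = Π(1 − λ̃δt) with λ̃ computed from spikes
  strictly before the window start, gives H(X | X⁻∞) and hence the
  exact R_tot (an upper bound for any embedding).  For a specific
  embedding (T, d, κ) the model is near-GLM (the reset term is
  effectively single-spike because ISIs ≫ 1/γ), so the true R(T, d, κ)
  is approximated by fitting a GLM on a training segment and evaluating
  its conditional entropy on a longer recording; the true R(T) curve
  takes the maximum over high-resolution embeddings (nested models, so
  richer embeddings only increase it).

## What the benchmarks do and do not show

The synthetic generators are stationary, single-unit, and free of
recording artifacts: no spike-sorting errors, no non-stationary drive,
no inhomogeneous rates.  Passing the benchmark checks shows that the
estimators are calibrated (BBC unbiased, Shuffling a lower bound, CIs
near nominal coverage) under the models' spiking statistics — spanning
Markovian, population-coupled and long-range-adapting regimes — not
that real recordings satisfy those assumptions.  On experimental data
the embedding model itself (contiguous, exponentially growing bins) can
be insufficient, in which case all estimates remain lower bounds.

## Problem sizes used in the shipped checks

The quantitative acceptance checks run at reduced problem sizes, chosen
once as the package's benchmark configuration:

* autoregressive recovery: 10⁷ steps (≈ 14 h of 5-ms data), T grid
  {10, 20, 40} ms, d ≤ 3, 4 κ values, 50 bootstrap samples;
* branching process: 90 min for the timescale fit (fit tolerance 25%),
  30 min for rate checks (3 analytic SEs including the branching
  autocovariance inflation);
* adapting-neuron benchmark: 40-min recording, 1-s kernel; GLM truth
  trained on the first 15 min and evaluated on the full 40 min; 6 past
  ranges in [10 ms, 1 s], d_max = 5, 4 κ values, 100 bootstrap samples
  per past range;
* short-recording bias: 10 independent 3-min recordings, with and
  without cross-validation, compared to the per-embedding GLM truth
  over the plateau; true τ_R from the GLM-approximated true R(T) with
  d ∈ {10, 20, 40} and τ₁ ≤ 1 ms;
* bootstrap calibration: 25 independent 3-min recordings at a fixed
  optimized embedding, 100 bootstrap samples each, Gaussian ±2σ̂
  intervals.

The NSB implementation is additionally checked against an independent
brute-force quadrature over β ∈ (10⁻⁸, 10⁹) (the wide range matters:
for very small N the integrand tail decays only as 1/β², and a
narrower grid visibly truncates mass).

## Known limitations

* The analysis assumes stationarity; rate drift inflates apparent
  history dependence.
* τ̂_R depends on the recording length (long-T gains are the hardest to
  estimate) — compare timescales only across recordings of similar
  length, and prefer ≥ 10-minute recordings.
* The Δt sweep is not automated; Δt is a configuration parameter
  (default 5 ms).
* GLM-based "truth" for the adapting neuron is itself an approximation
  (excellent in the benchmark's parameter regime, not in general).
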