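# histdep

Estimation of **history dependence** and **information timescales** in
single-neuron spike trains, using optimized binary past embeddings with
bias-safe mutual-information estimators.

## The problem

How much of a neuron's spiking is predictable from its own past, and
over what timescale is that predictive information accumulated?  Given
a stationary spike train discretized in bins of width Δt, the *history
dependence* at past range T is the mutual information between current
spiking X and the spiking history in [t − T, t), normalized by the
spiking entropy:

    R(T) = I(X; X⁻ᵀ) / H(X) = 1 − H(X | X⁻ᵀ) / H(X)  ∈ [0, 1].

R(T) increases monotonically and saturates at the **total history
dependence** R_tot.  From the gains ΔR(Tᵢ) = R(Tᵢ) − R(Tᵢ₋₁) the
**information timescale** is the generalized (gain-weighted) timescale

    τ_R = Σᵢ T̄ᵢ ΔR(Tᵢ) / Σⱼ ΔR(Tⱼ) − T₀,   T̄ᵢ = (Tᵢ + Tᵢ₋₁)/2,

which equals the exponential decay constant when the gains decay
exponentially.  Unlike the autocorrelation C(T) or the lagged mutual
information L(T), which read out single past bins and mix redundant
dependencies into their timescales, R(T) conditions on the entire
more-recent past, separating the *strength* (R_tot) from the
*timescale* (τ_R) of history dependence.

## The method

Estimating I(X; X⁻ᵀ) from limited data requires a reduced
representation of the past: the history in [t − T, t) is binarized into
d bins whose widths grow exponentially with the bin index,
τⱼ = τ₁·10^((j−1)κ).  For each T, the embedding parameters (d, κ) are
**optimized** to maximize the estimated history dependence — which is
only safe if every candidate estimate is unbiased or a lower bound.
Two regularized estimators ensure this:

* **BBC** (Bayesian bias criterion): accepts the Bayesian NSB
  (Dirichlet-mixture) estimate only when it agrees with the plugin (ML)
  estimate to a tolerance p, i.e. |R̂_NSB − R̂_ML| ≤ p·R̂_NSB;
* **Shuffling**: subtracts from the plugin estimate a bias term
  measured on surrogate data in which past bins are shuffled within
  the spike/no-spike classes; a lower bound in leading order of 1/N.

Plugin (ML), NSB and GLM estimators are available as references, with
blocks-of-blocks bootstrap uncertainties, optional cross-validation for
short recordings, and time-lagged comparison measures (C(T), τ_C, L(T),
τ_L).  Benchmark simulators with computable ground truth are included:
a binary autoregressive process, a subsampled branching process, and a
generalized leaky integrate-and-fire neuron with a plateau-then-power-law
spike-frequency-adaptation kernel.

## Worked example

Simulate a binary autoregressive process (depth 1 step, reactivation
m = 0.8, ~5 Hz) and estimate its history dependence:

```bash
$ histdep simulate ar --duration 1800 --seed 42 --out ar_spikes.txt
8657 spikes at 4.81 Hz -> ar_spikes.txt

$ histdep estimate ar_spikes.txt --estimator shuffling --d-max 3 \
      --n-t 6 --t-min 0.01 --t-max 0.08 --seed 42 --out hd_out
R_tot=0.6173  tau_R=2.6 ms  T_D=15 ms  (written to hd_out)
```

The analytic total history dependence of this process is
R_tot = 0.6263 (written to `ar_spikes.json` by the simulator); the
embedding-optimized Shuffling estimate 0.6173 is a tight lower bound.
The process is Markov of depth one 5-ms step, and the estimated
timescale τ_R = 2.6 ms correctly stays below one grid step: the curve
saturates essentially at the first past range.  `hd_out/curve.csv`
holds R̂(T) with the selected embedding (d*, κ*) per past range, and
`hd_out/summary.csv` the derived quantities.

The same analysis runs from the library:

```python
import numpy as np, histdep as hd

train = hd.read_spike_times("ar_spikes.txt")
cfg = hd.AnalysisConfig(estimator="shuffling", d_max=3,
                        t_grid=np.geomspace(0.01, 0.08, 6), seed=42)
curve = hd.compute_R_curve(train, cfg)
print(curve.R_tot, curve.tau_R, curve.T_D)
```

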