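"""History-dependence estimators operating on embedded spike data.

History dependence for a past embedding is the mutual information
between the current spike indicator X and the binary past word,
normalized by the spiking entropy:

    R = 1 - (H(X, past) - H(past)) / H(X).

``H(X)`` in the denominator always uses the closed binary form with
``p(spike)`` equal to the fraction of time bins containing a spike;
it is well sampled and needs no regularization.  The joint and marginal
entropies are estimated either by the plugin (ML) estimator, the
Bayesian NSB estimator, the Bayesian bias criterion (BBC, which accepts
the NSB value only when it agrees with ML to a tolerance), or the
Shuffling estimator (ML minus a surrogate-derived bias bound, giving a
leading-order lower bound).  A generalized linear model with binary past
regressors provides a parametric reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .embedding import (AnalysisConfig, EmbeddedSamples, EmbeddingSpec,
                        SpikeTrain, SymbolCounts, embed_samples,
                        make_embedding, solve_kappa_for_tau1)
from .entropy import (LN2, binary_entropy_bits, entropy_ml, entropy_nsb)

__all__ = [
    "REstimate",
    "SurrogateCorrection",
    "GLMFit",
    "estimate_R_ml",
    "estimate_R_nsb",
    "bbc_estimate",
    "shuffle_surrogate",
    "surrogate_correction",
    "estimate_R_shuffling",
    "fit_glm",
    "glm_log2_likelihood",
    "bic",
    "estimate_R_glm",
    "DEFAULT_GLM_D_SET",
]


@dataclass
class REstimate:
    """A history-dependence estimate for one embedding.

    ``accepted`` is meaningful for the bias criterion only; ``sigma`` is
    filled in by bootstrap resampling where requested.  Shuffling values
    may be slightly negative (lower-bound construction) and are never
    clipped.
    """

    value: float
    method: str
    embedding: EmbeddingSpec | None = None
    accepted: bool | None = None
    sigma: float | None = None
    T: float | None = None

    def __post_init__(self):
        if self.T is None and self.embedding is not None:
            self.T = self.embedding.T


def _h_x_bits(counts: SymbolCounts) -> float:
    h = binary_entropy_bits(counts.p_spike)
    if h == 0.0:
        raise ValueError("spiking entropy is zero (no spikes, or a spike in "
                         "every bin); history dependence is undefined")
    return h


def estimate_R_ml(counts: SymbolCounts, embedding: EmbeddingSpec | None = None) -> REstimate:
    """Plugin estimate: R = 1 - (H_ml(joint) - H_ml(past)) / H(X)."""
    h_x = _h_x_bits(counts)
    h_joint = entropy_ml(counts.joint_counts).value
    h_past = entropy_ml(counts.past_counts()).value
    value = 1.0 - (h_joint - h_past) / h_x
    return REstimate(value=value, method="ml", embedding=embedding)


def estimate_R_nsb(counts: SymbolCounts, embedding: EmbeddingSpec | None = None) -> REstimate:
    """NSB estimate with alphabet sizes 2**(d+1) (joint) and 2**d (past)."""
    h_x = _h_x_bits(counts)
    h_joint = entropy_nsb(counts.joint_counts, K=counts.K_joint, N=counts.N).value
    h_past = entropy_nsb(counts.past_counts(), K=counts.K_past, N=counts.N).value
    value = 1.0 - (h_joint - h_past) / h_x
    return REstimate(value=value, method="nsb", embedding=embedding)


def bbc_estimate(counts: SymbolCounts, p: float = 0.05,
                 embedding: EmbeddingSpec | None = None) -> REstimate:
    """Bayesian bias criterion: accept the NSB estimate if it agrees with ML.

    The estimate is flagged biased (and the value set to 0) when
    ``|R_nsb - R_ml| > p * R_nsb``.
    """
    if p <= 0:
        raise ValueError("tolerance p must be positive")
    r_nsb = estimate_R_nsb(counts, embedding).value
    r_ml = estimate_R_ml(counts, embedding).value
    accepted = abs(r_nsb - r_ml) <= p * r_nsb
    return REstimate(value=r_nsb if accepted else 0.0, method="bbc",
                     embedding=embedding, accepted=bool(accepted))


def shuffle_surrogate(samples: EmbeddedSamples, rng: np.random.Generator) -> np.ndarray:
    """Column-wise within-class permutation of the embedded past bits.

    Past observations of the same bin index are permuted separately among
    measurements followed by a spike and among those followed by no
    spike, which destroys correlations between past bins while exactly
    preserving all pairwise (x, bit_j) counts.
    """
    bits = samples.bits.copy()
    for x_val in (0, 1):
        idx = np.flatnonzero(samples.x == x_val)
        for j in range(samples.d):
            perm = rng.permutation(idx.size)
            bits[idx, j] = bits[idx[perm], j]
    return bits


@dataclass
class SurrogateCorrection:
    """Terms of the surrogate bias correction (all in bits).

    ``delta = H_ml_sh - H_true_sh`` estimates the (negative) plugin bias
    of the conditional past entropy on factorized surrogate data.
    """

    H_ml_cond: float
    H_ml_sh: float
    H_true_sh: float

    @property
    def delta(self) -> float:
        return self.H_ml_sh - self.H_true_sh


def _pairwise_conditional_entropy_bits(samples: EmbeddedSamples) -> float:
    """Sum over past bins of H(bit_j | X) from plugin pairwise probabilities."""
    N = samples.N
    h = 0.0
    for x_val in (0, 1):
        mask = samples.x == x_val
        n_x = int(mask.sum())
        if n_x == 0:
            continue
        ones = samples.bits[mask].sum(axis=0)
        h += n_x / N * sum(binary_entropy_bits(n1 / n_x) for n1 in ones)
    return h


def surrogate_correction(samples: EmbeddedSamples, rng: np.random.Generator,
                         counts: SymbolCounts | None = None) -> SurrogateCorrection:
    if counts is None:
        counts = SymbolCounts.from_samples(samples)
    h_x_ml = binary_entropy_bits(counts.p_spike)
    h_ml_cond = entropy_ml(counts.joint_counts).value - h_x_ml
    sh_bits = shuffle_surrogate(samples, rng)
    sh = EmbeddedSamples(samples.x, sh_bits, samples.emb, samples.medians)
    sh_counts = SymbolCounts.from_samples(sh)
    h_ml_sh = entropy_ml(sh_counts.joint_counts).value - h_x_ml
    h_true_sh = _pairwise_conditional_entropy_bits(samples)
    return SurrogateCorrection(H_ml_cond=h_ml_cond, H_ml_sh=h_ml_sh, H_true_sh=h_true_sh)


def estimate_R_shuffling(samples: EmbeddedSamples, rng: np.random.Generator,
                         n_shuffles: int = 1) -> REstimate:
    """Shuffling estimator: plugin estimate minus a surrogate bias bound.

    R = [H_ml(past) - (H_ml(past|X) - delta)] / H(X) with delta the mean
    surrogate correction over `n_shuffles` seeded permutations (one by
    default).  For d = 1 the correction vanishes by construction and the
    estimate equals the plugin estimate.
    """
    counts = SymbolCounts.from_samples(samples)
    h_x = _h_x_bits(counts)
    h_past = entropy_ml(counts.past_counts()).value
    if samples.d == 1:
        h_x_ml = binary_entropy_bits(counts.p_spike)
        h_cond = entropy_ml(counts.joint_counts).value - h_x_ml
        value = (h_past - h_cond) / h_x
        return REstimate(value=value, method="shuffling", embedding=samples.emb)
    deltas, h_cond = [], None
    for _ in range(n_shuffles):
        corr = surrogate_correction(samples, rng, counts=counts)
        deltas.append(corr.delta)
        h_cond = corr.H_ml_cond
    value = (h_past - (h_cond - float(np.mean(deltas)))) / h_x
    return REstimate(value=value, method="shuffling", embedding=samples.emb)


# ---------------------------------------------------------------------------
# GLM reference estimator


@dataclass
class GLMFit:
    """Fitted spiking GLM: rate lambda = exp(mu + sum_j h_j * bit_j).

    The Bernoulli spike probability per analysis bin is
    ``lambda*dt / (1 + lambda*dt)``, i.e. a logistic model with offset
    ``log(dt)``.  ``log2_likelihood`` is the maximized log-likelihood of
    the fitted data in bits; `separated` flags perfect separation (the
    reported coefficients are then capped, not converged).
    """

    mu: float
    h: np.ndarray
    log2_likelihood: float
    N: int
    separated: bool = False


def fit_glm(samples: EmbeddedSamples, max_coef: float = 30.0) -> GLMFit:
    """Maximum-likelihood fit of the spiking GLM by logistic regression."""
    import statsmodels.api as sm

    X = sm.add_constant(samples.bits.astype(float), has_constant="add")
    y = samples.x.astype(float)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except Exception:
            # singular Hessian under (quasi-)separation: gradient methods
            # still make progress toward the capped solution
            separated = True
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
        params = np.asarray(res.params)
        llf = float(res.llf)
    if np.any(np.abs(params) > max_coef):
        separated = True
        params = np.clip(params, -max_coef, max_coef)
        llf = float(sm.Logit(y, X).loglike(params))
    dt = samples.emb.dt
    mu = params[0] - np.log(dt)  # intercept absorbs the log(dt) offset
    return GLMFit(mu=float(mu), h=params[1:].copy(),
                  log2_likelihood=llf / LN2, N=samples.N, separated=separated)


def glm_log2_likelihood(fit: GLMFit, samples: EmbeddedSamples) -> float:
    """Log2-likelihood of `samples` under a fitted GLM (evaluation data)."""
    dt = samples.emb.dt
    eta = fit.mu + np.log(dt) + samples.bits.astype(float) @ fit.h
    # log p(x=1) = -log(1+e^-eta); log p(x=0) = -log(1+e^eta)
    sgn = np.where(samples.x == 1, 1.0, -1.0)
    return float(-np.sum(np.logaddexp(0.0, -sgn * eta)) / LN2)


def bic(d: int, N: int, log2_likelihood: float) -> float:
    """Bayesian information criterion (d + 1) log2 N - 2 L*."""
    return (d + 1) * np.log2(N) - 2.0 * log2_likelihood


DEFAULT_GLM_D_SET = list(range(1, 21)) + [25, 30, 35, 40, 45, 50]


def estimate_R_glm(spikes: SpikeTrain, T: float, cfg: AnalysisConfig,
                   d_set=None) -> REstimate:
    """GLM estimate of R(T), selecting d (and kappa) by minimum BIC.

    For each candidate dimension the scaling kappa is set so that the
    first past bin has width dt; R = 1 - H_glm / H(X) with
    H_glm = -L*/N from the selected fit.
    """
    if d_set is None:
        d_set = [d for d in DEFAULT_GLM_D_SET if d <= max(cfg.d_set)] or [1]
    best = None
    for d in d_set:
        kappa = solve_kappa_for_tau1(T, d, cfg.dt)
        emb = make_embedding(T, d, kappa, cfg.dt)
        samples = embed_samples(spikes, emb)
        fit = fit_glm(samples)
        score = bic(d, samples.N, fit.log2_likelihood)
        if best is None or score < best[0]:
            best = (score, emb, fit, samples)
    _, emb, fit, samples = best
    h_glm = -fit.log2_likelihood / fit.N
    counts = SymbolCounts.from_samples(samples)
    value = 1.0 - h_glm / _h_x_bits(counts)
    return REstimate(value=value, method="glm", embedding=emb)
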