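"""Entropy estimation from symbol counts: plugin (ML) and Bayesian NSB.

The NSB estimator places a mixture of symmetric Dirichlet priors on the
outcome probabilities, weighted so that the a-priori expected entropy
``xi(beta) = psi0(K*beta + 1) - psi0(beta + 1)`` is uniformly
distributed.  The posterior mean entropy is a one-dimensional integral
over the concentration parameter beta,

    H_NSB = int dbeta  dxi/dbeta * H(beta) * rho(beta, n)
          / int dbeta' dxi/dbeta' * rho(beta', n),

where ``rho`` is proportional to the Dirichlet-multinomial evidence and
``H(beta)`` the posterior mean entropy at fixed beta.  All posterior
arithmetic is carried out in nats (the natural units of the polygamma
functions) and converted to bits at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import gammaln, psi, polygamma

__all__ = [
    "EntropyEstimate",
    "entropy_ml",
    "entropy_ml_nats",
    "entropy_nsb",
    "xi_beta",
    "dxi_dbeta",
    "h_dirichlet_mean",
    "log_evidence",
    "binary_entropy_bits",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class EntropyEstimate:
    """Entropy in bits, with the estimator and sampling context."""

    value: float
    method: str
    K: int
    N: int


def binary_entropy_bits(p: float) -> float:
    """Shannon entropy (bits) of a Bernoulli(p) variable."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def entropy_ml_nats(counts) -> float:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    N = counts.sum()
    if N <= 0:
        raise ValueError("need at least one observation")
    p = counts / N
    return float(-np.sum(p * np.log(p)))


def entropy_ml(counts, K: int | None = None, N: int | None = None) -> EntropyEstimate:
    """Plugin (maximum-likelihood) entropy of a count vector, in bits."""
    counts = np.asarray(counts)
    n_total = int(counts.sum()) if N is None else N
    value = entropy_ml_nats(counts) / LN2
    return EntropyEstimate(value=value, method="ml",
                           K=int(K) if K is not None else int(np.count_nonzero(counts)),
                           N=n_total)


def xi_beta(beta: float, K: int) -> float:
    """A-priori expected entropy (nats) of a symmetric Dirichlet(beta) prior."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(psi(K * beta + 1.0) - psi(beta + 1.0))


def dxi_dbeta(beta: float, K: int) -> float:
    """Derivative of the a-priori expected entropy with respect to beta."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(K * polygamma(1, K * beta + 1.0) - polygamma(1, beta + 1.0))


def h_dirichlet_mean(beta: float, counts: np.ndarray, K: int, N: int) -> float:
    """Posterior mean entropy (nats) at fixed concentration beta.

    The sum runs over all K outcomes; the ``K - len(counts)`` unobserved
    outcomes contribute a common closed-form term.
    """
    counts = np.asarray(counts, dtype=float)
    n0 = K - counts.size
    denom = N + K * beta
    lead = psi(denom + 1.0)
    h = np.sum((counts + beta) / denom * (lead - psi(counts + beta + 1.0)))
    if n0 > 0:
        h += n0 * beta / denom * (lead - psi(beta + 1.0))
    return float(h)


def log_evidence(beta: float, counts: np.ndarray, K: int, N: int) -> float:
    """log rho(beta, n): Dirichlet-multinomial evidence up to a constant.

    Zero-count outcomes drop out of the product, so only the observed
    counts enter the sum.
    """
    counts = np.asarray(counts, dtype=float)
    return float(
        gammaln(K * beta)
        - gammaln(N + K * beta)
        + np.sum(gammaln(counts + beta))
        - counts.size * gammaln(beta)
    )


def _log_weight(log_beta: float, counts, K, N) -> float:
    """Log of the NSB integrand weight dxi/dbeta * rho in log-beta space.

    Includes the +log_beta Jacobian of the substitution beta = exp(t).
    """
    beta = np.exp(log_beta)
    return np.log(dxi_dbeta(beta, K)) + log_evidence(beta, counts, K, N) + log_beta


def entropy_nsb(counts, K: int, N: int | None = None) -> EntropyEstimate:
    """NSB (Dirichlet-mixture Bayesian) entropy estimate, in bits.

    `counts` may omit zero-count outcomes; `K` is the full alphabet size
    including unobserved outcomes.  The beta integral is evaluated by
    adaptive quadrature in log-beta space on an interval found from a
    Gaussian approximation around the maximizer of the integrand, widened
    until the integrand at the bounds falls below 1e-10 of its peak.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if N is None:
        N = int(counts.sum())
    if N < 1:
        raise ValueError("need at least one observation")
    if K < counts.size:
        raise ValueError("K smaller than the number of observed outcomes")
    if K == 1:
        return EntropyEstimate(0.0, "nsb", K, N)

    def g(t):
        return _log_weight(t, counts, K, N)

    # locate the maximum of the integrand: coarse log-spaced scan, then
    # bounded 1-D maximization around the best scan point
    t_scan = np.linspace(np.log(1e-8), np.log(1e4), 120)
    g_scan = np.array([g(t) for t in t_scan])
    i0 = int(np.argmax(g_scan))
    lo = t_scan[max(i0 - 2, 0)]
    hi = t_scan[min(i0 + 2, t_scan.size - 1)]
    res = optimize.minimize_scalar(lambda t: -g(t), bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    t_star = float(res.x)
    g_star = g(t_star)
    # Gaussian width from the numerical curvature at the peak
    eps = 1e-3
    curv = (g(t_star + eps) - 2 * g_star + g(t_star - eps)) / eps**2
    sigma = 1.0 / np.sqrt(-curv) if curv < 0 else 1.0
    log_cut = np.log(1e-10)
    t_lo, t_hi = t_star - 5 * sigma, t_star + 5 * sigma
    for _ in range(60):
        if g(t_lo) - g_star < log_cut:
            break
        t_lo -= 2 * sigma
    for _ in range(60):
        if g(t_hi) - g_star < log_cut:
            break
        t_hi += 2 * sigma

    def w(t):
        return np.exp(g(t) - g_star)

    def wh(t):
        return w(t) * h_dirichlet_mean(np.exp(t), counts, K, N)

    den, den_err = integrate.quad(w, t_lo, t_hi, limit=200)
    num, num_err = integrate.quad(wh, t_lo, t_hi, limit=200)
    if not np.isfinite(den) or den <= 0 or den_err > 1e-6 * max(den, 1e-300):
        raise RuntimeError("NSB quadrature did not converge")
    h_nats = num / den
    return EntropyEstimate(value=h_nats / LN2, method="nsb", K=int(K), N=int(N))
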