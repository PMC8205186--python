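"""Embedding optimization and assembly of the history-dependence curve.

For each past range T the embedding parameters (d, kappa) are optimized
to maximize the regularized estimate of history dependence; the
resulting curve R(T) yields the total history dependence R_tot (the
average over the plateau of the curve) and the information timescale
tau_R (the gain-weighted mean of past-range midpoints minus the starting
range T_0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bootstrap import block_length, blocks_of_blocks_resample, bootstrap_sigma
from .embedding import (AnalysisConfig, EmbeddedSamples, SpikeTrain,
                        SymbolCounts, embed_samples, kappa_grid, make_embedding)
from .estimators import (REstimate, bbc_estimate, estimate_R_ml,
                         estimate_R_nsb, estimate_R_shuffling)

__all__ = [
    "RCurve",
    "optimize_embedding",
    "compute_R_curve",
    "cross_validated_curve",
    "estimate_R_tot",
    "corrected_gains",
    "generalized_timescale",
]


def _rng_for(cfg: AnalysisConfig, *stream) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), *stream])


def _point_estimate(samples: EmbeddedSamples, cfg: AnalysisConfig,
                    rng: np.random.Generator) -> REstimate:
    """Evaluate the configured estimator on one embedded data set."""
    method = cfg.estimator
    if method == "shuffling":
        return estimate_R_shuffling(samples, rng)
    counts = SymbolCounts.from_samples(samples)
    if method == "bbc":
        return bbc_estimate(counts, cfg.bbc_tolerance, samples.emb)
    if method == "ml":
        return estimate_R_ml(counts, samples.emb)
    if method == "nsb":
        return estimate_R_nsb(counts, samples.emb)
    raise ValueError(f"estimator {method!r} is not embedding-optimizable here")


def _bootstrap_fn(cfg: AnalysisConfig):
    """Estimator applied to bootstrap resamples.

    The bias criterion itself is not re-applied on resamples: for a BBC
    analysis the resampled statistic is the NSB estimate.
    """
    if cfg.estimator == "shuffling":
        def fn(s, _rng=np.random.default_rng(cfg.seed % (2**31))):
            return estimate_R_shuffling(s, _rng).value
    elif cfg.estimator in ("bbc", "nsb"):
        def fn(s):
            return estimate_R_nsb(SymbolCounts.from_samples(s)).value
    else:
        def fn(s):
            return estimate_R_ml(SymbolCounts.from_samples(s)).value
    return fn


def candidate_embeddings(T: float, cfg: AnalysisConfig):
    for d in cfg.d_set:
        for kappa in kappa_grid(T, d, cfg):
            yield make_embedding(T, d, kappa, cfg.dt)


def optimize_embedding(spikes: SpikeTrain, T: float, cfg: AnalysisConfig,
                       eval_spikes: SpikeTrain | None = None) -> REstimate:
    """Best regularized estimate over the (d, kappa) grid for one past range.

    Every candidate embedding is evaluated with the configured estimator
    and the maximum is returned (for BBC, the maximum over accepted
    estimates only; if every candidate is rejected the result is 0 with
    ``accepted=False``).  Ties break toward the simplest embedding
    (smallest d, then smallest kappa).  With `eval_spikes` the embedding
    is selected on `spikes` but the returned estimate is recomputed on
    `eval_spikes` (cross-validation).
    """
    best: REstimate | None = None
    for i, emb in enumerate(candidate_embeddings(T, cfg)):
        rng = _rng_for(cfg, int(round(T * 1e6)), i)
        samples = embed_samples(spikes, emb)
        est = _point_estimate(samples, cfg, rng)
        if cfg.estimator == "bbc" and not est.accepted:
            continue
        if best is None or est.value > best.value:
            best = est
    if best is None:  # all candidates rejected by the bias criterion
        emb = make_embedding(T, cfg.d_set[0], 0.0, cfg.dt)
        best = REstimate(value=0.0, method=cfg.estimator, embedding=emb,
                         accepted=False)
    if eval_spikes is not None:
        rng = _rng_for(cfg, int(round(T * 1e6)), 10**6)
        samples = embed_samples(eval_spikes, best.embedding)
        if cfg.estimator == "bbc":
            est = estimate_R_nsb(SymbolCounts.from_samples(samples), best.embedding)
        else:
            est = _point_estimate(samples, cfg, rng)
        est.accepted = best.accepted
        best = est
    return best


@dataclass
class RCurve:
    """Embedding-optimized history dependence over a grid of past ranges."""

    T: np.ndarray
    R: np.ndarray
    estimates: list = field(repr=False)
    sigma_R_max: float | None = None
    R_tot: float | None = None
    T_D: float | None = None
    T_max: float | None = None
    tau_R: float | None = None

    @property
    def R_max(self) -> float:
        return float(np.max(self.R))

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.R))

    def best_embeddings(self):
        return [e.embedding for e in self.estimates]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "T": self.T,
            "R_hat": self.R,
            "sigma": [e.sigma if e.sigma is not None else np.nan for e in self.estimates],
            "d_star": [e.embedding.d if e.embedding else -1 for e in self.estimates],
            "kappa_star": [e.embedding.kappa if e.embedding else np.nan for e in self.estimates],
        })


def estimate_R_tot(curve: RCurve) -> tuple[float, float, float]:
    """Plateau average of the curve: (R_tot, T_D, T_max).

    The plateau is bounded by the first and last past ranges whose
    estimates lie within one standard deviation of the highest estimate;
    R_tot averages the estimates over that interval.
    """
    if curve.T.size == 0:
        raise ValueError("empty curve")
    sigma = curve.sigma_R_max or 0.0
    thresh = curve.R_max - sigma
    in_plateau = curve.R >= thresh
    idx = np.flatnonzero(in_plateau)
    i_lo, i_hi = idx[0], idx[-1]
    r_tot = float(np.mean(curve.R[i_lo:i_hi + 1]))
    return r_tot, float(curve.T[i_lo]), float(curve.T[i_hi])


def corrected_gains(T: np.ndarray, R: np.ndarray, R_tot: float) -> np.ndarray:
    """Non-negative gains from a noisy estimate curve.

    Estimates are replaced by the largest previous estimate when they
    fall below it (running maximum) and capped at R_tot when they exceed
    it; the gains are the differences of the corrected curve, so they are
    non-negative and vanish beyond the first past range reaching R_tot.
    """
    corrected = np.minimum(np.maximum.accumulate(np.asarray(R, dtype=float)), R_tot)
    return np.diff(corrected)


def generalized_timescale(T_points, gains, T0: float) -> float:
    """Gain-weighted mean of past-range midpoints minus the starting range.

    tau = sum_i Tbar_i * g_i / sum_j g_j - T0 with
    Tbar_i = (T_i + T_{i-1}) / 2.  `T_points` are the n+1 ascending past
    ranges starting at T0; `gains` are the n non-negative interval gains.
    Equals the decay constant when the gains decay exponentially and the
    grid is dense.
    """
    T_points = np.asarray(T_points, dtype=float)
    gains = np.asarray(gains, dtype=float)
    if gains.size != T_points.size - 1:
        raise ValueError("need one gain per interval between past ranges")
    if np.any(gains < 0):
        raise ValueError("gains must be non-negative")
    total = gains.sum()
    if total <= 0:
        raise ValueError("all gains are zero; the timescale is undefined")
    midpoints = 0.5 * (T_points[1:] + T_points[:-1])
    return float(np.sum(midpoints * gains) / total - T0)


def _finalize_curve(curve: RCurve, samples_max: EmbeddedSamples,
                    cfg: AnalysisConfig, rate: float) -> RCurve:
    """Bootstrap sigma at the maximum, then plateau, gains and timescale."""
    fn = _bootstrap_fn(cfg)
    l = cfg.block_length or block_length(rate, cfg.dt)
    rng = _rng_for(cfg, 7, 7)
    curve.sigma_R_max = bootstrap_sigma(samples_max, fn, l,
                                        cfg.n_bootstraps_r_max, rng)
    curve.estimates[curve.argmax].sigma = curve.sigma_R_max
    curve.R_tot, curve.T_D, curve.T_max = estimate_R_tot(curve)
    gains = corrected_gains(curve.T, curve.R, curve.R_tot)
    try:
        curve.tau_R = generalized_timescale(curve.T, gains, curve.T[0])
    except ValueError:
        # saturated at the first past range: no gain beyond T_0
        curve.tau_R = 0.0
    return curve


def compute_R_curve(spikes: SpikeTrain, cfg: AnalysisConfig) -> RCurve:
    """Embedding-optimized R(T) over cfg.t_grid, with R_tot, T_D and tau_R.

    The bootstrap standard deviation is computed for the argmax
    embedding only (it defines the plateau); per-T uncertainties can be
    added separately where needed.
    """
    if cfg.cross_validated:
        return cross_validated_curve(spikes, cfg)
    estimates = [optimize_embedding(spikes, T, cfg) for T in cfg.t_grid]
    curve = RCurve(T=np.asarray(cfg.t_grid, dtype=float),
                   R=np.array([e.value for e in estimates]), estimates=estimates)
    samples_max = embed_samples(spikes, estimates[curve.argmax].embedding)
    return _finalize_curve(curve, samples_max, cfg, spikes.rate)


def cross_validated_curve(spikes: SpikeTrain, cfg: AnalysisConfig) -> RCurve:
    """Optimize embeddings on the first half, evaluate on the second half."""
    mid = spikes.t_start + spikes.duration / 2.0
    train = spikes.restrict(spikes.t_start, mid)
    evaln = spikes.restrict(mid, spikes.t_end)
    estimates = [optimize_embedding(train, T, cfg, eval_spikes=evaln)
                 for T in cfg.t_grid]
    curve = RCurve(T=np.asarray(cfg.t_grid, dtype=float),
                   R=np.array([e.value for e in estimates]), estimates=estimates)
    samples_max = embed_samples(evaln, estimates[curve.argmax].embedding)
    return _finalize_curve(curve, samples_max, cfg, evaln.rate)
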