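"""Time-lagged comparison measures: autocorrelation and lagged MI.

Classical measures of temporal dependence quantify how spiking relates
to a *single* past bin at lag T: the autocorrelation C(T) (normalized
autocovariance of the binarized spike train) and the lagged mutual
information L(T).  Their timescales come from an exponential-with-offset
fit (tau_C) and from the generalized timescale applied to L (tau_L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .embedding import SpikeTrain
from .pipeline import generalized_timescale

__all__ = [
    "LaggedCurve",
    "binarize",
    "autocorrelation",
    "fit_autocorrelation_time",
    "lagged_mi",
    "generalized_timescale_L",
]


@dataclass
class LaggedCurve:
    """Values of a time-lagged measure on a grid of lags (seconds)."""

    lags: np.ndarray
    values: np.ndarray
    kind: str  # "autocorrelation" or "lagged_mi"
    normalized: bool = False
    fit: dict = field(default_factory=dict)


def binarize(spikes: SpikeTrain, dt: float) -> np.ndarray:
    """Binary series: 1 iff at least one spike per dt bin."""
    n = int(np.floor(spikes.duration / dt))
    idx = np.floor((spikes.times - spikes.t_start) / dt).astype(int)
    x = np.zeros(n, dtype=np.uint8)
    x[idx[idx < n]] = 1
    return x


def autocorrelation(spikes: SpikeTrain, dt: float, max_lag: float = 2.5) -> LaggedCurve:
    """Normalized autocovariance of the binarized train at multiples of dt."""
    x = binarize(spikes, dt).astype(float)
    x -= x.mean()
    var = np.dot(x, x) / x.size
    if var <= 0:
        raise ValueError("zero variance: constant binarized series")
    n_lags = int(np.floor(max_lag / dt))
    lags = dt * np.arange(1, n_lags + 1)
    vals = np.empty(n_lags)
    for k in range(1, n_lags + 1):
        vals[k - 1] = np.dot(x[k:], x[:-k]) / (x.size - k) / var
    return LaggedCurve(lags=lags, values=vals, kind="autocorrelation")


def _exp_offset(T, A, tau, O):
    return A * np.exp(-T / tau) + O


def fit_autocorrelation_time(curve: LaggedCurve, T0: float = 0.010) -> float:
    """Least-squares fit C(T) = A exp(-T/tau) + O over lags above T0.

    Initial guesses: A from the first fitted coefficient, tau from where
    the curve drops below A/e, O from the mean of the last quartile; tau
    is constrained positive.
    """
    mask = curve.lags > T0
    T, C = curve.lags[mask], curve.values[mask]
    if T.size < 4:
        raise ValueError("too few lags above T0 to fit")
    O0 = float(np.mean(C[-max(1, C.size // 4):]))
    A0 = float(C[0] - O0) or 1e-3
    below = np.flatnonzero(C - O0 < A0 / np.e)
    tau0 = float(T[below[0]] - T[0]) if below.size else float(T[-1] - T[0])
    tau0 = max(tau0, curve.lags[0])
    try:
        popt, _ = curve_fit(_exp_offset, T, C, p0=(A0, tau0, O0),
                            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError("autocorrelation fit did not converge") from err
    curve.fit.update(A=float(popt[0]), tau_C=float(popt[1]), O=float(popt[2]))
    return float(popt[1])


def _plugin_mi_2x2(joint: np.ndarray) -> float:
    """Plugin mutual information (bits) of a 2x2 joint count/probability table."""
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def lagged_mi(spikes: SpikeTrain, dt: float, lags, normalize: bool = False) -> LaggedCurve:
    """Plugin MI between bins separated by each lag (multiples of dt).

    With ``normalize=True`` the values are divided by the plugin spiking
    entropy H(X), making L(T) comparable to the history-dependence gain.
    """
    x = binarize(spikes, dt)
    lags = np.asarray(lags, dtype=float)
    steps = np.round(lags / dt).astype(int)
    if np.any(steps < 1):
        raise ValueError("lags must be at least one dt step")
    p1 = x.mean()
    h_x = 0.0 if p1 in (0.0, 1.0) else -(p1 * np.log2(p1) + (1 - p1) * np.log2(1 - p1))
    if normalize and h_x == 0.0:
        raise ValueError("zero spiking entropy")
    vals = np.empty(lags.size)
    for i, k in enumerate(steps):
        a, b = x[k:], x[:-k]
        joint = np.zeros((2, 2))
        for xa in (0, 1):
            for xb in (0, 1):
                joint[xa, xb] = np.count_nonzero((a == xa) & (b == xb))
        vals[i] = _plugin_mi_2x2(joint)
    if normalize:
        vals /= h_x
    return LaggedCurve(lags=dt * steps, values=vals, kind="lagged_mi",
                       normalized=normalize)


def generalized_timescale_L(curve: LaggedCurve, T0: float = 0.010) -> float:
    """Generalized timescale of the lagged MI: L-weighted mean of midpoints.

    Lags at or below T0 are excluded; the weights are the L(T) values at
    the remaining lags.
    """
    mask = curve.lags > T0
    lags = curve.lags[mask]
    vals = np.clip(curve.values[mask], 0.0, None)
    T_points = np.concatenate([[T0], lags])
    return generalized_timescale(T_points, vals, T0)
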