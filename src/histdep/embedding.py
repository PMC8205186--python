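"""Spike trains, binary past embeddings and joint symbol counts.

History dependence is estimated from the joint statistics of current
spiking in a small bin ``dt`` and a binarized representation of the
spiking history in a past window ``[t - T, t)``.  The past window is
partitioned into ``d`` bins whose widths grow exponentially with the bin
index, ``tau_j = tau_1 * 10**((j - 1) * kappa)``, where bin ``j = 1`` is
the bin adjacent to ``t`` (most recent past).  The window is slid through
the recording in steps of ``dt`` and each position contributes one
measurement ``(x, w)`` of the current spike indicator and the binary past
word.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpikeTrain",
    "AnalysisConfig",
    "EmbeddingSpec",
    "EmbeddedSamples",
    "SymbolCounts",
    "make_embedding",
    "kappa_grid",
    "solve_kappa_for_tau1",
    "embed_samples",
    "embed_spike_train",
    "read_spike_times",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds) within a recording ``[t_start, t_end)``."""

    times: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError("spike times must be sorted ascending")
            if times[0] < self.t_start or times[-1] >= self.t_end:
                raise ValueError("spike times must lie within [t_start, t_end)")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return self.n_spikes / self.duration

    @classmethod
    def from_times(cls, times, t_start=None, t_end=None, pad=0.0) -> "SpikeTrain":
        times = np.sort(np.asarray(times, dtype=float))
        if t_start is None:
            t_start = (times[0] if times.size else 0.0) - pad
        if t_end is None:
            t_end = (times[-1] if times.size else 1.0) + pad + 1e-9
        return cls(times, float(t_start), float(t_end))

    def restrict(self, t_start: float, t_end: float) -> "SpikeTrain":
        """Sub-train on ``[t_start, t_end)``, keeping times absolute."""
        lo, hi = np.searchsorted(self.times, [t_start, t_end])
        return SpikeTrain(self.times[lo:hi], t_start, t_end)

    def shifted(self, offset: float) -> "SpikeTrain":
        return SpikeTrain(self.times + offset, self.t_start + offset, self.t_end + offset)


def read_spike_times(path, unit_id=None) -> SpikeTrain:
    """Read spike times from a plain text file (one time in seconds per line).

    A two-column dialect ``unit_id time`` is also accepted; `unit_id`
    selects the unit (required if the file contains several).
    """
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] == 1:
        times = data[:, 0]
    elif data.shape[1] == 2:
        units = data[:, 0].astype(int)
        if unit_id is None:
            uniq = np.unique(units)
            if uniq.size > 1:
                raise ValueError(f"multi-unit file; pass unit_id (available: {uniq.tolist()})")
            unit_id = uniq[0]
        times = data[units == unit_id, 1]
    else:
        raise ValueError("expected 1 or 2 columns")
    return SpikeTrain.from_times(times, pad=0.0)


def _default_t_grid() -> np.ndarray:
    return np.geomspace(0.01, 5.0, 61)


@dataclass
class AnalysisConfig:
    """Analysis settings.

    Defaults follow the standard embedding-optimization settings:
    ``dt`` = 5 ms, ten linearly spaced scaling exponents per dimension,
    minimum first-bin width equal to ``dt``, minimum kappa spacing 0.01,
    bias-criterion tolerance ``p`` = 0.05 and 250 bootstrap samples for
    the plateau standard deviation.  ``d_max`` defaults to 5 past bins
    (the practical recommendation); use 20 for an exhaustive analysis.
    """

    dt: float = 0.005
    t_grid: np.ndarray = field(default_factory=_default_t_grid)
    t0: float = 0.010
    d_max: int = 5
    d_set: list | None = None
    n_kappa: int = 10
    tau1_min: float = 0.005
    dkappa_min: float = 0.01
    bbc_tolerance: float = 0.05
    n_bootstraps_r_max: int = 250
    block_length: int | None = None
    cross_validated: bool = False
    estimator: str = "shuffling"
    seed: int = 42

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.d_set is None:
            self.d_set = list(range(1, self.d_max + 1))
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.estimator not in {"bbc", "shuffling", "ml", "nsb", "glm"}:
            raise ValueError(f"unknown estimator {self.estimator!r}")

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Binary past embedding: past range ``T``, ``d`` bins, scaling ``kappa``.

    ``tau`` holds the bin widths ``tau_1 .. tau_d`` with ``tau[0]`` the
    most recent bin (adjacent to ``t``); widths grow by a factor
    ``10**kappa`` per step into the past and sum to ``T``.
    """

    T: float
    d: int
    kappa: float
    dt: float
    tau: np.ndarray = field(default=None, compare=False)

    @property
    def tau1(self) -> float:
        return float(self.tau[0])

    @property
    def edges(self) -> np.ndarray:
        """Cumulative offsets back from ``t``: [0, tau_1, tau_1+tau_2, ..., T]."""
        return np.concatenate([[0.0], np.cumsum(self.tau)])


def make_embedding(T: float, d: int, kappa: float, dt: float) -> EmbeddingSpec:
    """Build an exponential past embedding.

    ``tau_1 = T (10**kappa - 1) / (10**(d*kappa) - 1)`` for ``kappa > 0``,
    ``T/d`` otherwise; ``tau_j = tau_1 * 10**((j-1)*kappa)``.
    """
    if T <= 0:
        raise ValueError("past range T must be positive")
    if d < 1:
        raise ValueError("need at least one past bin")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    j = np.arange(d)
    if kappa == 0 or d == 1:
        tau1 = T / d
    else:
        # expm1 form of T (10^k - 1)/(10^(d k) - 1), stable for tiny kappa
        ln10 = np.log(10.0)
        tau1 = T * np.expm1(kappa * ln10) / np.expm1(d * kappa * ln10)
    tau = tau1 * 10.0 ** (j * kappa)
    # guard against accumulated rounding: rescale to sum exactly to T
    tau *= T / tau.sum()
    return EmbeddingSpec(T=float(T), d=int(d), kappa=float(kappa), dt=float(dt), tau=tau)


def _tau1(T: float, d: int, kappa: float) -> float:
    if kappa == 0:
        return T / d
    return T * (10.0**kappa - 1.0) / (10.0 ** (d * kappa) - 1.0)


def solve_kappa_for_tau1(T: float, d: int, tau1_target: float,
                         tol: float = 1e-6, kappa_hi: float = 10.0) -> float:
    """Kappa such that the first (most recent) bin has width ``tau1_target``.

    ``tau_1`` decreases monotonically with kappa; solved by bisection on
    ``[0, kappa_hi]`` to tolerance `tol` on ``tau_1``.  Returns 0 when even
    the uniform embedding has ``tau_1 <= tau1_target``.
    """
    if d == 1:
        return 0.0
    if _tau1(T, d, 0.0) <= tau1_target:
        return 0.0
    lo, hi = 0.0, kappa_hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        t1 = _tau1(T, d, mid)
        if abs(t1 - tau1_target) < tol:
            return mid
        if t1 > tau1_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def kappa_grid(T: float, d: int, cfg: AnalysisConfig) -> np.ndarray:
    """Candidate scaling exponents for a given past range and dimension.

    ``n_kappa`` linearly spaced values in ``[0, kappa_max]`` where
    ``kappa_max`` yields a first-bin width of ``tau1_min``.  Only ``{0}``
    is returned when the uniform embedding already has
    ``tau_1 <= tau1_min``; values closer than ``dkappa_min`` to the
    previously retained value are dropped.
    """
    if d == 1 or _tau1(T, d, 0.0) <= cfg.tau1_min:
        return np.array([0.0])
    kappa_max = solve_kappa_for_tau1(T, d, cfg.tau1_min)
    values = np.linspace(0.0, kappa_max, cfg.n_kappa)
    kept = [values[0]]
    for v in values[1:]:
        if v - kept[-1] >= cfg.dkappa_min:
            kept.append(v)
    return np.array(kept)


@dataclass
class EmbeddedSamples:
    """Per-measurement current bits and binary past words.

    ``x[n]`` indicates at least one spike in ``[t_n, t_n + dt)``;
    ``bits[n, j]`` is the binarized spike count of past bin ``j`` (column
    0 = most recent).  ``medians[j]`` is the per-bin median raw count used
    for binarization (count > median maps to 1).
    """

    x: np.ndarray
    bits: np.ndarray
    emb: EmbeddingSpec
    medians: np.ndarray

    @property
    def N(self) -> int:
        return int(self.x.size)

    @property
    def d(self) -> int:
        return int(self.bits.shape[1])

    def word_codes(self) -> np.ndarray:
        """Past words packed as integers; bit j (LSB = most recent bin)."""
        codes = np.zeros(self.N, dtype=np.int64)
        for j in range(self.d):
            codes |= self.bits[:, j].astype(np.int64) << j
        return codes

    def subset(self, idx: np.ndarray) -> "EmbeddedSamples":
        return EmbeddedSamples(self.x[idx], self.bits[idx], self.emb, self.medians)


@dataclass
class SymbolCounts:
    """Sparse frequency table of joint (current bit, past word) outcomes.

    ``codes`` are unique joint patterns packed as ``word | (x << d)``;
    the alphabet sizes ``K_joint = 2**(d+1)`` and ``K_past = 2**d`` count
    all possible outcomes, observed or not.
    """

    d: int
    N: int
    codes: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if self.counts.sum() != self.N:
            raise ValueError("counts must sum to N")
        if np.any(self.counts < 0):
            raise ValueError("negative count")

    @property
    def K_joint(self) -> int:
        return 2 ** (self.d + 1)

    @property
    def K_past(self) -> int:
        return 2**self.d

    @property
    def joint_counts(self) -> np.ndarray:
        return self.counts

    def past_counts(self) -> np.ndarray:
        """Marginal counts over past words (x summed out)."""
        words = self.codes & ((1 << self.d) - 1)
        _, inv = np.unique(words, return_inverse=True)
        out = np.zeros(inv.max() + 1, dtype=np.int64)
        np.add.at(out, inv, self.counts)
        return out

    @property
    def n_spike(self) -> int:
        """Number of measurements with a spike in the current bin."""
        return int(self.counts[(self.codes >> self.d) == 1].sum())

    @property
    def p_spike(self) -> float:
        return self.n_spike / self.N

    @classmethod
    def from_samples(cls, samples: EmbeddedSamples) -> "SymbolCounts":
        return cls.from_arrays(samples.x, samples.word_codes(), samples.d)

    @classmethod
    def from_arrays(cls, x: np.ndarray, word_codes: np.ndarray, d: int) -> "SymbolCounts":
        joint = word_codes | (x.astype(np.int64) << d)
        if d <= 21:  # dense counting is much faster than sorting
            dense = np.bincount(joint, minlength=2 ** (d + 1))
            codes = np.flatnonzero(dense)
            counts = dense[codes]
        else:
            codes, counts = np.unique(joint, return_counts=True)
        return cls(d=d, N=int(x.size), codes=codes.astype(np.int64),
                   counts=counts.astype(np.int64))


def embed_samples(spikes: SpikeTrain, emb: EmbeddingSpec) -> EmbeddedSamples:
    """Slide the past window through the recording and binarize.

    The window start positions are ``t_n = t_start + T + n*dt`` for
    ``n = 0 .. N-1`` with ``N = floor((T_rec - T)/dt)`` (the final partial
    window is discarded).  The current bit is 1 iff at least one spike
    falls in ``[t_n, t_n + dt)``; each past bin count is binarized by
    "count strictly greater than that bin's median count over all N
    measurements" (for sparse bins with median 0, any spike maps to 1).
    """
    T = emb.T
    if T >= spikes.duration:
        raise ValueError("past range must be shorter than the recording")
    N = int(np.floor((spikes.duration - T) / emb.dt))
    if N < 1:
        raise ValueError("recording too short for this past range and dt")
    t_n = spikes.t_start + T + emb.dt * np.arange(N)
    times = spikes.times
    # boundary offsets back from t_n, from the oldest edge (T) to 0
    edges = emb.edges  # [0, tau_1, ..., T]; edges[j] is the recent edge of bin j+1
    idx_prev = np.searchsorted(times, t_n - edges[emb.d])  # oldest boundary
    bits = np.empty((N, emb.d), dtype=np.uint8)
    medians = np.empty(emb.d)
    for j in range(emb.d - 1, -1, -1):  # from oldest bin to most recent
        idx = np.searchsorted(times, t_n - edges[j])
        counts_j = (idx - idx_prev).astype(np.int32)
        medians[j] = np.median(counts_j)
        bits[:, j] = counts_j > medians[j]
        idx_prev = idx
    idx_cur = np.searchsorted(times, t_n + emb.dt)
    x = (idx_cur - idx_prev > 0).astype(np.uint8)
    return EmbeddedSamples(x=x, bits=bits, emb=emb, medians=medians)


def embed_spike_train(spikes: SpikeTrain, emb: EmbeddingSpec) -> SymbolCounts:
    """Reduce a recording to joint (current bit, past word) counts."""
    return SymbolCounts.from_samples(embed_samples(spikes, emb))
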