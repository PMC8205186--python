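"""Benchmark spike-train generators with computable ground truth.

Three generative models whose history dependence is known or directly
computable:

* a binary autoregressive process (activation by external input with
  probability h, or by internal reactivation driven by activity in the
  past l steps) -- for l = 1 all stationary probabilities are in closed
  form;
* a subsampled branching process (population activity A_t evolving as a
  Poisson branching process with parameter m, observed through binomial
  subsampling) -- the population autocorrelation decays as m^k, giving
  the analytic autocorrelation time -dt/ln(m);
* a generalized leaky integrate-and-fire neuron whose firing threshold
  is raised by a plateau-then-power-law adaptation kernel summed over
  past spikes (spike-frequency adaptation).  The conditional spiking
  probability used in the simulation gives the model's exact total
  history dependence; a GLM fitted to long simulations approximates the
  true R for any particular past embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .embedding import (EmbeddingSpec, SpikeTrain, SymbolCounts,
                        embed_samples, make_embedding, solve_kappa_for_tau1)
from .entropy import binary_entropy_bits
from .estimators import GLMFit, fit_glm, glm_log2_likelihood

__all__ = [
    "ARParams", "BranchingParams", "GLIFParams", "glif_params_1s",
    "simulate_binary_ar", "ar_analytic_stats", "ar_spike_train",
    "simulate_branching_subsampled",
    "simulate_glif", "glif_true_R", "conditional_entropy_from_rates",
    "glm_R_for_embedding", "glm_ground_truth_R", "tune_glif_rate",
]


# ---------------------------------------------------------------------------
# Binary autoregressive process


@dataclass(frozen=True)
class ARParams:
    """Binary autoregressive process parameters.

    ``h``: external activation probability per step; ``m``: increase of
    the reactivation probability per active state in the past ``l``
    steps; ``dt``: step size in seconds.
    """

    h: float
    m: float
    l: int = 1
    dt: float = 0.005

    def __post_init__(self):
        if not 0 < self.h < 1:
            raise ValueError("h must be in (0, 1)")
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if self.l < 1:
            raise ValueError("temporal depth l must be at least 1")


@njit(cache=True)
def _ar_core(n_steps, h, m, l, seed):
    np.random.seed(seed)
    x = np.zeros(n_steps, dtype=np.uint8)
    for t in range(n_steps):
        s = 0
        lo = t - l if t >= l else 0
        for j in range(lo, t):
            s += x[j]
        p_react = m * s
        if p_react > 1.0:
            p_react = 1.0
        p = h + (1.0 - h) * p_react
        if np.random.random() < p:
            x[t] = 1
    return x


def simulate_binary_ar(params: ARParams, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate the binary series x_t.

    Activation probability per step: h + (1 - h) * min(1, m * sum of the
    past l states); for l = 1 this is p(1|1) = h + (1-h) m and
    p(1|0) = h.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    return _ar_core(n_steps, params.h, params.m, params.l, seed)


def ar_spike_train(x: np.ndarray, dt: float) -> SpikeTrain:
    """Spike train with one spike at the center of each active step."""
    times = (np.flatnonzero(x) + 0.5) * dt
    return SpikeTrain(times, 0.0, x.size * dt)


def ar_analytic_stats(params: ARParams) -> tuple[float, float, float]:
    """Exact (p_active, R_tot, I_tot) for the depth-1 process.

    Stationary activity p = h / (1 - m + m h); the joint of consecutive
    states follows from the transition probabilities, and R_tot is the
    mutual information I(X_t; X_{t-1}) over the binary entropy H(X_t).
    The process is Markov of order one, so R(T) saturates after a single
    step.
    """
    if params.l != 1:
        raise ValueError("closed form available for l = 1 only")
    h, m = params.h, params.m
    p1 = h / (1.0 - m + m * h)
    p11 = h + (1.0 - h) * m  # p(x_t=1 | x_{t-1}=1)
    p10 = h                  # p(x_t=1 | x_{t-1}=0)
    joint = np.array([
        [(1 - p1) * (1 - p10), (1 - p1) * p10],
        [p1 * (1 - p11), p1 * p11],
    ])  # joint[prev, cur]
    h_x = binary_entropy_bits(p1)
    pc = joint.sum(axis=0)
    pp = joint.sum(axis=1)
    i_tot = 0.0
    for a in (0, 1):
        for b in (0, 1):
            if joint[a, b] > 0:
                i_tot += joint[a, b] * np.log2(joint[a, b] / (pp[a] * pc[b]))
    r_tot = i_tot / h_x if h_x > 0 else 0.0
    return p1, r_tot, i_tot


# ---------------------------------------------------------------------------
# Subsampled branching process


@dataclass(frozen=True)
class BranchingParams:
    """Branching process observed through a single subsampled spike train.

    ``m``: branching parameter (autocovariance decays as m^k);
    ``pop_rate``: stationary population rate in Hz (mean activity per
    step a = pop_rate * dt, maintained by the drive a * (1 - m));
    ``p_sub``: per-event subsampling probability.
    """

    m: float = 0.98
    pop_rate: float = 500.0
    dt: float = 0.004
    p_sub: float = 0.01

    def __post_init__(self):
        if not 0 < self.m < 1:
            raise ValueError("m must be in (0, 1)")
        if not 0 < self.p_sub <= 1:
            raise ValueError("p_sub must be in (0, 1]")

    @property
    def tau_C(self) -> float:
        """Analytic autocorrelation time -dt/ln(m), seconds."""
        return -self.dt / np.log(self.m)


def simulate_branching_subsampled(params: BranchingParams, duration: float,
                                  rng: np.random.Generator,
                                  return_activity: bool = False):
    """Simulate population activity and subsample a single spike train.

    A_{t+1} ~ Poisson(m A_t + a(1-m)) with a = pop_rate * dt; each
    population event is observed with probability p_sub and observed
    events are jittered uniformly within their time step.
    """
    n_steps = int(np.floor(duration / params.dt))
    a = params.pop_rate * params.dt
    drive = a * (1.0 - params.m)
    activity = np.empty(n_steps, dtype=np.int64)
    A = rng.poisson(a)
    for t in range(n_steps):
        A = rng.poisson(params.m * A + drive)
        activity[t] = A
    sub_counts = rng.binomial(activity, params.p_sub)
    spike_bins = np.repeat(np.arange(n_steps), sub_counts)
    times = np.sort((spike_bins + rng.random(spike_bins.size)) * params.dt)
    train = SpikeTrain(times, 0.0, n_steps * params.dt)
    if return_activity:
        return train, activity
    return train


# ---------------------------------------------------------------------------
# Generalized leaky integrate-and-fire neuron with adaptation


@dataclass(frozen=True)
class GLIFParams:
    """Leaky integrate-and-fire neuron with a soft threshold and adaptation.

    Between spikes the membrane relaxes as
    ``V(t) = V_inf + (V_0 - V_inf) exp(-gamma (t - t_last))`` and spiking
    is an inhomogeneous Bernoulli process with rate
    ``lambda = lambda0 exp((V - V_T)/dV)``.  Each emitted spike raises
    the threshold by an adaptation kernel that is constant at ``a_xi``
    for ``T_xi`` = 8.3 ms and then decays as a power law with exponent
    ``beta_xi`` = 0.93 until ``kernel_cutoff``.  Defaults are the
    parameters of the 22-s-kernel somatosensory pyramidal-cell fit.
    """

    lambda0: float = 2.0        # latency, 1/ms
    gamma: float = 1.0 / 15.3   # inverse membrane timescale, 1/ms
    V_inf: float = -45.9        # equilibrium potential, mV (absorbs I_ext)
    V0: float = -38.8           # reset potential, mV
    VT_star: float = -51.9      # threshold baseline, mV
    dV: float = 0.75            # threshold sharpness, mV
    a_xi: float = 19.3          # adaptation kernel magnitude, mV
    beta_xi: float = 0.93       # power-law exponent
    T_xi: float = 8.3           # kernel plateau, ms
    kernel_cutoff: float = 22_000.0  # ms
    sim_dt: float = 0.5         # simulation step, ms
    burn_in: float = 100.0      # seconds discarded before recording

    def kernel_table(self) -> np.ndarray:
        """xi evaluated at s = (k+1) * sim_dt for all steps within the cutoff."""
        n = int(round(self.kernel_cutoff / self.sim_dt))
        s = (np.arange(n) + 1) * self.sim_dt
        xi = np.where(s <= self.T_xi, self.a_xi,
                      self.a_xi * (s / self.T_xi) ** (-self.beta_xi))
        xi[s >= self.kernel_cutoff] = 0.0
        return xi


def glif_params_1s(**overrides) -> GLIFParams:
    """The 1-s-kernel variant: a_xi = 35.2 mV, cutoff 1 s, 4 Hz firing."""
    kw = dict(a_xi=35.2, kernel_cutoff=1000.0)
    kw.update(overrides)
    return GLIFParams(**kw)


@njit(cache=True)
def _glif_core(n_steps, dt, lam0, gamma, v_inf, v0, vt_star, dv, xi, seed):
    np.random.seed(seed)
    thr = np.zeros(n_steps)
    x = np.zeros(n_steps, dtype=np.uint8)
    n_kernel = xi.size
    i_last = -1
    n_clipped = 0
    for i in range(n_steps):
        if i_last < 0:
            v = v_inf
        else:
            v = v_inf + (v0 - v_inf) * np.exp(-gamma * (i - i_last) * dt)
        lam = lam0 * np.exp((v - (vt_star + thr[i])) / dv)
        p = lam * dt
        if p > 0.1:
            n_clipped += 1
            if p > 1.0:
                p = 1.0
        if np.random.random() < p:
            x[i] = 1
            i_last = i
            stop = i + 1 + n_kernel
            if stop > n_steps:
                stop = n_steps
            for k in range(i + 1, stop):
                thr[k] += xi[k - i - 1]
    return x, n_clipped


def simulate_glif(params: GLIFParams, duration: float, rng: np.random.Generator,
                  return_steps: bool = False):
    """Simulate the neuron for `duration` seconds after the burn-in.

    The membrane uses the exact inter-spike closed form on the sim_dt
    grid; threshold contributions are summed event-wise from the kernel
    lookup table.  Returns the SpikeTrain (times relative to the end of
    the burn-in); with ``return_steps=True`` also the full per-step
    binary spike array *including* the burn-in (as required by
    :func:`glif_true_R`, whose early windows must see their true past).
    """
    dt = params.sim_dt  # ms
    n_burn = int(round(params.burn_in * 1000.0 / dt))
    n_rec = int(round(duration * 1000.0 / dt))
    seed = int(rng.integers(0, 2**31 - 1))
    x, n_clipped = _glif_core(n_burn + n_rec, dt, params.lambda0, params.gamma,
                              params.V_inf, params.V0, params.VT_star, params.dV,
                              params.kernel_table(), seed)
    if n_clipped > 0:
        import warnings
        warnings.warn(f"spike probability exceeded 0.1 in {n_clipped} steps; "
                      "the time discretization may be too coarse")
    x_rec = x[n_burn:]
    steps = np.flatnonzero(x_rec)
    times = (steps + 0.5) * dt / 1000.0
    train = SpikeTrain(times, 0.0, n_rec * dt / 1000.0)
    if return_steps:
        return train, x
    return train


def tune_glif_rate(params: GLIFParams, rng: np.random.Generator,
                   target_rate: float = 4.0, calibration: float = 600.0,
                   rel_tol: float = 0.01, bracket: tuple = (-10.0, 5.0)) -> GLIFParams:
    """Calibrate the equilibrium potential to a target firing rate.

    The constant external drive enters the dynamics only through V_inf,
    so the drive is tuned by bisection on a V_inf offset until a seeded
    calibration run hits `target_rate` within `rel_tol`.  Each trial run
    reuses the same random numbers, making the rate monotone in the
    offset and the bisection deterministic.
    """
    seed = int(rng.integers(0, 2**31 - 1))

    def rate(offset: float) -> float:
        trial = replace(params, V_inf=params.V_inf + offset)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            train = simulate_glif(trial, calibration, np.random.default_rng(seed))
        return train.rate

    lo, hi = bracket
    if not rate(lo) < target_rate < rate(hi):
        raise ValueError("target rate outside the calibration bracket")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate) <= rel_tol * target_rate:
            return replace(params, V_inf=params.V_inf + mid)
        if r > target_rate:
            hi = mid
        else:
            lo = mid
    return replace(params, V_inf=params.V_inf + 0.5 * (lo + hi))


@njit(cache=True)
def _glif_window_rates(x, n_burn, dt, lam0, gamma, v_inf, v0, vt_star, dv,
                       xi, steps_per_window):
    """Conditional rate per sim step, frozen at each analysis-window start.

    For every analysis window the rate over its steps is computed using
    only spikes emitted before the window start (later spikes, including
    ones inside the window, do not enter), which is what the conditional
    probability of the window's spike outcome requires.
    """
    n_total = x.size
    n_rec = n_total - n_burn
    n_windows = n_rec // steps_per_window
    lam = np.zeros((n_windows, steps_per_window))
    spike_steps = np.nonzero(x)[0]
    n_kernel = xi.size
    ptr = 0  # spikes strictly before the window start
    for w in range(n_windows):
        start = n_burn + w * steps_per_window
        while ptr < spike_steps.size and spike_steps[ptr] < start:
            ptr += 1
        i_last = spike_steps[ptr - 1] if ptr > 0 else -1
        # spikes within the kernel reach of this window
        lo = ptr
        while lo > 0 and start - spike_steps[lo - 1] <= n_kernel:
            lo -= 1
        for j in range(steps_per_window):
            i = start + j
            if i_last < 0:
                v = v_inf
            else:
                v = v_inf + (v0 - v_inf) * np.exp(-gamma * (i - i_last) * dt)
            thr = 0.0
            for s in range(lo, ptr):
                k = i - spike_steps[s] - 1
                if k < n_kernel:
                    thr += xi[k]
            lam[w, j] = lam0 * np.exp((v - (vt_star + thr)) / dv)
    return lam


def conditional_entropy_from_rates(lam_windows: np.ndarray, x_windows: np.ndarray,
                                   sim_dt_ms: float) -> float:
    """Mean conditional spiking information (bits) from per-step rates.

    ``p(no spike in window) = prod_j (1 - lam_j * dt)``; the entropy is
    the negative mean log2 probability of the observed window outcomes.
    """
    q = np.clip(1.0 - lam_windows * sim_dt_ms, 1e-300, 1.0)
    p0 = np.exp(np.sum(np.log(q), axis=1))
    p_obs = np.where(x_windows == 1, 1.0 - p0, p0)
    p_obs = np.clip(p_obs, 1e-300, 1.0)
    return float(-np.mean(np.log2(p_obs)))


def glif_true_R(x_steps: np.ndarray, params: GLIFParams, dt_analysis: float,
                n_burn_steps: int | None = None) -> tuple[float, float]:
    """Exact total history dependence of a simulated recording.

    `x_steps` is the full per-sim-step spike array including the burn-in
    (needed so early windows see their true past); returns
    (R_tot, H(X|past)) where the conditional entropy uses the model's own
    conditional spiking probability per analysis window.
    """
    dt = params.sim_dt
    M = int(round(dt_analysis * 1000.0 / dt))
    if n_burn_steps is None:
        n_burn_steps = int(round(params.burn_in * 1000.0 / dt))
    lam = _glif_window_rates(x_steps, n_burn_steps, dt, params.lambda0,
                             params.gamma, params.V_inf, params.V0,
                             params.VT_star, params.dV, params.kernel_table(), M)
    n_windows = lam.shape[0]
    x_rec = x_steps[n_burn_steps:n_burn_steps + n_windows * M]
    x_win = x_rec.reshape(n_windows, M).max(axis=1)
    h_cond = conditional_entropy_from_rates(lam, x_win, dt)
    h_x = binary_entropy_bits(float(x_win.mean()))
    if h_x == 0:
        return 0.0, h_cond
    return 1.0 - h_cond / h_x, h_cond


# ---------------------------------------------------------------------------
# GLM approximation of the model's true history dependence


def glm_R_for_embedding(train_spikes: SpikeTrain, eval_spikes: SpikeTrain,
                        emb: EmbeddingSpec) -> float:
    """True R(T, d, kappa) of a near-GLM neuron, by fit-and-evaluate.

    The GLM is fitted on `train_spikes` and its conditional entropy
    evaluated on `eval_spikes` (normally a longer recording), which
    avoids the overfitting bias of in-sample evaluation.
    """
    fit = fit_glm(embed_samples(train_spikes, emb))
    samples_eval = embed_samples(eval_spikes, emb)
    h_glm = -glm_log2_likelihood(fit, samples_eval) / samples_eval.N
    h_x = binary_entropy_bits(float(samples_eval.x.mean()))
    return 1.0 - h_glm / h_x


def glm_ground_truth_R(train_spikes: SpikeTrain, eval_spikes: SpikeTrain,
                       T: float, dt: float, d_set=(25, 50, 75, 100, 125, 150),
                       tau1_max: float = 0.0005) -> float:
    """Best GLM approximation of the true R(T) over high-resolution embeddings.

    For each candidate dimension the scaling is set so the first past bin
    is at most `tau1_max` wide; the maximum over dimensions approximates
    the embedding-unconstrained history dependence at past range T.
    Estimates increase with d (nested models), so the maximum is the
    least-insufficient embedding in the set.
    """
    best = -np.inf
    for d in d_set:
        if T / d <= tau1_max:
            kappa = 0.0
        else:
            kappa = solve_kappa_for_tau1(T, d, tau1_max)
        emb = make_embedding(T, d, kappa, dt)
        best = max(best, glm_R_for_embedding(train_spikes, eval_spikes, emb))
    return best
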