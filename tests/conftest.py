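"""Shared fixtures: benchmark simulations reused across test modules.

The expensive simulations (calibrated adapting neuron, long binary
autoregressive run) are session-scoped so that the acceptance checks and
unit tests share them.  All randomness is seeded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import histdep as hd
from histdep import simulators as sim

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")

SEED = 20260928

# problem sizes for the benchmark suite (see docs/methods.md)
GLIF_LONG_MIN = 40.0       # minutes: benchmark recording
GLIF_TRUTH_TRAIN_MIN = 15.0  # minutes: GLM-truth training segment


@pytest.fixture(scope="session")
def glif_params():
    """1-s-kernel adapting neuron calibrated to 4 Hz."""
    rng = np.random.default_rng(SEED)
    return sim.tune_glif_rate(sim.glif_params_1s(), rng)


@pytest.fixture(scope="session")
def glif_long(glif_params):
    """A long benchmark recording: (SpikeTrain, per-step spike array)."""
    rng = np.random.default_rng(SEED + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train, x = sim.simulate_glif(glif_params, GLIF_LONG_MIN * 60.0, rng,
                                     return_steps=True)
    return train, x


class GlmTruth:
    """GLM-approximated true history dependence of the model neuron.

    Fits are trained on the first segment of the long recording and
    evaluated on the full recording; results are cached per embedding.
    """

    def __init__(self, train_full):
        self.full = train_full
        self.train = train_full.restrict(0.0, GLIF_TRUTH_TRAIN_MIN * 60.0)
        self._cache = {}

    def for_embedding(self, emb):
        key = (round(emb.T, 9), emb.d, round(emb.kappa, 9))
        if key not in self._cache:
            self._cache[key] = sim.glm_R_for_embedding(self.train, self.full, emb)
        return self._cache[key]


@pytest.fixture(scope="session")
def glif_truth(glif_long):
    train, _ = glif_long
    return GlmTruth(train)


@pytest.fixture(scope="session")
def glif_true_R_tot(glif_long, glif_params):
    _, x = glif_long
    r_tot, _ = sim.glif_true_R(x, glif_params, dt_analysis=0.005)
    return r_tot


AR_PARAMS = sim.ARParams(h=0.0051, m=0.8, l=1, dt=0.005)  # ~5 Hz at 5 ms steps
AR_N_STEPS = 10**7


@pytest.fixture(scope="session")
def ar_long():
    """10^7-step depth-1 autoregressive series and its spike train."""
    rng = np.random.default_rng(SEED + 2)
    x = sim.simulate_binary_ar(AR_PARAMS, AR_N_STEPS, rng)
    return x, sim.ar_spike_train(x, AR_PARAMS.dt)
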