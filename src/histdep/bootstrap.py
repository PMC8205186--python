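"""Blocks-of-blocks bootstrap over embedded measurements.

Embedded measurements are serially dependent, so plain resampling would
understate the variance.  Contiguous blocks of length ``l`` (in units of
the analysis step dt) are drawn with replacement from all overlapping
start positions; ``l`` defaults to the mean interspike interval in dt
units, ``l = 1/(r*dt)``, so that each block spans roughly one ISI.
Confidence intervals assume a Gaussian sampling distribution:
``R +- 2*sigma``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["block_length", "blocks_of_blocks_indices", "blocks_of_blocks_resample",
           "bootstrap_sigma"]


def block_length(rate: float, dt: float) -> int:
    """Block length l = 1/(r*dt) in analysis steps (at least 1)."""
    if rate <= 0:
        return 1
    return max(1, int(round(1.0 / (rate * dt))))


def blocks_of_blocks_indices(N: int, l: int, rng: np.random.Generator) -> np.ndarray:
    """Index array for one resample: floor(N/l) blocks of l contiguous steps.

    Blocks are drawn with replacement from all N - l + 1 overlapping
    start positions; the resampled length is floor(N/l) * l.
    """
    if l < 1:
        raise ValueError("block length must be at least 1")
    if l > N:
        raise ValueError("block length exceeds the number of measurements")
    n_blocks = N // l
    starts = rng.integers(0, N - l + 1, size=n_blocks)
    return (starts[:, None] + np.arange(l)[None, :]).reshape(-1)


def blocks_of_blocks_resample(samples, l: int, rng: np.random.Generator):
    """Resample an embedded-sample object (anything with ``.subset(idx)``)."""
    if l == samples.N:
        return samples
    idx = blocks_of_blocks_indices(samples.N, l, rng)
    return samples.subset(idx)


def bootstrap_sigma(samples, estimator_fn, l: int, n_boot: int,
                    rng: np.random.Generator) -> float:
    """SD of an estimator over blocks-of-blocks resamples.

    `estimator_fn` maps an embedded-sample object to a scalar; failures
    on individual resamples propagate (they indicate degenerate data,
    e.g. a resample without spikes).
    """
    if n_boot < 2:
        raise ValueError("need at least two bootstrap samples")
    values = np.empty(n_boot)
    for b in range(n_boot):
        values[b] = estimator_fn(blocks_of_blocks_resample(samples, l, rng))
    return float(np.std(values, ddof=1))
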