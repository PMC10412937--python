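"""Null-calibration experiments for the surrogate significance tests.

Both experiments measure empirical false-positive rates on synthetic null
data, checking that the surrogate thresholds deliver their nominal
alpha = 0.05:

* spectral coherence between independent white Gaussian pairs, with
  per-frequency thresholds from phase-randomization surrogates;
* window-averaged pairwise Granger causality between independent AR(1)
  pairs, with a block-resampling surrogate null and normal-approximation
  threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .causality import granger_significance
from .coupling import coherence_with_significance

__all__ = [
    "coherence_false_positive_rate",
    "granger_false_positive_rate",
]


def coherence_false_positive_rate(
    n_reps: int = 200,
    duration_s: float = 60.0,
    fs: float = 250.0,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean fraction of frequency bins flagged significant for independent
    white-noise pairs (should approximate ``alpha``)."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    fractions = np.empty(n_reps)
    for i in range(n_reps):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        res = coherence_with_significance(
            x, y, fs, n_surrogates=n_surrogates, alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        fractions[i] = res.significant_fraction
    return float(fractions.mean())


def granger_false_positive_rate(
    n_reps: int = 200,
    duration_s: float = 60.0,
    fs: float = 250.0,
    ar_coef: float = 0.7,
    n_surrogates: int = 120,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Per-direction false-positive rates of the block-resampling Granger
    test on independent AR(1) pairs (each should approximate ``alpha``)."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    fp = np.zeros(2)
    for i in range(n_reps):
        x = lfilter([1.0], [1.0, -ar_coef], rng.standard_normal(n))
        y = lfilter([1.0], [1.0, -ar_coef], rng.standard_normal(n))
        res = granger_significance(
            x, y, fs=fs, n_surrogates=n_surrogates, alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        fp += (res.significant_xy, res.significant_yx)
    return float(fp[0] / n_reps), float(fp[1] / n_reps)
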