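"""Truncated-normal sampling helpers used by the Gibbs sampler.

Inverse-CDF sampling done in log space (``ndtri_exp``) so that draws stay
accurate arbitrarily far into the tail — the positive-truncated draws for
the latent skewing variables can sit many standard deviations above the
conditional mean when an effect is a strong outlier of the opposite sign.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri, ndtri_exp

__all__ = ["truncnorm_positive", "truncnorm_interval"]

_TINY = 1e-300


def truncnorm_positive(mean, sd, rng: np.random.Generator) -> np.ndarray:
    """Vectorized draw from N(mean, sd^2) truncated to (0, inf)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = -mean / sd  # standardized lower bound
    u = np.maximum(rng.uniform(size=np.broadcast(mean, sd).shape), _TINY)
    # upper-tail probability v = u * P(Z >= a), then z = -Phi^{-1}(v)
    z = -ndtri_exp(np.log(u) + log_ndtr(-a))
    return mean + sd * z


def truncnorm_interval(mean: float, sd: float, lo: float, hi: float,
                       rng: np.random.Generator) -> float:
    """Scalar draw from N(mean, sd^2) truncated to [lo, hi]."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    pa, pb = ndtr(a), ndtr(b)
    u = max(rng.uniform(), _TINY)
    if pb - pa > 1e-14:
        return mean + sd * ndtri(pa + u * (pb - pa))
    # interval mass underflows: sample the tail nearest the interval
    if a > 0:  # both bounds far right of the mean
        z = -ndtri_exp(np.log(u) + log_ndtr(-a))
        return float(np.clip(mean + sd * z, lo, hi))
    z = ndtri_exp(np.log(u) + log_ndtr(b))
    return float(np.clip(mean + sd * z, lo, hi))
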