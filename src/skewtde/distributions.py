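"""Sahu-parameterized skew-normal and skew-t distributions.

This is the pure math layer behind the asymmetric Student's-t (AT) priors.
The construction follows Sahu, Dey & Branco (2003) in the univariate case:
a skew-normal variate is ``x = lam * u + eps`` with ``u`` standard
half-normal and ``eps ~ N(0, sigma2)``; the skew-t divides the pair
``(u, eps)`` jointly by ``sqrt(s)`` with ``s ~ Gamma(nu/2, rate=nu/2)``.
Setting ``lam = 0`` recovers the symmetric Student's t with ``nu`` degrees
of freedom (scaled by ``sqrt(sigma2)``); letting ``nu -> inf`` recovers the
skew-normal; both together give the Gaussian.

Closed forms used below:

* skew-normal density
  ``f(x) = 2 phi(x; 0, sigma2 + lam^2) Phi(lam x / (sigma omega))``
  with ``omega = sqrt(sigma2 + lam^2)``;
* skew-t density
  ``f(x) = 2 t_nu(x / omega) / omega *
  T_{nu+1}( (lam/sigma) (x/omega) sqrt((nu+1)/(nu + x^2/omega^2)) )``,
  the Gamma-mixed marginal of the conditional skew-normal;
* mean ``E[x] = lam sqrt(nu/pi) Gamma((nu-1)/2) / Gamma(nu/2)`` (nu > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "SkewTParams",
    "skew_normal_logpdf",
    "skew_t_logpdf",
    "sample_skew_t",
    "skew_t_mean",
    "skew_t_variance",
]

#: Default lower truncation for the degrees of freedom. nu > 4 guarantees
#: finite kurtosis and keeps the t away from its Cauchy-like regime.
NU_LOWER_DEFAULT = 4.0


@dataclass(frozen=True)
class SkewTParams:
    """Parameters of the univariate Sahu skew-t.

    Attributes
    ----------
    sigma2:
        Scale of the underlying normal kernel (variance of ``eps``), in
        squared log2-expression units. This is *not* the marginal variance;
        see :func:`skew_t_variance`.
    nu:
        Degrees of freedom (> ``nu_lower``); small values mean heavy tails,
        values above ~30 are practically Gaussian.
    lam:
        Asymmetry parameter, in log2-expression units. ``lam = 0`` is
        perfect symmetry; positive (negative) values proportionally
        inflate the right (left) tail.
    nu_lower:
        Lower bound enforced on ``nu``.
    """

    sigma2: float
    nu: float
    lam: float
    nu_lower: float = NU_LOWER_DEFAULT

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive and finite, got {self.sigma2}")
        if not self.nu > self.nu_lower:
            raise ValueError(
                f"nu must exceed the lower bound {self.nu_lower}, got {self.nu}"
            )
        if not np.isfinite(self.lam):
            raise ValueError(f"lam must be finite, got {self.lam}")


def skew_normal_logpdf(x, sigma2: float, lam: float):
    """Log-density of the Sahu skew-normal with kernel variance ``sigma2``
    and asymmetry ``lam``, evaluated elementwise at ``x``.

    ``lam = 0`` collapses to ``N(0, sigma2)``.
    """
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive and finite, got {sigma2}")
    if not np.isfinite(lam):
        raise ValueError(f"lam must be finite, got {lam}")
    x = np.asarray(x, dtype=float)
    omega2 = sigma2 + lam * lam
    omega = np.sqrt(omega2)
    sigma = np.sqrt(sigma2)
    return (
        np.log(2.0)
        + stats.norm.logpdf(x, loc=0.0, scale=omega)
        + stats.norm.logcdf(lam * x / (sigma * omega))
    )


def skew_t_logpdf(x, params: SkewTParams):
    """Log-density of the univariate Sahu skew-t, elementwise at ``x``.

    For ``lam = 0`` this is the symmetric Student's t with ``nu`` degrees of
    freedom scaled by ``sqrt(sigma2)``; for large ``nu`` it approaches the
    skew-normal with the same ``(sigma2, lam)``.
    """
    if not isinstance(params, SkewTParams):
        params = SkewTParams(*params)
    x = np.asarray(x, dtype=float)
    sigma2, nu, lam = params.sigma2, params.nu, params.lam
    omega2 = sigma2 + lam * lam
    omega = np.sqrt(omega2)
    sigma = np.sqrt(sigma2)
    z = x / omega
    # T_{nu+1} argument: (lam/sigma) z sqrt((nu+1)/(nu+z^2))
    arg = (lam / sigma) * z * np.sqrt((nu + 1.0) / (nu + z * z))
    return (
        np.log(2.0)
        + stats.t.logpdf(z, df=nu)
        - np.log(omega)
        + stats.t.logcdf(arg, df=nu + 1.0)
    )


def sample_skew_t(n: int, params: SkewTParams, seed) -> np.ndarray:
    """Draw ``n`` variates from the Sahu skew-t by its stochastic
    representation: ``s ~ Gamma(nu/2, rate nu/2)``, ``u`` half-normal with
    variance ``1/s``, ``eps ~ N(0, sigma2/s)``, return ``lam*u + eps``.

    ``seed`` may be an int or a :class:`numpy.random.Generator`;
    identical seeds give bit-identical output.
    """
    if not isinstance(params, SkewTParams):
        params = SkewTParams(*params)
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nu = params.nu
    s = rng.gamma(shape=nu / 2.0, scale=2.0 / nu, size=n)
    root_s = np.sqrt(s)
    u = np.abs(rng.standard_normal(n)) / root_s
    eps = rng.standard_normal(n) * np.sqrt(params.sigma2) / root_s
    return params.lam * u + eps


def _half_normal_t_moment(nu: float) -> float:
    """E[u / sqrt(s)] = sqrt(nu/pi) Gamma((nu-1)/2) / Gamma(nu/2)."""
    return np.sqrt(nu / np.pi) * np.exp(gammaln((nu - 1.0) / 2.0) - gammaln(nu / 2.0))


def skew_t_mean(params: SkewTParams) -> float:
    """Closed-form mean ``lam * sqrt(nu/pi) * Gamma((nu-1)/2) / Gamma(nu/2)``.

    Anti-symmetric in ``lam``; requires ``nu > 1`` (the moment is undefined
    otherwise).
    """
    if not isinstance(params, SkewTParams):
        params = SkewTParams(*params)
    if params.nu <= 1.0:
        raise ValueError(f"mean undefined for nu <= 1, got nu={params.nu}")
    return params.lam * _half_normal_t_moment(params.nu)


def skew_t_variance(params: SkewTParams) -> float:
    """Marginal variance: ``sigma2 nu/(nu-2) + lam^2 (nu/(nu-2) - k^2)``
    with ``k = sqrt(nu/pi) Gamma((nu-1)/2)/Gamma(nu/2)``; requires nu > 2.
    """
    if not isinstance(params, SkewTParams):
        params = SkewTParams(*params)
    nu = params.nu
    if nu <= 2.0:
        raise ValueError(f"variance undefined for nu <= 2, got nu={nu}")
    k = _half_normal_t_moment(nu)
    tail = nu / (nu - 2.0)
    return params.sigma2 * tail + params.lam**2 * (tail - k * k)
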