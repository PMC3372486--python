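"""Model specification: prior family, hyperpriors and sampler controls."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["ModelSpec", "FAMILIES"]

FAMILIES = ("SG", "ST", "AT")


@dataclass
class ModelSpec:
    """Prior family and MCMC settings for one model fit.

    The three families differ only in the prior on the probe (p) and
    differential-expression (d) random effects:

    * ``SG`` — zero-mean Gaussians with variances sigma2_p, sigma2_d;
    * ``ST`` — symmetric Student's t (the AT family with lambda fixed at 0);
    * ``AT`` — asymmetric Student's t in the Sahu parameterization, with a
      uniform prior on the asymmetry lambda and a (truncated) exponential
      prior on the degrees of freedom nu.

    Array effects carry a flat prior by default (``a_prior_var = inf``);
    variance parameters carry flat priors by default (prior df -2, scale 0,
    i.e. an improper uniform on (var_floor, inf)). Proper alternatives are
    exposed because sampler-validation procedures (e.g. Geweke-style
    joint-distribution checks) require integrable priors.
    """

    family: str = "AT"
    # hyperpriors
    lam_bound: float = 10.0      # uniform prior on lambda over [-lam_bound, lam_bound]
    nu_lower: float = 4.0        # lower truncation of the degrees of freedom
    nu_prior_rate: float = 0.1   # exponential prior rate for (nu - nu_lower)
    a_prior_var: float = np.inf  # Gaussian prior variance for array effects
    effect_var_prior_df: float = -2.0    # scaled-inv-chi2 prior for sigma2_p/sigma2_d
    effect_var_prior_scale: float = 0.0  # (df=-2, scale=0 == flat on sigma2)
    resid_var_prior_df: float = -2.0     # scaled-inv-chi2 prior for sigma2_e
    resid_var_prior_scale: float = 0.0
    # sampler controls
    n_iter: int = 500_000
    burn_in: int = 50_000
    thin: int = 10
    seed: int = 0
    nu_proposal_scale: float = 0.5   # random-walk sd on log(nu - nu_lower)
    adapt_nu_proposal: bool = True   # tune during burn-in to 20-50% acceptance
    var_floor: float = 1e-8
    # differential-expression test
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.lam_bound < 0:
            raise ValueError("lam_bound must be >= 0")
        if self.nu_lower <= 1.0:
            raise ValueError("nu_lower must exceed 1 (posterior moments of nu)")
        if self.nu_prior_rate <= 0:
            raise ValueError("nu_prior_rate must be positive")
        if self.nu_proposal_scale <= 0:
            raise ValueError("nu proposal scale must be positive")
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def effective_lam_bound(self) -> float:
        """Half-width of the lambda prior actually used: 0 under ST/SG."""
        return self.lam_bound if self.family == "AT" else 0.0

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        d = asdict(self)
        if np.isinf(d["a_prior_var"]):
            d["a_prior_var"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if d.get("a_prior_var") == "inf":
            d["a_prior_var"] = np.inf
        return cls(**d)
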