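"""Synthetic two-group microarray data with the model's exact generative
structure, plus truth records for recovery / power / specificity testing.

The default configuration emulates an unbalanced two-treatment comparison
of the kind common in public single-channel expression series (6 vs 14
arrays, thousands of probes): probe effects drawn from a right-skewed
heavy-tailed skew-t (lam_p = 2, nu_p = 8), differential effects from a
left-skewed one (lam_d = -1.5, nu_d = 8), gene-specific residual variances
log-normal around 0.25 (squared log2 units), and array effects uniform on
[7, 9] — the systematic slide level of a typical log2 intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ExpressionDataSet
from .distributions import SkewTParams, sample_skew_t

__all__ = ["SimulationTruth", "simulate_dataset", "spike_null_differentials"]


@dataclass
class SimulationTruth:
    """Every generating parameter and realization of one synthetic dataset.

    Together with ``seed`` these fields regenerate the dataset
    bit-identically through :func:`simulate_dataset`.
    """

    m: int = 2000
    n1: int = 6
    n2: int = 14
    sigma2_p: float = 1.0
    nu_p: float = 8.0
    lam_p: float = 2.0
    sigma2_d: float = 0.25
    nu_d: float = 8.0
    lam_d: float = -1.5
    resid_log_mean: float = float(np.log(0.25))  # log-normal residual variances
    resid_log_sd: float = 0.5
    a_low: float = 7.0   # uniform range for array effects (log2 level)
    a_high: float = 9.0
    seed: int = 0
    # realizations (filled by simulate_dataset)
    a: np.ndarray | None = None
    p: np.ndarray | None = None
    d: np.ndarray | None = None
    sigma2_e: np.ndarray | None = None
    null_probes: np.ndarray | None = None  # indices where d was forced to 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 probes")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 arrays per group")
        if self.sigma2_p <= 0 or self.sigma2_d <= 0:
            raise ValueError("effect scales must be positive")
        if self.resid_log_sd < 0:
            raise ValueError("residual log-sd must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("a", "p", "d", "sigma2_e", "null_probes"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        d = dict(d)
        for key in ("a", "p", "d", "sigma2_e"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        if d.get("null_probes") is not None:
            d["null_probes"] = np.asarray(d["null_probes"], dtype=int)
        return cls(**d)


def simulate_dataset(truth: SimulationTruth | None = None, **overrides
                     ) -> tuple[ExpressionDataSet, SimulationTruth]:
    """Generate one synthetic dataset; returns (dataset, completed truth).

    y_ik = a_i + p_k + d_k * [group(i) = 2] + e_ik with
    p_k ~ skew-t(sigma2_p, nu_p, lam_p), d_k ~ skew-t(sigma2_d, nu_d, lam_d),
    e_ik ~ N(0, sigma2_e,k) and sigma2_e,k log-normal. Reproducible given
    ``truth.seed``. Keyword overrides are applied to a default truth.
    """
    if truth is None:
        truth = SimulationTruth(**overrides)
    elif overrides:
        raise TypeError("pass either a truth object or keyword overrides, not both")
    rng = np.random.default_rng(truth.seed)
    m, n1, n2 = truth.m, truth.n1, truth.n2
    n = n1 + n2
    a = rng.uniform(truth.a_low, truth.a_high, size=n)
    p = sample_skew_t(m, SkewTParams(truth.sigma2_p, truth.nu_p, truth.lam_p), rng)
    d = sample_skew_t(m, SkewTParams(truth.sigma2_d, truth.nu_d, truth.lam_d), rng)
    if truth.null_probes is not None:
        d[truth.null_probes] = 0.0
    sigma2_e = np.exp(truth.resid_log_mean + truth.resid_log_sd * rng.standard_normal(m))
    group = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2)])
    g2 = (group == 2).astype(float)
    noise = rng.standard_normal((m, n)) * np.sqrt(sigma2_e)[:, None]
    values = a[None, :] + p[:, None] + np.outer(d, g2) + noise
    ds = ExpressionDataSet(
        values=values,
        probe_ids=[f"probe_{k:05d}" for k in range(m)],
        array_ids=[f"array_{i:02d}" for i in range(n)],
        group=group,
    )
    import dataclasses
    done = dataclasses.replace(truth, a=a, p=p, d=d, sigma2_e=sigma2_e)
    return ds, done


def spike_null_differentials(truth: SimulationTruth, fraction_null: float,
                             seed: int | None = None) -> SimulationTruth:
    """Return a truth whose next simulation forces a random subset of the
    differential effects d_k exactly to 0 (recorded in ``null_probes``).

    With ``fraction_null = f`` exactly ``round(f * m)`` probes become true
    nulls, so false-positive behavior of the DE caller can be measured.
    """
    if not 0.0 <= fraction_null <= 1.0:
        raise ValueError(f"fraction_null must lie in [0, 1], got {fraction_null}")
    import dataclasses
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    k = int(round(fraction_null * truth.m))
    nulls = np.sort(rng.choice(truth.m, size=k, replace=False))
    out = dataclasses.replace(truth, null_probes=nulls)
    if out.d is not None:
        out.d = out.d.copy()
        out.d[nulls] = 0.0
    return out
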