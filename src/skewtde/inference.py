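"""Posterior summarization, DIC model comparison and DE calling.

Point estimates follow the reporting convention of the modeling layer:
the posterior mode (argmax of a Gaussian-KDE density fit to the trace) with
the shortest 95% highest-posterior-density interval. Model comparison uses
the deviance information criterion DIC = Dbar + pD with pD = Dbar - Dhat,
where the deviance is the -2 log heteroskedastic Gaussian likelihood
conditional on the location effects and per-probe residual variances (the
random effects are "in focus", so pD counts the per-probe effective
parameters). Differential expression is called per probe from posterior
tail probabilities of d_k against the Bonferroni-like threshold
alpha / pi, pi being the number of probes analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .design import DesignMatrices
from .sampler import ChainSamples

__all__ = [
    "PosteriorSummary",
    "DICReport",
    "DEResult",
    "posterior_mode",
    "hpd_interval",
    "summarize_trace",
    "summarize_hyperparameters",
    "compute_dic",
    "call_differential_expression",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PosteriorSummary:
    """Mode, HPD95 and moments of one scalar parameter's trace."""

    name: str
    mode: float
    hpd_lower: float
    hpd_upper: float
    mean: float
    sd: float


@dataclass(frozen=True)
class DICReport:
    """DIC decomposition for one fitted model: dic = dbar + pd,
    pd = dbar - dhat (effective number of parameters)."""

    model: str
    dbar: float
    dhat: float
    pd: float
    dic: float


@dataclass
class DEResult:
    """Per-probe differential-expression calls.

    ``table`` columns: probe_id, p_gt0, p_lt0, significant. A probe is
    significant iff min(P(d_k > 0), P(d_k < 0)) < alpha / pi.
    """

    table: pd.DataFrame
    alpha: float
    n_probes: int
    threshold: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_probes(self) -> list:
        return self.table.loc[self.table["significant"], "probe_id"].tolist()


def posterior_mode(trace: np.ndarray) -> float:
    """Posterior mode: argmax of a Silverman-bandwidth Gaussian KDE of the
    trace, evaluated on a 512-point grid spanning the trace range.

    A (numerically) constant trace returns that constant.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < 100:
        raise ValueError(f"need >= 100 draws for a mode estimate, got {trace.size}")
    lo, hi = trace.min(), trace.max()
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        return float(trace[0])
    kde = gaussian_kde(trace, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(trace: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` of the
    sorted draws (sample HPD)."""
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < 100:
        raise ValueError(f"need >= 100 draws for an HPD interval, got {trace.size}")
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    x = np.sort(trace)
    n = x.size
    k = int(np.ceil(mass * n))  # number of draws the interval must contain
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarize_trace(name: str, trace: np.ndarray, mass: float = 0.95) -> PosteriorSummary:
    """Mode + HPD + moments for one trace."""
    lo, hi = hpd_interval(trace, mass)
    return PosteriorSummary(
        name=name,
        mode=posterior_mode(trace),
        hpd_lower=lo,
        hpd_upper=hi,
        mean=float(np.mean(trace)),
        sd=float(np.std(trace)),
    )


def summarize_hyperparameters(samples: ChainSamples, mass: float = 0.95) -> pd.DataFrame:
    """Mode/HPD95/mean/sd table for all stored scalar hyperparameters."""
    names = ["sigma2_p", "sigma2_d", "nu_p", "nu_d", "lam_p", "lam_d"]
    rows = []
    for name in names:
        tr = samples.hyperparameter_trace(name)
        if not np.all(np.isfinite(tr)):  # e.g. nu under SG
            continue
        s = summarize_trace(name, tr, mass)
        rows.append(
            dict(parameter=name, mode=s.mode, hpd_lower=s.hpd_lower,
                 hpd_upper=s.hpd_upper, mean=s.mean, sd=s.sd)
        )
    return pd.DataFrame(rows)


def compute_dic(samples: ChainSamples, design: DesignMatrices,
                model: str | None = None) -> DICReport:
    """DIC with the random effects in focus.

    dbar is the posterior mean of the per-iteration deviances accumulated
    by the sampler; dhat evaluates the deviance at the posterior means of
    the per-observation fitted values and per-probe residual variances.
    """
    if samples.n_accum < 1 or not np.isfinite(samples.dbar):
        raise ValueError("chain carries no deviance accumulation")
    M = design.mask.astype(float)
    n_k = M.sum(axis=1)
    E = (design.Y - samples.fitted_mean) * M
    ssr_k = (E * E).sum(axis=1)
    s2 = samples.sigma2_e_mean
    dhat = float(np.sum(n_k * (np.log(s2) + _LOG2PI)) + np.sum(ssr_k / s2))
    dbar = samples.dbar
    pd_ = dbar - dhat
    return DICReport(
        model=model or samples.spec.family,
        dbar=dbar,
        dhat=dhat,
        pd=pd_,
        dic=dbar + pd_,
    )


def rank_models(reports: list[DICReport]) -> pd.DataFrame:
    """DIC comparison table, ordered by DIC ascending (best first)."""
    df = pd.DataFrame(
        [dict(model=r.model, dbar=r.dbar, dhat=r.dhat, pd=r.pd, dic=r.dic)
         for r in reports]
    )
    return df.sort_values("dic", ignore_index=True)


def call_differential_expression(samples: ChainSamples,
                                 alpha: float | None = None) -> DEResult:
    """Flag differentially expressed probes at the alpha/pi threshold.

    Tail probabilities P(d_k > 0) and P(d_k < 0) come from the sign
    counters the sampler accumulated at every post-burn-in iteration; probe
    k is significant iff the smaller tail probability falls below
    alpha / pi with pi the number of probes analyzed.
    """
    alpha = samples.spec.alpha if alpha is None else alpha
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    n = samples.n_accum
    if n < 1:
        raise ValueError("no accumulated draws for the DE test")
    p_gt = samples.d_pos / n
    p_lt = samples.d_neg / n
    pi = len(samples.probe_ids)
    threshold = alpha / pi
    sig = np.minimum(p_gt, p_lt) < threshold
    table = pd.DataFrame(
        dict(probe_id=samples.probe_ids, p_gt0=p_gt, p_lt0=p_lt, significant=sig)
    )
    return DEResult(table=table, alpha=alpha, n_probes=pi, threshold=threshold)
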