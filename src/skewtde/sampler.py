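"""Gibbs/Metropolis sampler for the hierarchical mixed model.

One sweep updates, in order: array effects a -> probe effects p and their
latents (u_p, s_p) -> differential effects d and latents (u_d, s_d) ->
level-translation moves -> asymmetries lambda -> degrees of freedom nu ->
variance parameters. All location and variance updates are exact Gaussian /
scaled-inverse-chi-square full conditionals; nu uses a random-walk
Metropolis step on log(nu - nu_lower).

The skew-t priors enter through the Sahu data augmentation: conditional on
the per-probe latents, effect x_k has the Gaussian prior
N(lambda * u_k, sigma2 / s_k) with u_k half-normal(0, 1/s_k) and
s_k ~ Gamma(nu/2, rate nu/2); marginalizing (u_k, s_k) recovers the skew-t.
Model SG freezes s at 1 with lambda = 0 (plain Gaussian prior); model ST
keeps the augmentation but pins lambda at 0.

Because array effects carry a flat prior, the likelihood is invariant under
a constant shift between a and p (and, on group-2 arrays, between a and d).
Single-site Gibbs moves crawl along these ridges, so each sweep adds exact
translation updates that resample the shared level from its conditional —
a standard partial-resampling move for location hierarchies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._truncated import truncnorm_interval, truncnorm_positive
from .design import DesignMatrices
from .model import ModelSpec

__all__ = ["ChainState", "ChainSamples", "GibbsSampler", "run_chain"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ChainState:
    """All model unknowns at one MCMC iteration."""

    a: np.ndarray          # array effects (n,)
    p: np.ndarray          # probe effects (m,)
    d: np.ndarray          # differential effects (m,)
    u_p: np.ndarray        # positive latent skewing variables (m,)
    s_p: np.ndarray        # Gamma mixing variables (m,)
    u_d: np.ndarray
    s_d: np.ndarray
    sigma2_p: float        # probe-effect prior scale
    sigma2_d: float        # differential-effect prior scale
    sigma2_e: np.ndarray   # per-probe residual variances (m,)
    nu_p: float            # degrees of freedom (inf under SG)
    nu_d: float
    lam_p: float           # asymmetry (0 under SG/ST)
    lam_d: float

    def copy(self) -> "ChainState":
        return replace(
            self,
            a=self.a.copy(), p=self.p.copy(), d=self.d.copy(),
            u_p=self.u_p.copy(), s_p=self.s_p.copy(),
            u_d=self.u_d.copy(), s_d=self.s_d.copy(),
            sigma2_e=self.sigma2_e.copy(),
        )


@dataclass
class ChainSamples:
    """Stored output of one chain.

    Full traces are kept for the scalar hyperparameters only (post burn-in,
    thinned); per-probe effects are tracked through running first/second
    moments plus sign counters for d (accumulated at every post-burn-in
    iteration), which is what posterior summaries, DIC and the
    differential-expression test need.
    """

    spec: ModelSpec
    probe_ids: list
    array_ids: list
    scalars: pd.DataFrame          # iteration, deviance, sigma2_*, nu_*, lam_*
    n_accum: int                   # post-burn-in iterations accumulated
    p_mean: np.ndarray
    p_sd: np.ndarray
    d_mean: np.ndarray
    d_sd: np.ndarray
    d_pos: np.ndarray              # counts of d_k > 0 over accumulation
    d_neg: np.ndarray
    d_zero: np.ndarray
    a_mean: np.ndarray
    fitted_mean: np.ndarray        # (m, n) posterior-mean fitted grid
    sigma2_e_mean: np.ndarray
    dbar: float                    # posterior mean deviance (all accumulated iters)
    nu_accept_rate: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return len(self.scalars)

    def hyperparameter_trace(self, name: str) -> np.ndarray:
        return self.scalars[name].to_numpy()


class GibbsSampler:
    """Sampler bound to one design and one model specification.

    The update blocks are exposed as methods so they can be exercised (and
    validated) individually; :meth:`run` strings them together.
    """

    def __init__(self, design: DesignMatrices, spec: ModelSpec):
        self.design = design
        self.spec = spec
        self.M = design.mask.astype(float)
        self.Y = np.where(design.mask, design.Y, 0.0)
        self.g2 = np.flatnonzero(design.group2)
        self.g2f = design.group2.astype(float)
        self.m, self.n = self.Y.shape
        self.n_k = self.M.sum(axis=1)              # observations per probe
        self.n2_k = self.M[:, self.g2].sum(axis=1)  # group-2 observations per probe
        self.n2 = self.g2.size
        if np.any(self.n2_k < 1):
            raise ValueError("every probe needs at least one group-2 observation")
        self.nu_scales = {"p": spec.nu_proposal_scale, "d": spec.nu_proposal_scale}
        self._nu_accept = {"p": 0, "d": 0}
        self._nu_tries = {"p": 0, "d": 0}
        self._nu_window = {"p": [0, 0], "d": [0, 0]}  # [accepts, tries] in window
        self._ssr_e = None  # per-probe residual SSQ cached by update_variances

    # ------------------------------------------------------------------ init

    def initial_state(self, rng: np.random.Generator) -> ChainState:
        """Moment-based starting values: least-squares-style effects,
        residual-moment variances, latents at 1, lambda at 0, nu at 8."""
        spec = self.spec
        with np.errstate(invalid="ignore"):
            col_mean = self.Y.sum(axis=0) / np.maximum(self.M.sum(axis=0), 1.0)
        R = (self.Y - col_mean[None, :]) * self.M
        g1 = np.flatnonzero(~self.design.group2)
        n1_k = self.M[:, g1].sum(axis=1)
        p0 = R[:, g1].sum(axis=1) / np.maximum(n1_k, 1.0)
        mean2 = R[:, self.g2].sum(axis=1) / np.maximum(self.n2_k, 1.0)
        d0 = mean2 - p0
        fitted = col_mean[None, :] + p0[:, None] + np.outer(d0, self.g2f)
        E = (self.Y - fitted) * self.M
        ssr = (E * E).sum(axis=1)
        denom = np.maximum(self.n_k - 2.0, 1.0)
        s2e = ssr / denom
        # degenerate rows: no within-group variation at all
        with np.errstate(invalid="ignore"):
            wg_var = np.zeros(self.m)
            for cols in (g1, self.g2):
                sub = self.Y[:, cols]
                msub = self.M[:, cols]
                cnt = np.maximum(msub.sum(axis=1), 1.0)
                mu = (sub * msub).sum(axis=1) / cnt
                wg_var += (((sub - mu[:, None]) * msub) ** 2).sum(axis=1) / cnt
        flat_rows = wg_var < 1e-12
        if np.any(flat_rows):
            warnings.warn(
                f"{int(flat_rows.sum())} probe rows have (near-)zero residual "
                "variance; jittering their initial residual variance",
                RuntimeWarning,
            )
            s2e = np.where(flat_rows, 1e-6, s2e)
        s2e = np.maximum(s2e, spec.var_floor)
        m = self.m
        return ChainState(
            a=col_mean.copy(),
            p=p0,
            d=d0,
            u_p=np.ones(m),
            s_p=np.ones(m),
            u_d=np.ones(m),
            s_d=np.ones(m),
            sigma2_p=max(float(np.var(p0)), spec.var_floor * 10),
            sigma2_d=max(float(np.var(d0)), spec.var_floor * 10),
            sigma2_e=s2e,
            nu_p=np.inf if spec.family == "SG" else 8.0,
            nu_d=np.inf if spec.family == "SG" else 8.0,
            lam_p=0.0,
            lam_d=0.0,
        )

    # ------------------------------------------------------------- locations

    def update_location_effects(self, state: ChainState, rng: np.random.Generator) -> None:
        """Gaussian full-conditional draws for a, p and d (in place).

        a_i: flat (or Gaussian) prior against the heteroskedastic
        likelihood; p_k and d_k combine the likelihood with the conditional
        prior N(lambda * u_k, sigma2 / s_k) given the latents (lambda=0,
        s=1 recovers the plain Gaussian-prior conditional).
        """
        spec = self.spec
        inv_se = 1.0 / state.sigma2_e
        a_prior_prec = 0.0 if np.isinf(spec.a_prior_var) else 1.0 / spec.a_prior_var

        # array effects
        Rm = (self.Y - state.p[:, None] - np.outer(state.d, self.g2f)) * self.M
        num = inv_se @ Rm
        prec = inv_se @ self.M + a_prior_prec
        if not np.all(np.isfinite(prec)) or np.any(prec <= 0):
            raise FloatingPointError("non-finite conditional precision for array effects")
        state.a = num / prec + rng.standard_normal(self.n) / np.sqrt(prec)

        # probe effects
        Rm = (self.Y - state.a[None, :] - np.outer(state.d, self.g2f)) * self.M
        num = inv_se * Rm.sum(axis=1)
        prior_prec = state.s_p / state.sigma2_p
        prec = self.n_k * inv_se + prior_prec
        mean = (num + state.lam_p * state.u_p * prior_prec) / prec
        state.p = mean + rng.standard_normal(self.m) / np.sqrt(prec)

        # differential effects (group-2 observations only)
        Y2 = self.Y[:, self.g2]
        M2 = self.M[:, self.g2]
        Rm2 = (Y2 - state.a[self.g2][None, :] - state.p[:, None]) * M2
        num = inv_se * Rm2.sum(axis=1)
        prior_prec = state.s_d / state.sigma2_d
        prec = self.n2_k * inv_se + prior_prec
        mean = (num + state.lam_d * state.u_d * prior_prec) / prec
        state.d = mean + rng.standard_normal(self.m) / np.sqrt(prec)

    def update_translations(self, state: ChainState, rng: np.random.Generator) -> None:
        """Resample the likelihood-invariant level shifts between a and p,
        and between group-2 a and d, from their exact conditionals."""
        spec = self.spec
        a_prior_prec = 0.0 if np.isinf(spec.a_prior_var) else 1.0 / spec.a_prior_var

        w = state.s_p / state.sigma2_p
        prec = w.sum() + self.n * a_prior_prec
        num = np.sum(w * (state.p - state.lam_p * state.u_p)) - a_prior_prec * state.a.sum()
        c = num / prec + rng.standard_normal() / np.sqrt(prec)
        state.a = state.a + c
        state.p = state.p - c

        w = state.s_d / state.sigma2_d
        prec = w.sum() + self.n2 * a_prior_prec
        num = np.sum(w * (state.d - state.lam_d * state.u_d)) - a_prior_prec * state.a[self.g2].sum()
        c = num / prec + rng.standard_normal() / np.sqrt(prec)
        state.a[self.g2] += c
        state.d = state.d - c

    # --------------------------------------------------------------- latents

    def update_latents(self, state: ChainState, rng: np.random.Generator) -> None:
        """Draw the latent skewing (u) and Gamma mixing (s) variables for
        the p and d blocks from their full conditionals (in place).

        u_k | . ~ N+( lam x_k / (sigma2 + lam^2), sigma2 / (s_k (sigma2 + lam^2)) );
        s_k | . ~ Gamma( (nu + 2)/2, rate (nu + u_k^2 + (x_k - lam u_k)^2 / sigma2) / 2 ).
        """
        if self.spec.family == "SG":
            return
        for x, lam, sigma2, nu, which in (
            (state.p, state.lam_p, state.sigma2_p, state.nu_p, "p"),
            (state.d, state.lam_d, state.sigma2_d, state.nu_d, "d"),
        ):
            s = state.s_p if which == "p" else state.s_d
            omega2 = sigma2 + lam * lam
            mean_u = lam * x / omega2
            sd_u = np.sqrt(sigma2 / (s * omega2))
            u = truncnorm_positive(mean_u, sd_u, rng)
            resid = x - lam * u
            rate = 0.5 * (nu + u * u + resid * resid / sigma2)
            s_new = rng.gamma(shape=(nu + 2.0) / 2.0, scale=1.0 / rate)
            s_new = np.maximum(s_new, 1e-12)
            if which == "p":
                state.u_p, state.s_p = u, s_new
            else:
                state.u_d, state.s_d = u, s_new

    # ------------------------------------------------------------- asymmetry

    def update_asymmetry(self, state: ChainState, rng: np.random.Generator) -> None:
        """Draw lambda_p and lambda_d from their truncated-Gaussian full
        conditionals (weighted regression of effects on latents u)."""
        if self.spec.family != "AT":
            return
        L = self.spec.lam_bound
        if L == 0.0:
            state.lam_p = 0.0
            state.lam_d = 0.0
            return
        for x, u, s, sigma2, which in (
            (state.p, state.u_p, state.s_p, state.sigma2_p, "p"),
            (state.d, state.u_d, state.s_d, state.sigma2_d, "d"),
        ):
            w = s / sigma2
            prec = float(np.sum(w * u * u))
            if prec < 1e-30:  # degenerate latents: fall back to the prior
                lam = rng.uniform(-L, L)
            else:
                mean = float(np.sum(w * u * x)) / prec
                lam = truncnorm_interval(mean, 1.0 / np.sqrt(prec), -L, L, rng)
            if which == "p":
                state.lam_p = lam
            else:
                state.lam_d = lam

    # ---------------------------------------------------- degrees of freedom

    def _nu_logpost(self, nu: float, s: np.ndarray) -> float:
        """Log posterior kernel of nu given the mixing variables: product of
        Gamma(nu/2, rate nu/2) densities times the truncated-exponential prior."""
        half = nu / 2.0
        return (
            self.m * (half * np.log(half) - gammaln(half))
            + half * float(np.sum(np.log(s)) - np.sum(s))
            - self.spec.nu_prior_rate * (nu - self.spec.nu_lower)
        )

    def update_nu(self, state: ChainState, rng: np.random.Generator,
                  adapt: bool = False) -> None:
        """Random-walk Metropolis update of nu_p and nu_d on the
        log(nu - nu_lower) scale; optionally adapts the proposal scale
        toward 20-50% acceptance (burn-in only)."""
        if self.spec.family == "SG":
            return
        nu0 = self.spec.nu_lower
        for which, s in (("p", state.s_p), ("d", state.s_d)):
            nu = state.nu_p if which == "p" else state.nu_d
            eta = np.log(nu - nu0)
            eta_new = eta + self.nu_scales[which] * rng.standard_normal()
            nu_new = nu0 + np.exp(eta_new)
            # Jacobian of eta -> nu adds log(nu - nu0) to the log target
            log_ratio = (
                self._nu_logpost(nu_new, s) + eta_new
                - self._nu_logpost(nu, s) - eta
            )
            self._nu_tries[which] += 1
            self._nu_window[which][1] += 1
            if np.log(max(rng.uniform(), 1e-300)) < log_ratio:
                nu = nu_new
                self._nu_accept[which] += 1
                self._nu_window[which][0] += 1
            if which == "p":
                state.nu_p = nu
            else:
                state.nu_d = nu
            if adapt and self._nu_window[which][1] >= 100:
                acc, tries = self._nu_window[which]
                rate = acc / tries
                if rate > 0.5:
                    self.nu_scales[which] *= 1.3
                elif rate < 0.2:
                    self.nu_scales[which] /= 1.3
                self._nu_window[which] = [0, 0]

    # --------------------------------------------------------------- variances

    def update_variances(self, state: ChainState, rng: np.random.Generator) -> None:
        """Scaled-inverse-chi-square full-conditional draws for sigma2_p,
        sigma2_d and the per-probe residual variances (in place)."""
        spec = self.spec
        df0, sc0 = spec.effect_var_prior_df, spec.effect_var_prior_scale
        for x, u, s, lam, which in (
            (state.p, state.u_p, state.s_p, state.lam_p, "p"),
            (state.d, state.u_d, state.s_d, state.lam_d, "d"),
        ):
            resid = x - lam * u if spec.family != "SG" else x
            s_eff = s if spec.family != "SG" else 1.0
            ssr = float(np.sum(s_eff * resid * resid)) + df0 * sc0
            df = self.m + df0
            if df <= 0:
                raise ValueError("too few probes for the variance conditional")
            val = max(ssr / rng.chisquare(df), spec.var_floor)
            if which == "p":
                state.sigma2_p = val
            else:
                state.sigma2_d = val

        fitted = state.a[None, :] + state.p[:, None] + np.outer(state.d, self.g2f)
        E = (self.Y - fitted) * self.M
        ssr_k = (E * E).sum(axis=1)
        self._ssr_e = ssr_k
        df0, sc0 = spec.resid_var_prior_df, spec.resid_var_prior_scale
        df_k = self.n_k + df0
        ok = df_k >= 1.0
        s2 = np.full(self.m, spec.var_floor)
        if np.any(ok):
            chi = rng.chisquare(df_k[ok])
            s2[ok] = np.maximum((ssr_k[ok] + df0 * sc0) / chi, spec.var_floor)
        state.sigma2_e = s2

    # --------------------------------------------------------------- deviance

    def deviance(self, state: ChainState, ssr_k: np.ndarray | None = None) -> float:
        """-2 log of the heteroskedastic Gaussian likelihood at the state."""
        if ssr_k is None:
            fitted = state.a[None, :] + state.p[:, None] + np.outer(state.d, self.g2f)
            E = (self.Y - fitted) * self.M
            ssr_k = (E * E).sum(axis=1)
        return float(
            np.sum(self.n_k * (np.log(state.sigma2_e) + _LOG2PI))
            + np.sum(ssr_k / state.sigma2_e)
        )

    # ------------------------------------------------------------- Geweke aid

    def draw_data(self, state: ChainState, rng: np.random.Generator) -> None:
        """Replace the observations with a draw from the likelihood at the
        current state (used by joint-distribution sampler checks)."""
        fitted = state.a[None, :] + state.p[:, None] + np.outer(state.d, self.g2f)
        noise = rng.standard_normal((self.m, self.n)) * np.sqrt(state.sigma2_e)[:, None]
        self.Y = (fitted + noise) * self.M

    def draw_effects_from_prior(self, state: ChainState, rng: np.random.Generator) -> None:
        """Replace p, d and their latents with draws from the (conditional)
        prior hierarchy at the current hyperparameters (Geweke helper)."""
        spec = self.spec
        for which in ("p", "d"):
            sigma2 = state.sigma2_p if which == "p" else state.sigma2_d
            lam = state.lam_p if which == "p" else state.lam_d
            nu = state.nu_p if which == "p" else state.nu_d
            if spec.family == "SG":
                s = np.ones(self.m)
                u = np.ones(self.m)
                x = rng.standard_normal(self.m) * np.sqrt(sigma2)
            else:
                s = rng.gamma(nu / 2.0, 2.0 / nu, size=self.m)
                u = np.abs(rng.standard_normal(self.m)) / np.sqrt(s)
                x = lam * u + rng.standard_normal(self.m) * np.sqrt(sigma2 / s)
            if which == "p":
                state.u_p, state.s_p, state.p = u, s, x
            else:
                state.u_d, state.s_d, state.d = u, s, x

    # ------------------------------------------------------------------- run

    def sweep(self, state: ChainState, rng: np.random.Generator,
              adapt: bool = False) -> None:
        """One full update cycle over all blocks (in place)."""
        self.update_location_effects(state, rng)
        self.update_latents(state, rng)
        self.update_translations(state, rng)
        self.update_asymmetry(state, rng)
        self.update_nu(state, rng, adapt=adapt)
        self.update_variances(state, rng)

    def run(self, progress_every: int = 0) -> ChainSamples:
        """Run the full chain defined by the spec and return stored samples."""
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        state = self.initial_state(rng)
        m, n = self.m, self.n
        n_store = spec.n_stored
        scal_names = ["iteration", "deviance", "sigma2_p", "sigma2_d",
                      "nu_p", "nu_d", "lam_p", "lam_d"]
        scal = np.empty((n_store, len(scal_names)))
        stored = 0
        n_accum = 0
        p_sum = np.zeros(m); p2_sum = np.zeros(m)
        d_sum = np.zeros(m); d2_sum = np.zeros(m)
        a_sum = np.zeros(n)
        d_pos = np.zeros(m, dtype=np.int64)
        d_neg = np.zeros(m, dtype=np.int64)
        fitted_sum = np.zeros((m, n))
        s2e_sum = np.zeros(m)
        dev_sum = 0.0

        for it in range(spec.n_iter):
            self.sweep(state, rng, adapt=spec.adapt_nu_proposal and it < spec.burn_in)
            if it < spec.burn_in:
                continue
            dev = self.deviance(state, self._ssr_e)
            if not np.isfinite(dev):
                raise RuntimeError(
                    f"divergent chain state at iteration {it}: non-finite deviance"
                )
            n_accum += 1
            dev_sum += dev
            p_sum += state.p; p2_sum += state.p * state.p
            d_sum += state.d; d2_sum += state.d * state.d
            a_sum += state.a
            d_pos += state.d > 0
            d_neg += state.d < 0
            fitted_sum += state.a[None, :] + state.p[:, None] + np.outer(state.d, self.g2f)
            s2e_sum += state.sigma2_e
            if (it - spec.burn_in) % spec.thin == 0 and stored < n_store:
                scal[stored] = (it, dev, state.sigma2_p, state.sigma2_d,
                                state.nu_p, state.nu_d, state.lam_p, state.lam_d)
                stored += 1
            if progress_every and (it + 1) % progress_every == 0:
                acc = {k: (self._nu_accept[k] / self._nu_tries[k]
                           if self._nu_tries[k] else float("nan"))
                       for k in ("p", "d")}
                print(
                    f"iter {it + 1}/{spec.n_iter} deviance={dev:.1f} "
                    f"nu=({state.nu_p:.2f},{state.nu_d:.2f}) "
                    f"lam=({state.lam_p:.3f},{state.lam_d:.3f}) "
                    f"nu-accept=({acc['p']:.2f},{acc['d']:.2f})",
                    flush=True,
                )

        scalars = pd.DataFrame(scal[:stored], columns=scal_names)
        scalars["iteration"] = scalars["iteration"].astype(int)
        inv = 1.0 / max(n_accum, 1)
        p_mean = p_sum * inv
        d_mean = d_sum * inv
        p_var = np.maximum(p2_sum * inv - p_mean**2, 0.0)
        d_var = np.maximum(d2_sum * inv - d_mean**2, 0.0)
        accept = {
            k: (self._nu_accept[k] / self._nu_tries[k] if self._nu_tries[k] else np.nan)
            for k in ("p", "d")
        }
        return ChainSamples(
            spec=spec,
            probe_ids=self.design.probe_ids,
            array_ids=self.design.array_ids,
            scalars=scalars,
            n_accum=n_accum,
            p_mean=p_mean,
            p_sd=np.sqrt(p_var),
            d_mean=d_mean,
            d_sd=np.sqrt(d_var),
            d_pos=d_pos,
            d_neg=d_neg,
            d_zero=n_accum - d_pos - d_neg,
            a_mean=a_sum * inv,
            fitted_mean=fitted_sum * inv,
            sigma2_e_mean=s2e_sum * inv,
            dbar=dev_sum * inv,
            nu_accept_rate=accept,
        )


def run_chain(design: DesignMatrices, spec: ModelSpec,
              progress_every: int = 0) -> ChainSamples:
    """Run a single MCMC chain for the given design and model spec.

    Bit-reproducible for a fixed ``spec.seed``.
    """
    return GibbsSampler(design, spec).run(progress_every=progress_every)
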