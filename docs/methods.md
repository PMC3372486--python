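# Methods

## Model

For a probes × arrays matrix of log2 expression values from two treatment
groups, the observation for probe *k* on array *i* is

    y_ik = a_i + p_k + d_k·[group(i) = 2] + e_ik,
    e_ik ~ N(0, σ²_e,k),

with incidence matrices X, Z1, Z2 mapping observations to array effects
**a**, probe effects **p** and within-probe differential-expression
effects **d**. Key assumptions:

* **Reference-group coding.** Group 1 is baseline; d_k is the group-2
  minus group-1 contrast within probe k, so Z2 is a 0/1 incidence matrix
  whose rows are nonzero exactly for group-2 observations.
* **Array effects are systematic.** a_i carries the slide-level intensity
  (including the global intercept) under a flat prior. No sum-to-zero
  constraint is imposed: the sampler treats the likelihood-invariant
  directions explicitly (below), and model assessment compares fitted
  cell means and contrasts, which are estimable.
* **Heteroskedastic residuals.** Each probe has its own residual variance
  σ²_e,k, independent across probes (diagonal R), with a flat prior on
  (var_floor, ∞).
* **Missing cells** (NaN) are simply dropped from the observation vector;
  the mixed model tolerates the resulting unbalancedness.

### Prior families

* `SG` — p_k ~ N(0, σ²_p), d_k ~ N(0, σ²_d) independently.
* `AT` — each effect follows the univariate Sahu skew-t, represented by
  augmentation: s_k ~ Gamma(ν/2, rate ν/2), u_k ~ N+(0, 1/s_k),
  x_k | u_k, s_k ~ N(λ u_k, σ²/s_k). Marginally

      f(x) = 2 t_ν(x/ω)/ω · T_{ν+1}((λ/σ)(x/ω)√((ν+1)/(ν+x²/ω²))),
      ω² = σ² + λ².

  σ² is the *kernel* scale (variance of the Gaussian part), not the
  marginal variance; the marginal variance is
  σ²ν/(ν−2) + λ²(ν/(ν−2) − (ν/π)(Γ((ν−1)/2)/Γ(ν/2))²), and the marginal
  mean is λ√(ν/π)Γ((ν−1)/2)/Γ(ν/2). λ = 0 gives the symmetric Student's
  t; ν → ∞ gives the skew-normal 2φ(x; 0, ω²)Φ(λx/(σω)); both give the
  Gaussian.
* `ST` — the AT family with λ pinned at 0 throughout.

The probe and differential blocks have independent hyperparameters
(σ²_p, ν_p, λ_p) and (σ²_d, ν_d, λ_d).

### Hyperpriors (defaults, units)

| Parameter | Prior | Default | Why |
|---|---|---|---|
| λ_p, λ_d (log2 units) | uniform on [−L, L] | L = 10 | diffuse; real-data asymmetry estimates are O(1), so ±10 is effectively unbounded while keeping the conditional proper |
| ν_p, ν_d (dimensionless) | exponential, truncated below | lower bound 4, rate 0.1 | ν > 4 guarantees finite kurtosis and keeps the t away from its pathological regime; rate 0.1 puts the prior mean at 14 with mass across the 4–30 range where real-data estimates fall |
| σ²_p, σ²_d, σ²_e,k | flat on (10⁻⁸, ∞) | — | scaled-inverse-χ² conditionals with df = m−2 or n_k−2; proper alternatives (prior df/scale) are exposed because joint-distribution sampler validation needs integrable priors |
| a_i | flat (Gaussian with variance ∞) | — | systematic effects |

## Sampler

One sweep updates: a → (p, d) → latents (u, s) → level translations →
λ → ν → variances. All location and variance updates are exact full
conditionals; ν uses random-walk Metropolis on log(ν − ν_lower) (with the
Jacobian term), its proposal scale adapted during burn-in toward 20–50%
acceptance and frozen afterwards.

Numerical choices:

* **Truncated-normal draws** for u_k use inverse-CDF sampling in log
  space (`ndtri_exp ∘ log_ndtr`), accurate arbitrarily far into the tail;
  this matters because an effect strongly opposed in sign to λ pushes the
  positive-truncated conditional many SDs above its mean.
* **Translation moves.** The flat prior on a leaves the likelihood
  invariant under (a + c, p − c) and, on group-2 arrays, (a + c, d − c).
  Single-site Gibbs crawls along these ridges, so each sweep resamples
  the shared level c from its exact conditional (a standard
  partial-resampling move). Without it, λ and the effect levels mix
  pathologically slowly.
* **Initialization** is moment-based (column means for a, group means for
  p and d, residual moments for variances, u = s = 1, λ = 0, ν = 8); rows
  with no within-group variation trigger a warning and a jittered
  initial residual variance. A variance floor of 10⁻⁸ guards degenerate
  conditionals; non-finite deviance aborts the chain with a diagnostic.
* **Storage.** Full traces are kept only for the scalar hyperparameters
  (thinned, default 10); per-probe effects are tracked by running
  first/second moments, the fitted-value grid by a running mean, and d_k
  by sign counters accumulated at every post-burn-in iteration — these
  are exactly the sufficient statistics for the summaries, DIC and the
  DE test, and bound memory at m ~ 10⁴ probes.
* Determinism: every draw flows from one `numpy` Generator seeded by
  `ModelSpec.seed`; identical seeds give bit-identical chains.

Sampler exactness is validated by a Geweke-style joint-distribution test
(marginal-conditional prior draws vs successive-conditional chain draws
on a 3-probe, 4-array model with proper priors; 64 first/second-moment
statistics, all |z| < 4) and by checking that the augmentation chain's
marginal reproduces the closed-form skew-t density (KS test).

## Posterior summaries, DIC, DE calling

* **Mode**: argmax of a Silverman-bandwidth Gaussian KDE evaluated on a
  512-point grid over the trace range. **HPD95**: shortest contiguous
  window containing ⌈0.95 n⌉ sorted draws.
* **DIC**: deviance is −2 log of the heteroskedastic Gaussian likelihood
  *conditional on the location effects and residual variances* (random
  effects in focus). Dbar averages per-iteration deviances over all
  post-burn-in iterations; Dhat evaluates the deviance at the posterior
  means of the per-observation fitted values and per-probe residual
  variances; pD = Dbar − Dhat. The in-focus choice makes pD count the
  per-probe effective parameters, which is what produces large
  between-model complexity differences. Verified against the closed-form
  effective-parameter count m·tr(Σ_post X'X/σ²) in a conjugate Gaussian
  setting.
* **DE test**: probe k is flagged when min(P(d_k > 0), P(d_k < 0)) <
  α/π, with π the number of probes analyzed and α = 0.05 by default. The
  tail probabilities come from the sign counters, so their resolution is
  1/(number of accumulated iterations); chains should be long enough
  that α/π exceeds a few times that resolution. The rule is two-sided in
  the sense that either tail can trigger the flag.

## Synthetic data

`simulate_dataset` draws from exactly the generative model above:
p_k ~ skew-t(σ²_p, ν_p, λ_p), d_k ~ skew-t(σ²_d, ν_d, λ_d),
σ²_e,k log-normal, a_i uniform. Defaults define the study conditions
used throughout the validation suite: m = 2000 probes, 6 vs 14 arrays
(an unbalanced design typical of public two-group series), σ²_p = 1,
ν_p = 8, λ_p = 2 (strong right-hand asymmetry of probe effects),
σ²_d = 0.25, ν_d = 8, λ_d = −1.5 (left-hand asymmetric differential
expression), residual variances log-normal with median 0.25 and log-SD
0.5 (squared log2 units), array effects uniform on [7, 9] (typical log2
intensity level). `spike_null_differentials` forces a chosen fraction of
d_k exactly to zero, recording which, so false-positive behavior is
measurable against known nulls.

What the generator does *not* emulate: probe-level platform artifacts,
batch effects, normalization failures, correlated residuals between
probes, or probe-set summarization. Passing the validation suite
therefore shows that the implementation is faithful to its own model
and recovers its parameters under realistic sizes — not that the model
captures every feature of real array data.

Validation scales (chosen to keep the suite desk-sized): recovery fits
use 20,000 iterations with 2,000 burn-in on the m = 2000 conditions;
comparison fits 8,000–12,000 iterations; the spiked specificity run uses
m = 1000 with 90% nulls. Full-data analyses would use the 500,000 / 50,000
defaults exposed by the CLI.

## Design choices on open points

* **Spiked specificity regime.** The specificity experiment uses a
  symmetric signal (λ_d = 0) for the 10% non-null probes. Under a
  strongly asymmetric signal the fitted AT asymmetry shifts the null
  cluster away from zero, which is a power regime rather than a
  specificity one.
* **Known limitation — Gaussian priors on spiked-null data.** With 90%
  exact zeros among the d_k, the SG model's σ²_d posterior collapses
  toward the null variance and, because residual variances are
  gene-specific and free, large spiked signals are partly absorbed into
  σ²_e,k: SG then flags essentially nothing, while the robust ST/AT
  priors adapt locally (small s_k for outlying effects) and retain
  power. Consequently the "AT flags are nested inside SG flags" behavior
  seen on real data — where all effects follow a smooth common
  distribution and no point-mass of exact nulls exists — does not
  transfer to spiked-null simulations; there AT is the more powerful
  model, with false positives still at zero. The corresponding
  validation check documents this expectation.
* **DIC focus** (above) is the random-effects-in-focus deviance; a
  marginalized focus would need intractable integrals over the skew-t
  and would not count per-probe parameters.
* **ν truncation at 4** is configurable; analyses expecting
  ultra-heavy tails can lower it at the cost of (possibly) infinite
  kurtosis regimes.
* Whether rows are individual probes or summarized probe sets is left to
  the user; the model is agnostic ("probes" throughout).
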