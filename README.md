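# skewtde

Bayesian hierarchical mixed models with **skew-t random effects** for
two-group, single-channel (non-competitive) microarray differential
expression.

Gene expression data are routinely modeled with zero-mean Gaussian random
effects, yet probe-level intensities show heavy tails (outlier expression)
and asymmetry (over-expressed right or left tails) even after
normalization. `skewtde` fits the mixed model

```
y = X a + Z1 p + Z2 d + e
```

where, for probe *k* on array *i*, the observation decomposes into the
systematic array effect *a_i*, the probe effect *p_k*, the within-probe
differential-expression effect *d_k* (present only for treatment-group-2
observations) and a heteroskedastic residual *e_ik ~ N(0, σ²_e,k)* with
**gene-specific residual variances**. Three prior families for the random
effects (p, d) are available:

| Model | Prior on p_k and d_k |
|-------|----------------------|
| `SG`  | zero-mean Gaussian, variances σ²_p, σ²_d |
| `ST`  | symmetric Student's t (AT with λ = 0) |
| `AT`  | asymmetric Student's t (Sahu parameterization) |

The AT prior is built by data augmentation: conditional on a positive
latent *u_k* and a Gamma(ν/2, rate ν/2) mixing variable *s_k*, the effect
is Gaussian, `x_k | u_k, s_k ~ N(λ u_k, σ²/s_k)` with
`u_k ~ N+(0, 1/s_k)`. Marginally *x_k* follows the skew-t density

```
f(x) = 2 t_ν(x/ω)/ω · T_{ν+1}( (λ/σ)(x/ω) √((ν+1)/(ν + x²/ω²)) ),   ω² = σ² + λ²
```

with degrees of freedom ν (tail weight: ν < 10 means substantial outlier
incidence, ν > 30 is practically Gaussian) and asymmetry λ (λ = 0 perfect
symmetry; positive/negative λ inflates the right/left tail). A uniform
prior is placed on λ, a truncated exponential prior on ν, flat priors on
the variance parameters.

All unknowns are sampled by a Gibbs sampler (Gaussian and
scaled-inverse-χ² full conditionals, truncated-normal and Gamma draws for
the latents, random-walk Metropolis for ν). Models are compared by the
deviance information criterion, `DIC = Dbar + pD` with
`pD = Dbar − Dhat`; differences above 3–5 DIC units are treated as
relevant. Differential expression is called per probe from posterior tail
probabilities of *d_k* against a Bonferroni-like threshold **α/π** (π =
number of probes analyzed); per-parameter summaries are reported as the
posterior mode with the shortest 95% highest-posterior-density interval.

Intended users: statistical-genomics researchers analyzing two-condition
expression matrices (e.g. GEO series exported as tab-separated text) who
want robust, asymmetry-aware random-effect modeling rather than the
standard Gaussian mixed-model analysis.

## Worked example

Simulate a 500-probe, 5 vs 5 dataset with right-skewed probe effects
(λ_p = 2, ν_p = 8) and left-skewed differential effects (λ_d = −1.5,
ν_d = 8), then fit Model AT:

```bash
skewtde simulate --outdir demo --m 500 --n1 5 --n2 5 --seed 7
skewtde fit --model AT \
    --expression demo/expression.tsv \
    --metadata demo/expression_metadata.tsv \
    --outdir demo/fit_at --n-iter 5000 --burn-in 1000 --thin 2 --seed 1
```

The fit prints its DIC record:

```json
{
  "model": "AT",
  "dbar": 7687.635909979364,
  "dhat": 6897.353122941849,
  "pd": 790.2827870375158,
  "dic": 8477.918697016881,
  "n_significant": 127
}
```

`pd ≈ 790` effective parameters reflects the per-probe random effects in
focus; 127 probes pass the α/π = 0.05/500 threshold (the simulated
differential effects are globally shifted left, so many probes are truly
differential). `demo/fit_at/hyperparameter_summary.tsv` holds the
mode/HPD95 summaries, e.g.

```
parameter   mode    hpd_lower  hpd_upper
sigma2_p    0.902   0.584      1.421
sigma2_d    0.192   0.055      0.418
nu_p        11.269  5.829      24.368
```

covering the generating values σ²_p = 1, σ²_d = 0.25. Other outputs:
`differential_expression.tsv` (per-probe tail probabilities and flags),
`scalar_trace.tsv` (hyperparameter traces), `probe_summary.tsv`,
`run_manifest.json` (seed, versions, config hash). `skewtde compare`
fits all three families and writes `dic_comparison.json`. The full-data
defaults are a 500,000-iteration chain with 50,000 burn-in; the short
chains above are for the demo.

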