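"""Sampler unit checks: determinism, individual full conditionals,
reductions between families, and small-scale parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from skewtde import (
    ExpressionDataSet,
    ModelSpec,
    build_design,
    run_chain,
    simulate_dataset,
)
from skewtde.sampler import GibbsSampler


def tiny_design(m=3, n1=2, n2=2, seed=0):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    ds = ExpressionDataSet(
        rng.normal(0.0, 1.0, size=(m, n)),
        [f"p{k}" for k in range(m)],
        [f"a{i}" for i in range(n)],
        np.array([1] * n1 + [2] * n2),
    )
    return build_design(ds)


def test_chain_determinism():
    ds, _ = simulate_dataset(m=50, n1=3, n2=3, seed=11)
    design = build_design(ds)
    spec = ModelSpec(family="AT", n_iter=400, burn_in=100, thin=2, seed=99)
    s1 = run_chain(design, spec)
    s2 = run_chain(design, spec)
    assert s1.scalars.equals(s2.scalars)
    np.testing.assert_array_equal(s1.d_mean, s2.d_mean)
    np.testing.assert_array_equal(s1.fitted_mean, s2.fitted_mean)


def test_stored_iteration_count():
    ds, _ = simulate_dataset(m=20, n1=2, n2=2, seed=1)
    design = build_design(ds)
    spec = ModelSpec(family="SG", n_iter=1000, burn_in=100, thin=7, seed=0)
    samples = run_chain(design, spec)
    assert samples.n_stored == (1000 - 100) // 7 == spec.n_stored
    assert samples.n_accum == 900


def test_sg_recovers_variance_components():
    """Gaussian-prior fit on Gaussian-simulated data recovers the
    generating variance components within 3 posterior SDs."""
    ds, truth = simulate_dataset(
        m=200, n1=5, n2=5, lam_p=0.0, lam_d=0.0, nu_p=1e6, nu_d=1e6,
        sigma2_p=1.0, sigma2_d=0.25, seed=21,
    )
    design = build_design(ds)
    spec = ModelSpec(family="SG", n_iter=20_000, burn_in=2_000, thin=10, seed=8)
    samples = run_chain(design, spec)
    for name, true_val in (("sigma2_p", 1.0), ("sigma2_d", 0.25)):
        tr = samples.hyperparameter_trace(name)
        assert abs(tr.mean() - true_val) < 3 * tr.std(), name


def test_st_equals_at_with_lambda_pinned():
    """ST is AT with lambda fixed at 0: fits agree within Monte-Carlo error."""
    ds, _ = simulate_dataset(m=150, n1=4, n2=4, lam_p=0.0, lam_d=0.0, seed=31)
    design = build_design(ds)
    st = run_chain(design, ModelSpec(family="ST", n_iter=6000, burn_in=1000, seed=2))
    at0 = run_chain(
        design,
        ModelSpec(family="AT", lam_bound=0.0, n_iter=6000, burn_in=1000, seed=2),
    )
    assert np.all(at0.hyperparameter_trace("lam_p") == 0.0)
    for name in ("sigma2_p", "sigma2_d", "nu_p", "nu_d"):
        a = st.hyperparameter_trace(name)
        b = at0.hyperparameter_trace(name)
        se = np.sqrt(a.std() ** 2 + b.std() ** 2) / np.sqrt(len(a) / 20.0)
        assert abs(a.mean() - b.mean()) < 4 * max(se, 1e-3), name


class TestLatentConditionals:
    def _sampler_state(self, m, seed=5):
        design = tiny_design(m=m, seed=seed)
        spec = ModelSpec(family="AT", n_iter=10, burn_in=0, seed=seed)
        sampler = GibbsSampler(design, spec)
        rng = np.random.default_rng(seed)
        state = sampler.initial_state(rng)
        return sampler, state, rng

    def test_mixing_variable_gamma_conditional(self):
        """With lambda=0, sigma2=1, x=0, nu=4: s | u ~ Gamma(3, (4+u^2)/2),
        so E[s * (4+u^2)/6 | u] = 1."""
        m = 40_000
        sampler, state, rng = self._sampler_state(m)
        state.p = np.zeros(m)
        state.lam_p = 0.0
        state.sigma2_p = 1.0
        state.nu_p = 4.0
        sampler.update_latents(state, rng)
        ratio = state.s_p * (4.0 + state.u_p**2) / 6.0
        assert ratio.mean() == pytest.approx(1.0, abs=4 / np.sqrt(m))

    def test_skewing_variable_half_normal_at_symmetry(self):
        """With lambda=0 and x=0 the u conditional is half-normal with scale
        1/sqrt(s): E[u * sqrt(s)] = sqrt(2/pi)."""
        m = 40_000
        sampler, state, rng = self._sampler_state(m)
        state.p = np.zeros(m)
        state.lam_p = 0.0
        state.sigma2_p = 1.0
        state.nu_p = 6.0
        s_before = state.s_p.copy()  # u is drawn conditional on current s
        sampler.update_latents(state, rng)
        z = state.u_p * np.sqrt(s_before)
        assert z.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=4 / np.sqrt(m))
        assert np.all(state.u_p > 0)


class TestAsymmetryConditional:
    def test_regression_through_origin_mean(self):
        """Equal latents reduce the lambda conditional to regression through
        the origin: the draw concentrates at sum(u x)/sum(u^2)."""
        m = 40_000
        design = tiny_design(m=m, seed=6)
        spec = ModelSpec(family="AT", n_iter=10, burn_in=0, seed=6)
        sampler = GibbsSampler(design, spec)
        rng = np.random.default_rng(6)
        state = sampler.initial_state(rng)
        x = rng.normal(1.5, 0.2, size=m)
        state.p = x
        state.u_p = np.ones(m)
        state.s_p = np.ones(m)
        state.sigma2_p = 1.0
        sampler.update_asymmetry(state, rng)
        expected = x.mean()  # sum(u x) / sum(u^2) with u == 1
        assert state.lam_p == pytest.approx(expected, abs=5 / np.sqrt(m))

    def test_lambda_recovery_from_known_latents(self):
        """Effects generated as lam*u + noise with known u: the conditional
        mean of lambda sits within 3 conditional SDs of the truth."""
        m = 5000
        rng = np.random.default_rng(7)
        design = tiny_design(m=m, seed=7)
        spec = ModelSpec(family="AT", n_iter=10, burn_in=0, seed=7)
        sampler = GibbsSampler(design, spec)
        state = sampler.initial_state(rng)
        u = np.abs(rng.standard_normal(m))
        state.u_p = u
        state.s_p = np.ones(m)
        state.sigma2_p = 1.0
        state.p = 2.0 * u + rng.standard_normal(m)
        draws = np.array([
            (sampler.update_asymmetry(state, rng), state.lam_p)[1]
            for _ in range(200)
        ])
        cond_sd = 1.0 / np.sqrt(np.sum(u * u))
        assert abs(draws.mean() - 2.0) < 3 * cond_sd + 5 * cond_sd / np.sqrt(200)

    def test_zero_bound_pins_lambda(self):
        design = tiny_design(m=5)
        spec = ModelSpec(family="AT", lam_bound=0.0, n_iter=10, burn_in=0, seed=1)
        sampler = GibbsSampler(design, spec)
        rng = np.random.default_rng(1)
        state = sampler.initial_state(rng)
        state.lam_p = 0.7
        sampler.update_asymmetry(state, rng)
        assert state.lam_p == 0.0 and state.lam_d == 0.0


class TestNuUpdate:
    def test_posterior_mode_recovery(self):
        """Mixing variables simulated at nu=8 pull the sampled nu into
        [6, 10]."""
        m = 10_000
        rng = np.random.default_rng(17)
        design = tiny_design(m=20, seed=17)  # design size irrelevant here
        spec = ModelSpec(family="AT", n_iter=10, burn_in=0, seed=17,
                         adapt_nu_proposal=False)
        sampler = GibbsSampler(design, spec)
        state = sampler.initial_state(np.random.default_rng(17))
        sampler.m = m  # nu conditional only sees the mixing vector length
        state.s_p = rng.gamma(4.0, 1 / 4.0, size=m)
        state.s_d = state.s_p
        trace = []
        for _ in range(2000):
            sampler.update_nu(state, rng)
            trace.append(state.nu_p)
        assert 6.0 < np.mean(trace[500:]) < 10.0

    def test_mh_ratio_matches_brute_force_density(self):
        design = tiny_design(m=100, seed=3)
        spec = ModelSpec(family="AT", n_iter=10, burn_in=0, seed=3)
        sampler = GibbsSampler(design, spec)
        rng = np.random.default_rng(3)
        s = rng.gamma(3.0, 1 / 3.0, size=100)
        for nu in (5.0, 9.0, 25.0):
            direct = (
                stats.gamma.logpdf(s, a=nu / 2, scale=2 / nu).sum()
                - spec.nu_prior_rate * (nu - spec.nu_lower)
            )
            kernel = sampler._nu_logpost(nu, s)
            # identical up to a nu-free constant: compare differences
            if nu == 5.0:
                offset = direct - kernel
            else:
                assert direct - kernel == pytest.approx(offset, abs=1e-8)

    def test_truncation_respected(self):
        design = tiny_design(m=50, seed=4)
        spec = ModelSpec(family="AT", nu_lower=4.0, n_iter=10, burn_in=0, seed=4)
        sampler = GibbsSampler(design, spec)
        rng = np.random.default_rng(4)
        state = sampler.initial_state(rng)
        state.nu_p = 4.05
        for _ in range(500):
            sampler.update_nu(state, rng)
            assert state.nu_p > 4.0 and state.nu_d > 4.0


class TestVarianceConditionals:
    def test_residual_variance_matches_inverse_chi_square(self):
        """Flat prior: sigma2_e,k | . ~ SSR_k / chisq(n_k - 2)."""
        design = tiny_design(m=3, n1=5, n2=5, seed=8)
        spec = ModelSpec(family="SG", n_iter=10, burn_in=0, seed=8)
        sampler = GibbsSampler(design, spec)
        rng = np.random.default_rng(8)
        state = sampler.initial_state(rng)
        fitted = state.a[None, :] + state.p[:, None] + np.outer(state.d, sampler.g2f)
        ssr0 = (((sampler.Y - fitted) * sampler.M) ** 2).sum(axis=1)[0]
        draws = []
        for _ in range(4000):
            sampler.update_variances(state, rng)
            draws.append(state.sigma2_e[0])
        res = stats.ks_1samp(
            draws, stats.invgamma(a=(10 - 2) / 2, scale=ssr0 / 2).cdf
        )
        assert res.pvalue > 0.01

    def test_heteroskedastic_recovery(self):
        """Three known residual-variance tiers are recovered within 20%."""
        rng = np.random.default_rng(9)
        m, n1, n2 = 150, 25, 25
        tiers = np.repeat([0.25, 1.0, 4.0], m // 3)
        values = rng.normal(0.0, 1.0, size=(m, 1)) + rng.standard_normal(
            (m, n1 + n2)
        ) * np.sqrt(tiers)[:, None]
        ds = ExpressionDataSet(
            values, [f"p{k}" for k in range(m)],
            [f"a{i}" for i in range(n1 + n2)],
            np.array([1] * n1 + [2] * n2),
        )
        samples = run_chain(
            build_design(ds),
            ModelSpec(family="SG", n_iter=3000, burn_in=500, seed=10),
        )
        for tier in (0.25, 1.0, 4.0):
            est = samples.sigma2_e_mean[tiers == tier].mean()
            assert est == pytest.approx(tier, rel=0.2)

    def test_constant_probe_row_warns_and_runs(self):
        values = np.random.default_rng(2).normal(size=(10, 6))
        values[3] = 5.0  # zero-variance row
        ds = ExpressionDataSet(
            values, [f"p{k}" for k in range(10)],
            [f"a{i}" for i in range(6)], np.array([1, 1, 1, 2, 2, 2]),
        )
        design = build_design(ds)
        spec = ModelSpec(family="SG", n_iter=200, burn_in=50, seed=1)
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            run_chain(design, spec)
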