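"""Shared fixtures.

The expensive MCMC fits used by the model-validation tests are
session-scoped so that the recovery, DIC-ordering and DE-calling checks
share chains instead of refitting.
"""

from __future__ import annotations

import numpy as np
import pytest

from skewtde import (
    ModelSpec,
    SimulationTruth,
    build_design,
    run_chain,
    simulate_dataset,
    spike_null_differentials,
)

#: Study conditions for the skewed-simulation experiments: unbalanced
#: 6 vs 14 arrays, m=2000 probes, right-skewed heavy-tailed probe effects
#: (lam_p=2, nu_p=8) and left-skewed differential effects (lam_d=-1.5,
#: nu_d=8) — the generator defaults.
SKEW_TRUTH = dict(
    sigma2_p=1.0, nu_p=8.0, lam_p=2.0,
    sigma2_d=0.25, nu_d=8.0, lam_d=-1.5,
)


@pytest.fixture(scope="session")
def skew_data():
    """Default-conditions simulation (m=2000, 6 vs 14) plus its design."""
    ds, truth = simulate_dataset(seed=101)
    return ds, truth, build_design(ds)


@pytest.fixture(scope="session")
def skew_fit_at(skew_data):
    """Model AT fitted to the skewed simulation: 20k iterations, 2k burn-in."""
    _, _, design = skew_data
    spec = ModelSpec(family="AT", n_iter=20_000, burn_in=2_000, thin=10, seed=7)
    return run_chain(design, spec)


@pytest.fixture(scope="session")
def skew_fit_st(skew_data):
    _, _, design = skew_data
    spec = ModelSpec(family="ST", n_iter=12_000, burn_in=2_000, thin=10, seed=7)
    return run_chain(design, spec)


@pytest.fixture(scope="session")
def skew_fit_sg(skew_data):
    _, _, design = skew_data
    spec = ModelSpec(family="SG", n_iter=8_000, burn_in=2_000, thin=10, seed=7)
    return run_chain(design, spec)


@pytest.fixture(scope="session")
def gaussian_data_fits():
    """SG-simulated data (symmetric, light tails) with SG and AT fits."""
    ds, truth = simulate_dataset(
        m=1000, n1=6, n2=14, lam_p=0.0, lam_d=0.0, nu_p=1e6, nu_d=1e6, seed=202
    )
    design = build_design(ds)
    fits = {}
    for fam, iters in (("SG", 8_000), ("AT", 12_000)):
        spec = ModelSpec(family=fam, n_iter=iters, burn_in=2_000, thin=10, seed=3)
        fits[fam] = run_chain(design, spec)
    return design, fits


@pytest.fixture(scope="session")
def spiked_null_fits():
    """90%-null spiked simulation (m=1000, symmetric heavy-tailed signal)
    fitted with all three model families."""
    truth = SimulationTruth(m=1000, n1=6, n2=14, lam_d=0.0, seed=303)
    truth = spike_null_differentials(truth, 0.9)
    ds, done = simulate_dataset(truth)
    design = build_design(ds)
    fits = {}
    for fam, iters in (("SG", 8_000), ("ST", 10_000), ("AT", 12_000)):
        spec = ModelSpec(family=fam, n_iter=iters, burn_in=2_000, thin=10, seed=5)
        fits[fam] = run_chain(design, spec)
    return done, design, fits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
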