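"""Shared fixtures: small synthetic survival problems built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from coxmds import simdata


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture()
def small_cox_problem(rng):
    """A modest Cox regression instance with known sparse signal."""
    n, d = 200, 6
    P = rng.standard_normal((n, d))
    U = np.column_stack([rng.binomial(1, 0.5, n), rng.uniform(0, 1, n)])
    beta = np.array([0.8, -0.6, 0.0, 0.0, 0.4, 0.0])
    gam = np.array([0.5, -0.3])
    lam = 0.5 * np.exp(P @ beta + U @ gam)
    D = rng.exponential(1 / lam)
    C = rng.exponential(2.0, n)
    T = np.minimum(D, C)
    E = (D <= C).astype(int)
    return dict(times=T, events=E, P=P, U=U, beta=beta, gamma=gam)


@pytest.fixture(scope="session")
def tiny_scenario_config():
    """Scaled-down correlated-Gaussian condition for pipeline-level tests."""
    return simdata.SimConfig(
        n=160, p=300, rho=0.5, kappa_alpha=0.8, kappa_beta=0.6,
        target_censoring=0.3,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scenario_config):
    c0 = simdata.calibrate_censoring(tiny_scenario_config)
    data, truth = simdata.simulate_dataset(tiny_scenario_config, seed=42, c0=c0)
    return data, truth
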