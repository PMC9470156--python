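"""Shared fixtures: small reference life cycles and cached model runs.

Session scope is used for the expensive deterministic runs (fitness
landscapes, Lande trajectories) so multiple tests can assert different
properties of the same computation.
"""

import numpy as np
import pytest

import etidyn as e


@pytest.fixture(scope="session")
def n2_lifecycle() -> e.LifeCycle:
    """Two-class cycle with A = [[0.5, 1.0], [0.2, 0.6]] and lambda = 1."""
    return e.LifeCycle(gamma=[0.2, 0.0], mu=[0.0, 0.1], delta=[0.5, 0.3], beta=[0.2, 0.9])


@pytest.fixture(scope="session")
def fig5_params() -> e.TradeoffParams:
    return e.TradeoffParams(N=30, eta=8.0, p1=0.1)


@pytest.fixture(scope="session")
def fig5_landscape(fig5_params):
    return e.fitness_landscape(fig5_params, 1001)


@pytest.fixture(scope="session")
def fig5_run(fig5_params):
    """1D Lande ascent on F(theta) from the counterfactual optimum theta0 = 0."""
    return e.evolve_tradeoff_1d(fig5_params, theta0=0.0, sigma_theta=0.01)


@pytest.fixture(scope="session")
def fig7_run():
    """2D (s, b) run with the strongly anticorrelated kernel."""
    params = e.TradeoffParams(N=15, eta=8.0, p1=0.1)
    kernel = e.MutationKernel(sigma_s=0.05, sigma_b=0.05, rho=-0.9)
    return e.evolve_tradeoff_2d(params, kernel, start=(0.0, 1.0), t_max=1e4)


@pytest.fixture(scope="session")
def box2_run():
    """Scaffolding (q, beta) run at the published parameter point."""
    params = e.ScaffoldParams(
        Npatch=1e6, T=30.0, d=0.0, rho_soma=0.01, q=0.0, beta_trait=1.8
    )
    kernel = e.MutationKernel(sigma_s=0.001, sigma_b=0.1, rho=0.0)
    return e.evolve_scaffold(params, kernel)


@pytest.fixture(scope="session")
def box3_run():
    """Ratcheting (delta_c, p) run at the published parameter point."""
    return e.evolve_ratchet()


def random_primitive_lifecycle(rng: np.random.Generator, N: int) -> e.LifeCycle:
    """Sample a valid life cycle satisfying the primitivity sufficient
    condition (all alpha in (0, 1), all beta > 0)."""
    # split the unit interval so gamma + mu + delta <= 0.9 and alpha >= 0.1
    gamma = rng.uniform(0.05, 0.3, N)
    mu = rng.uniform(0.05, 0.3, N)
    delta = rng.uniform(0.05, 0.3, N)
    gamma[-1] = 0.0
    mu[0] = 0.0
    beta = rng.uniform(0.1, 1.0, N)
    return e.LifeCycle(gamma=gamma, mu=mu, delta=delta, beta=beta)
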