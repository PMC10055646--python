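import numpy as np
import pytest

import hillode as h


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_theta(n, m, seed=0, scale=0.8, mixed_gates=False):
    """A generic random parameter set with order-one weights."""
    rng = np.random.default_rng(seed)
    theta = h.init_params(n, m, rng, weight_scale=scale)
    theta.b_sum = rng.normal(0, 0.3, m)
    theta.b_prod = rng.normal(0, 0.3, m)
    if mixed_gates:
        theta.v = rng.normal(0.4, 0.6, n)
    return theta


def decay_theta(n=1):
    """Parameters realizing dg/dt = -g exactly (zero blocks, open gates)."""
    theta = h.init_params(n, n, 0, weight_scale=0.0)
    theta.W_combine[:] = 0.0
    return theta


@pytest.fixture
def small_theta():
    return random_theta(6, 4, seed=7, mixed_gates=True)


@pytest.fixture(scope="session")
def tiny_sim():
    """A 12-gene synthetic system with trajectories, reused across tests."""
    cfg = h.SimConfig(n_genes=12, n_edges=20, n_trajectories=30, seed=5)
    truth = h.generate_grn(cfg)
    trajs = h.simulate_trajectories(truth, cfg)
    return cfg, truth, trajs
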