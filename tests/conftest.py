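"""Shared fixtures: a separable window fixture and small trained networks.

The separable fixture mimics what the loop/background contrast looks like
after windowing: both classes share a flat Poisson background, and the
positive class carries a bright blob at the window centre, so a correctly
wired classifier can reach near-perfect accuracy quickly.
"""

import numpy as np
import pytest

from cdloop.diffusion import EpsNet, make_schedule, train_diffusion
from cdloop.prior import build_prior_net, train_prior


def make_separable_fixture(n: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    x = rng.poisson(2.0, size=(n, 28, 28)).astype(float)
    y = (rng.random(n) < 0.5).astype(int)
    for k in range(n):
        if y[k]:
            x[k, 11:16, 11:16] += rng.poisson(12.0, size=(5, 5))
    return x, y


@pytest.fixture(scope="session")
def separable_fixture():
    return make_separable_fixture(200, seed=0)


@pytest.fixture(scope="session")
def trained_prior(separable_fixture):
    x, y = separable_fixture
    net = build_prior_net(seed=0)
    net, history = train_prior(net, x, y, epochs=20, seed=0)
    return net, history


@pytest.fixture(scope="session")
def small_schedule():
    return make_schedule(50)


@pytest.fixture(scope="session")
def trained_diffusion(separable_fixture, trained_prior, small_schedule):
    x, y = separable_fixture
    pnet, _ = trained_prior
    enet = EpsNet(width=128, seed=0)
    enet, history = train_diffusion(enet, pnet, x, y, small_schedule,
                                    epochs=40, seed=0)
    return enet, history
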