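import numpy as np
import pytest

import epibranch as eb


@pytest.fixture(scope="session")
def reg3():
    """3-regular network degree distribution."""
    return eb.regular(3)


@pytest.fixture(scope="session")
def d3():
    """Heavy-tailed three-point distribution: masses 1/8, 5/6, 1/24 on 1, 3, 9."""
    return eb.make_distribution([(1, 1 / 8), (3, 5 / 6), (9, 1 / 24)])


@pytest.fixture(scope="session")
def model_reg3(reg3):
    """3-regular, tau=2, gamma=1: r = 1, w1 = (1/3, 1/3, 1/3, 0)."""
    return eb.build_model(reg3, 2.0, 1.0)


@pytest.fixture(scope="session")
def model_d3(d3):
    """Three-point distribution, tau=2, gamma=1: r = 7/3."""
    return eb.build_model(d3, 2.0, 1.0)


def random_model(rng, supercritical=None, k_support=6):
    """A random non-degenerate branching model for identity checks."""
    while True:
        n_support = rng.integers(2, k_support)
        degs = rng.choice(np.arange(1, k_support + 1), size=n_support, replace=False)
        w = rng.uniform(0.05, 1.0, size=n_support)
        dist = eb.make_distribution(list(zip(degs.tolist(), (w / w.sum()).tolist())))
        tau = rng.uniform(0.3, 3.0)
        gamma = rng.uniform(0.3, 3.0)
        mu = eb.size_bias(dist).mu_tilde_m2
        if abs(mu) < 0.1:
            continue
        model = eb.build_model(dist, tau, gamma)
        if supercritical is True and model.r <= 0.05:
            continue
        if supercritical is False and model.r >= -0.05:
            continue
        return model
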