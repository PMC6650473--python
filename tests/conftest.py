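import numpy as np
import pytest

from copulareid import make_scenario
from copulareid.bench import _zipf_probs  # noqa: F401  (used by tests)
from copulareid.copula import CopulaModel
from copulareid.marginals import categorical_marginal


@pytest.fixture(scope="session")
def tiny_binary():
    return make_scenario("tiny_binary")


@pytest.fixture(scope="session")
def tiny_mixed():
    return make_scenario("tiny_mixed")


@pytest.fixture(scope="session")
def small_model():
    """A 3-attribute (3 x 4 x 2 cells) model with known parameters."""
    sigma = np.array([[1.0, 0.5, 0.2],
                      [0.5, 1.0, 0.4],
                      [0.2, 0.4, 1.0]])
    margs = [categorical_marginal([0.5, 0.3, 0.2]),
             categorical_marginal([0.4, 0.3, 0.2, 0.1]),
             categorical_marginal([0.6, 0.4])]
    return CopulaModel(sigma=sigma, marginals=margs, population_size=1000)


def pair_model(sigma, psi_i, psi_j, n=10):
    """Bivariate copula model helper for association tests."""
    s = np.array([[1.0, sigma], [sigma, 1.0]])
    return CopulaModel(sigma=s, marginals=[psi_i, psi_j], population_size=n)
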