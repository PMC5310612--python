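import numpy as np
import pandas as pd
import pytest

from eggdiscrim.psychometrics import TrialTable
from eggdiscrim.synthetic_data import make_visual_system
from eggdiscrim.visual_model import chromatic_basis, receptor_noise


@pytest.fixture(scope="session")
def vs_default():
    return make_visual_system()


@pytest.fixture(scope="session")
def noise_default(vs_default):
    return receptor_noise(vs_default)


@pytest.fixture(scope="session")
def basis_default(noise_default):
    return chromatic_basis(noise_default)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_logistic_table(
    n: int, beta0: float, beta1: float, seed: int = 0, xlo=-2.0, xhi=6.0
) -> TrialTable:
    """Direct logistic-response table: response ~ Bernoulli(expit(b0 + b1 x))."""
    g = np.random.default_rng(seed)
    x = g.uniform(xlo, xhi, n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (g.uniform(size=n) < p).astype(int)
    return TrialTable(pd.DataFrame({"response": y, "x": x}))


@pytest.fixture()
def toy_table():
    """8-row table with a well-conditioned (non-separated) MLE."""
    x = np.array([-1.5, -1.0, -0.5, -0.2, 0.2, 0.5, 1.0, 1.5])
    y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
    return TrialTable(pd.DataFrame({"response": y, "x": x}))
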