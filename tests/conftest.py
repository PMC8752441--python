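import numpy as np
import pandas as pd
import pytest

from traitenv.synthdata import WorldConfig, simulate_world


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    cfg = WorldConfig(
        n_species=120,
        n_ecoregions=30,
        n_traits=17,
        seed=42,
        mean_extra_ecoregions=3.0,
    )
    obs, env, eco, truth = simulate_world(cfg)
    return obs, env, eco, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trait_frame(rng, n=60, p=4, positive=True):
    """Random trait table; lognormal when positive."""
    X = rng.normal(0.0, 1.0, (n, p))
    if positive:
        X = np.exp(X)
    return pd.DataFrame(X, columns=[f"t{j + 1}" for j in range(p)])
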