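import numpy as np
import pytest

from cafeh.data import GenotypePanel, TraitMatrix
from cafeh.infer import FitConfig, fit_g
from cafeh.simulate import SimDesign, simulate_two_group


@pytest.fixture(scope="session")
def two_group():
    """Seeded two-group dataset (T=4, q=1 per group, rho=0.2) and its fit."""
    design = SimDesign(N=500, G=200, T=4, q=1, rho=0.2, seed=3)
    panel, traits, truth = simulate_two_group(design)
    post = fit_g(panel, traits, config=FitConfig(K=10, seed=0))
    return panel, traits, truth, post


@pytest.fixture()
def small_panel():
    rng = np.random.default_rng(11)
    x = rng.standard_normal((60, 8))
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return GenotypePanel(x, [f"s{i}" for i in range(8)], standardized=True)


@pytest.fixture()
def noise_traits(small_panel):
    rng = np.random.default_rng(12)
    return TraitMatrix(rng.standard_normal((60, 2)), ["t1", "t2"])
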