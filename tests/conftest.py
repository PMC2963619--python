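import numpy as np
import pytest

from fvakit.fixtures import make_diamond, make_linear_pathway, make_random_model


@pytest.fixture
def linear_pathway():
    return make_linear_pathway(3, 10.0)


@pytest.fixture
def diamond():
    return make_diamond(10.0)


@pytest.fixture(scope="session")
def small_random_models():
    """A handful of seeded feasible random models for property checks."""
    rng = np.random.default_rng(42)
    models = []
    for i in range(8):
        m = int(rng.integers(3, 9))
        n = int(rng.integers(m + 3, 2 * m + 8))
        models.append(make_random_model(m, n, seed=500 + i))
    return models
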