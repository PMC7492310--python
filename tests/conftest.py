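import numpy as np
import pytest
from hypothesis import settings

from qsarkit.core import ActivitySeries, DescriptorTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_problem(rng, n=20, p=3, noise=0.1, seed_beta=None):
    """Random OLS problem with a known linear signal."""
    X = rng.standard_normal((n, p))
    beta = seed_beta if seed_beta is not None else rng.uniform(-2, 2, size=p)
    intercept = rng.uniform(-1, 1)
    y = intercept + X @ beta + noise * rng.standard_normal(n)
    ids = [f"c{i}" for i in range(n)]
    names = [f"x{j}" for j in range(p)]
    return (
        DescriptorTable.from_arrays(ids, names, X),
        ActivitySeries.from_values(ids, y),
        np.asarray(beta),
        float(intercept),
    )


@pytest.fixture
def make_problem(rng):
    def _make(**kw):
        return random_problem(rng, **kw)

    return _make


@pytest.fixture
def eq2():
    from qsarkit.io import reference_model

    return reference_model()
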