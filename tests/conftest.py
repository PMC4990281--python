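import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cyclenoise.models import BurstModel, PartitionModel
from cyclenoise.timing import ErlangMixture, erlang_mixture_from_target


@pytest.fixture
def erlang20():
    """Low-noise clock (CV_T^2 = 0.05) with unit mean."""
    return ErlangMixture((20,), (1.0,), 1.0)


@pytest.fixture
def exponential_clock():
    return ErlangMixture((1,), (1.0,), 1.0)


@pytest.fixture
def mixed_clock():
    """Adjacent-order mixture with CV_T^2 = 0.3."""
    return erlang_mixture_from_target(1.0, 0.3)


@pytest.fixture
def geometric_burst():
    """Geometric bursts on {0,1,...} with <B> = 1.5 arriving at rate 20."""
    return BurstModel.geometric(kx=20.0, burst_mean=1.5)


@pytest.fixture
def binomial_partition():
    return PartitionModel(alpha=1.0)


def random_mixture(rng: np.random.Generator, max_orders: int = 3) -> ErlangMixture:
    """A random valid Erlang mixture for property tests."""
    n = rng.integers(1, max_orders + 1)
    orders = np.sort(rng.choice(np.arange(1, 26), size=n, replace=False))
    probs = rng.dirichlet(np.ones(n))
    k = float(rng.uniform(0.2, 5.0))
    return ErlangMixture(tuple(int(i) for i in orders), tuple(probs), k)
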