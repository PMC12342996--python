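import numpy as np
import pytest

from argscope import fixtures, preprocess


@pytest.fixture
def canonical():
    return fixtures.canonical_example()


@pytest.fixture
def canonical_store(canonical):
    return preprocess.build_store(canonical)


@pytest.fixture(scope="session")
def sim_store():
    """A moderately sized simulated ARG store shared across tests."""
    ts = fixtures.simulate_wf_arg(
        fixtures.SimParams(n_samples=20, sequence_length=200.0, seed=42)
    )
    return preprocess.build_store(ts)


@pytest.fixture(scope="session")
def sweep_store():
    return preprocess.build_store(fixtures.sweep_example(seed=1))


def random_viewport(rng, sequence_length, t_max):
    from argscope.raster import Viewport

    x = np.sort(rng.uniform(0, sequence_length, 2))
    y = np.sort(rng.uniform(0, t_max * 1.1, 2))
    while x[0] == x[1]:
        x = np.sort(rng.uniform(0, sequence_length, 2))
    while y[0] == y[1]:
        y = np.sort(rng.uniform(0, t_max * 1.1, 2))
    return Viewport(float(x[0]), float(x[1]), float(y[0]), float(y[1]))
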