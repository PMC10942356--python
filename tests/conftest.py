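import numpy as np
import pytest

from ephate import SyntheticConfig, generate_dataset
from ephate.multiview import view_operator


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic cohort shared by fast tests."""
    return generate_dataset(SyntheticConfig(n=80, p=60, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_operator(rng):
    """Row-stochastic operator from random data, with affinity provenance."""
    X = rng.standard_normal((12, 4))
    return view_operator(X, k=3, alpha=10.0)


@pytest.fixture(scope="session")
def benchmark_results():
    """Five-seed representation benchmark on the planted-interaction cohort.

    Session-scoped: the headline-ordering and noise-control comparisons both
    read from this single computation.
    """
    from ephate import benchmark_representations

    out = {}
    for seed in range(5):
        ds = generate_dataset(SyntheticConfig(seed=seed))
        scores, comparisons = benchmark_representations(ds, seed=seed)
        out[seed] = (scores, comparisons)
    return out
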