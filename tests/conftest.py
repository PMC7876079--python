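import numpy as np
import pytest

from mikern import AbundanceTable, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_count_table(rng, n=20, d=30, zero_fraction=0.3, seed=None):
    """Random count table with the requested sparsity."""
    if seed is not None:
        rng = np.random.default_rng(seed)
    counts = rng.poisson(50, size=(n, d)).astype(float)
    mask = rng.random((n, d)) < zero_fraction
    mask[np.arange(n), counts.argmax(axis=1)] = False
    counts[mask] = 0.0
    return AbundanceTable(counts, [f"s{i}" for i in range(n)],
                          [f"t{j}" for j in range(d)])


def make_positive_table(rng, n=20, d=30, seed=None):
    """Random strictly positive (compositional-count-like) table."""
    if seed is not None:
        rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=2.0, sigma=1.0, size=(n, d))
    return AbundanceTable(vals, [f"s{i}" for i in range(n)],
                          [f"t{j}" for j in range(d)])


@pytest.fixture
def count_table(rng):
    return make_count_table(rng)


@pytest.fixture
def positive_table(rng):
    return make_positive_table(rng)


@pytest.fixture
def small_cfg():
    return SimulationConfig(n_individuals=40, n_taxa=60, n_informative=6,
                            effect_size=2.0, seed=7)
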