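import numpy as np
import pytest

from slgnn import SyntheticSpec, generate_benchmark, symmetrize_kg


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard desk-scale planted-factor benchmark (spec defaults)."""
    return generate_benchmark(SyntheticSpec())


@pytest.fixture(scope="session")
def mini_benchmark():
    """A very small benchmark for fast training smoke tests."""
    spec = SyntheticSpec(n_genes=60, n_relations=6, n_factors=4, n_triples=500,
                         n_sl_edges=150, context_per_factor_type=5, seed=7)
    kg, sl, gt = generate_benchmark(spec)
    return symmetrize_kg(kg), sl, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
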