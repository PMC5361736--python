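import numpy as np
import pytest

from knnmdr.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_genotypes():
    """Factory: iid genotype matrix with per-marker frequency in [0.2, 0.5]."""

    def make(n_ind, n_mark, seed=0):
        r = np.random.default_rng(seed)
        p = r.uniform(0.2, 0.5, size=n_mark)
        return r.binomial(2, p, size=(n_ind, n_mark)).astype(np.int8)

    return make


@pytest.fixture(scope="session")
def planted_dataset():
    """One strongly epistatic dataset reused across detection tests."""
    cfg = SimulationConfig(
        n_causal=2, n_cases=250, n_controls=250, n_markers=100,
        n_founders=100, block_size=10, effect_size=0.5, thin=False, seed=42,
        causal_idx=(23, 71),
    )
    return simulate_dataset(cfg)
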