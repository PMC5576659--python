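import pytest

from metseg.segio import ProteinChain, WindowConfig, extract_segments
from metseg.synthetic import SimulationSpec, generate_dataset


@pytest.fixture
def tiny_chain():
    return ProteinChain(
        id="tiny",
        sequence="ACDEFGHIKL",
        binding_positions=frozenset({3, 7}),
        ss="CCHHHEECCC",
        rsa=(0.1, 0.3, 0.5, 0.7, 0.2, 0.4, 0.45, 0.6, 0.15, 0.8),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """50 annotated chains with a clear planted center signal."""
    spec = SimulationSpec(
        n_chains=50, chain_length=100, site_density=2.0, L=7, theta=0.9, seed=0
    )
    chains, truth = generate_dataset(spec)
    return chains, truth, spec


@pytest.fixture(scope="session")
def small_segments(small_dataset):
    chains, _, spec = small_dataset
    cfg = WindowConfig(spec.L)
    return [s for chain in chains for s in extract_segments(chain, cfg)]
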