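import pytest

from tssline import (
    SimulationConfig,
    call_tss,
    classify_tss,
    generate_end_profiles,
    generate_genome,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def synthetic_dataset(default_config):
    """Default 200 kb / 100 gene synthetic genome with TEX+/- profiles."""
    genome, truth = generate_genome(default_config)
    tex_plus, tex_minus = generate_end_profiles(genome, truth, default_config)
    return genome, truth, tex_plus, tex_minus


@pytest.fixture(scope="session")
def called_classified(synthetic_dataset):
    genome, truth, tex_plus, tex_minus = synthetic_dataset
    records = call_tss(tex_plus, tex_minus)
    classify_tss(records, genome.features, len(genome))
    return genome, truth, records
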