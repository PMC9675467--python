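import pytest

from pascrispr import (
    SimConfig,
    scan_cds_pas,
    simulate_population,
    simulate_reference,
)


@pytest.fixture(scope="session")
def config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def gene(config):
    return simulate_reference(config)


@pytest.fixture(scope="session")
def population(config, gene):
    return simulate_population(config, gene)


@pytest.fixture(scope="session")
def scan_result(config, gene):
    records, summary = scan_cds_pas(gene.all_variants, gene.sequence, gene.transcript)
    return records, summary


@pytest.fixture(scope="session")
def clean_config():
    """No within-haplotype noise: consensus and subject calls are exact."""
    return SimConfig(seed=2, within_haplotype_noise=0.0)


@pytest.fixture(scope="session")
def clean_gene(clean_config):
    return simulate_reference(clean_config)


@pytest.fixture(scope="session")
def clean_population(clean_config, clean_gene):
    return simulate_population(clean_config, clean_gene)
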