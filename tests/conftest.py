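import pytest

from congenomics.simulate import SimulationConfig, simulate_congenic_design


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A fast two-chromosome design with one introgressed block containing
    the causal locus; used wherever full-scale realism is not the point."""
    defaults = dict(
        chromosome_lengths=(("1", 4_000_000), ("2", 3_000_000)),
        n_genes_per_chrom=25,
        donor_snp_density=30.0,
        introgressed_blocks=(("1", 1_000_000, 3_000_000),),
        causal_locus=("1", 1_500_000, 2_500_000),
        n_regulated_cyps=4,
        n_stabilized_cyps=2,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_congenic_design(small_config())


@pytest.fixture
def tiny_config():
    return small_config()
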