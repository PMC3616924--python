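import pytest

from forumdomains import SimConfig, simulate_expression, simulate_genome, simulate_raft_reads


@pytest.fixture(scope="session")
def small_sim():
    """One 2 Mb chromosome with ~80 planted hot spots, shared across tests."""
    cfg = SimConfig(
        chrom_lengths={"chr1": 2_000_000},
        hotspot_spacing_median=20_000,
        seed=11,
    )
    genome, truth = simulate_genome(cfg)
    reads, aligns = simulate_raft_reads(genome, truth, cfg)
    expr = simulate_expression(truth, cfg)
    return cfg, genome, truth, reads, aligns, expr
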