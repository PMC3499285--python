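import pytest

from defmine import SimulationConfig, simulate_genome, make_reference_panel


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study system shared across discovery tests."""
    cfg = SimulationConfig(
        seed=11, n_contigs=2, contig_length=50_000, n_planted_genes=5,
        three_exon_fraction=0.4,
    )
    contigs, truth = simulate_genome(cfg)
    panel = make_reference_panel(truth, (0.05, 0.25), seed=12)
    return cfg, contigs, truth, panel
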