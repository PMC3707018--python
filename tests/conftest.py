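import pytest

from draftanchor.formats_io import Assembly, SeqRecord
from draftanchor import simulate as sim


@pytest.fixture
def tiny_assembly() -> Assembly:
    return Assembly(
        records=[
            SeqRecord(id="s1", sequence="ACGTACGTNNACGT"),
            SeqRecord(id="s2", sequence="GGGGCCCC"),
        ],
        name="tiny",
    )


@pytest.fixture(scope="session")
def superscaffold_fixture():
    """Superscaffold preset: 1 Mb genome cut into 40 scaffolds, 4 map contigs."""
    cfg = sim.preset_config("superscaffold", seed=11)
    genome, _ = sim.simulate_genome(cfg)
    assembly, truth = sim.fragment_assembly(genome, cfg)
    pmap, tags = sim.generate_wgp_map(genome, truth, cfg)
    return cfg, genome, assembly, pmap, tags, truth


@pytest.fixture(scope="session")
def ispcr_fixture():
    """Marker preset: 200 kb genome with 50 planted primer pairs."""
    cfg = sim.preset_config("ispcr", seed=3)
    genome, _ = sim.simulate_genome(cfg)
    genome, table, truth = sim.plant_markers(genome, cfg)
    return cfg, Assembly([genome]), table, truth
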