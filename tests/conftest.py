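import pytest

from msgasm import build_graph
from msgasm.simulate import repeat_free_genome, tile_reads

# The printed worked example: three reads tiling the reference "TAGTCGAGG".
WORKED_READS = ["TAGTCG", "AGTCGA", "TCGAGG"]
WORKED_REFERENCE = "TAGTCGAGG"


@pytest.fixture
def worked_graph():
    """1-step bi-directed graph of the three worked-example reads at k=3."""
    return build_graph(WORKED_READS, 3)


def chain_graph(n_edges: int, k: int = 15, seed: int = 0):
    """A pure unanimous path of exactly ``n_edges`` 1-step edges, built from
    a repeat-free genome so no molecule repeats."""
    genome = repeat_free_genome(k + n_edges, k, seed)
    g = build_graph([genome], k)
    assert g.n_edges() == n_edges
    return g


def random_read_graph(seed: int, genome_length: int = 400, k: int = 21):
    """A small graph from randomly sampled reads of a random genome; branchy
    enough to exercise selection and chain decomposition."""
    from msgasm.simulate import SimConfig, random_genome, sample_reads

    genome = random_genome(genome_length, seed)
    cfg = SimConfig(
        genome_length=genome_length, k=k, read_length=60, coverage=6.0, seed=seed
    )
    return build_graph(sample_reads(genome, cfg), k)
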