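import pytest

from mitocomp.io import CircularSequence, GeneFeature, MitoGenome
from mitocomp.synthetic_data import GenomeSpec, generate_mitogenome


@pytest.fixture(scope="session")
def default_genome():
    """One synthetic mitogenome plus its planted ground truth."""
    return generate_mitogenome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def genome_batch():
    """A handful of synthetic genomes over distinct seeds."""
    return [generate_mitogenome(GenomeSpec(seed=s)) for s in range(4)]


def make_genome(seq, features, genome_id="toy"):
    return MitoGenome(id=genome_id, seq=CircularSequence(seq),
                      features=list(features))


@pytest.fixture
def toy_genome_factory():
    return make_genome


def gene(name, start, end, kind="PCG", strand="J", wraps=False):
    return GeneFeature(name=name, kind=kind, strand=strand, start=start,
                       end=end, wraps=wraps)


@pytest.fixture
def gene_factory():
    return gene
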