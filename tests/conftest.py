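import io

import pytest

from utrmine import genome_mining as gm
from utrmine import synthetic as syn


@pytest.fixture
def tandem_spec():
    """Five plus-strand genes whose gaps straddle the length-filter bounds."""
    return syn.GenomeSpec(
        n_genes=5,
        gap_lengths=(59, 60, 170, 171),
        strand_pattern=("+",) * 5,
        seed=7,
    )


@pytest.fixture
def tandem_genome(tandem_spec):
    genbank, truth = syn.generate_genome(tandem_spec)
    return genbank, truth


def parse_gbk(genbank_text):
    from Bio import SeqIO

    genes = gm.parse_genome(io.StringIO(genbank_text))
    record = next(SeqIO.parse(io.StringIO(genbank_text), "genbank"))
    return genes, str(record.seq)


@pytest.fixture
def mixed_strand_genome():
    """Genome exercising tandem, divergent and convergent gene contexts."""
    spec = syn.GenomeSpec(
        n_genes=8,
        gap_lengths=(80, 100, 0, 120, 90, 65, 150),
        strand_pattern=("+", "+", "-", "+", "+", "-", "-", "+"),
        seed=11,
    )
    genbank, truth = syn.generate_genome(spec)
    return spec, genbank, truth
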