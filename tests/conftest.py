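import numpy as np
import pytest

from mitorecomb import PipelineConfig
from mitorecomb.mtio import Chromosome, GeneOrder, GenomeSequence


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240331)


def random_dna(n, rng):
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), size=n)) \
        if isinstance(rng, int) else "".join(rng.choice(list("ACGT"), size=n))


def make_order(name, *chrom_specs):
    """chrom_specs: (tokens..., circular_bool) tuples; tokens like 'a', '-b'."""
    chroms = []
    for spec in chrom_specs:
        *tokens, circular = spec
        genes = tuple((t.lstrip("-"), -1 if t.startswith("-") else 1) for t in tokens)
        chroms.append(Chromosome(genes, circular))
    return GeneOrder(name, tuple(chroms))


def circular_order(name, *tokens):
    return make_order(name, (*tokens, True))
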