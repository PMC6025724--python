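import numpy as np
import pandas as pd
import pytest

from intronmeth.features import GeneModel, derive_features
from intronmeth.synth import SynthConfig, SynthCorpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small but fully structured synthetic corpus (in memory)."""
    return SynthCorpus(SynthConfig(n_genes=200, n_chroms=3, seed=7))


@pytest.fixture(scope="session")
def small_matrix(small_corpus):
    return small_corpus.methylation_matrix()


def random_gene(rng: np.random.Generator, gene_id: str = "g") -> GeneModel:
    """A random multi- or single-exon gene for property tests."""
    n_exons = int(rng.integers(1, 7))
    pos = int(rng.integers(2000, 10000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(60, 900))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, "chr1", strand, exons, chrom_length=10**6)
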