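import numpy as np
import pytest

from isotrunc.genemodel import Exon, GenomicInterval, TranscriptModel
from isotrunc.orfscan import translate
from isotrunc.simulate import SimulationConfig, simulate_gene_model


@pytest.fixture
def toy_plus():
    """Two-exon plus-strand transcript: exons (99,200) and (299,400)."""
    return TranscriptModel(
        "toy+", "g1",
        [
            Exon(GenomicInterval("chr1", 99, 200, "+"), 1),
            Exon(GenomicInterval("chr1", 299, 400, "+"), 2),
        ],
    )


@pytest.fixture
def toy_minus():
    """Same intervals on the minus strand; exon 1 has the larger start."""
    return TranscriptModel(
        "toy-", "g1",
        [
            Exon(GenomicInterval("chr1", 299, 400, "-"), 1),
            Exon(GenomicInterval("chr1", 99, 200, "-"), 2),
        ],
    )


@pytest.fixture(scope="session")
def default_gene():
    """The canonical synthetic locus (default configuration)."""
    return simulate_gene_model(SimulationConfig())


@pytest.fixture(scope="session")
def short_protein(default_gene):
    t = default_gene.transcript
    return translate(default_gene.transcript_seq[default_gene.short_start_nt : t.cds_stop])


@pytest.fixture(scope="session")
def canonical_protein(default_gene):
    t = default_gene.transcript
    return translate(default_gene.transcript_seq[t.cds_start : t.cds_stop])


def random_toy_transcript(rng: np.random.Generator) -> TranscriptModel:
    """Random small transcript for coordinate property tests."""
    n = int(rng.integers(1, 6))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, 50))
    ivs = []
    for _ in range(n):
        length = int(rng.integers(1, 40))
        ivs.append(GenomicInterval("chrT", pos, pos + length, strand))
        pos += length + int(rng.integers(1, 30))
    if strand == "-":
        ivs = ivs[::-1]
    return TranscriptModel("t", "g", [Exon(iv, i + 1) for i, iv in enumerate(ivs)])
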