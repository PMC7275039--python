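import numpy as np
import pytest

from hotscan.io import GenomeSequence, MutationCatalog, MutationRecord, RegionSet


@pytest.fixture
def toy_genome():
    # chr1 has an N run and a long homopolymer; chr2 is short
    return GenomeSequence(
        {
            "chr1": "AACGTAACCGGTTNNNNAAAAAACGCGCGTATATACCCCCCCGTACGTAC",
            "chr2": "ACGTACGTACGTACGTACGT",
        }
    )


@pytest.fixture
def toy_catalog(toy_genome):
    recs = [
        MutationRecord("chr1", 4, "G", "A", "S1"),
        MutationRecord("chr1", 5, "T", "C", "S2"),
        MutationRecord("chr1", 30, "T", "G", "S1"),
        MutationRecord("chr2", 10, "G", "T", "S3"),
        MutationRecord("chr2", 11, "T", "TA", "S3"),  # indel
    ]
    return MutationCatalog(recs)


@pytest.fixture
def full_mask(toy_genome):
    return RegionSet(
        [(c, 0, ln) for c, ln in toy_genome.lengths.items()], label="all"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
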