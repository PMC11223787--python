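import pytest

from hgvsmap.fixtures import (
    make_toy_chain,
    make_toy_reference,
    synthetic_clinical_snapshot,
)


@pytest.fixture(scope="session")
def toy():
    """Seeded toy reference: 8 genes, both strands, 1-4 exons."""
    return make_toy_reference(seed=1)


@pytest.fixture(scope="session")
def toy_mane(toy):
    return [t for t in toy.transcripts if t.is_mane]


@pytest.fixture(scope="session")
def snapshot():
    """Synthetic GRCh38-coordinate snapshot anchoring the V600 codon."""
    return synthetic_clinical_snapshot(seed=0)


@pytest.fixture(scope="session")
def toy_chain(toy):
    """Chain fixture with offset, gap and inversion edits plus truth table."""
    return make_toy_chain(
        seed=2,
        assembly=toy.assembly,
        ops=[
            {"kind": "offset", "chrom": "chr1", "amount": 100},
            {"kind": "gap", "chrom": "chr1", "start": 200, "length": 50},
            {"kind": "inversion", "chrom": "chr2", "start": 50, "end": 120},
        ],
    )
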