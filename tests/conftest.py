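import pytest

from mirsite import MatureMiRNA, mir619_5p
from mirsite.energy import DEFAULT_SCHEME
from mirsite.seqcore import TranscriptRecord


@pytest.fixture(scope="session")
def mirna() -> MatureMiRNA:
    return mir619_5p()


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def perfect_site(mirna) -> str:
    return mirna.perfect_site()


def build_transcript(utr5: str, cds: str, utr3: str, **kw) -> TranscriptRecord:
    """Assemble a transcript from explicit region sequences."""
    defaults = dict(transcript_id="T1", gene="G1", species="Hsa")
    defaults.update(kw)
    return TranscriptRecord(
        sequence=utr5 + cds + utr3,
        cds_start=len(utr5) + 1,
        cds_end=len(utr5) + len(cds),
        **defaults,
    )


# Fixed codon choices for reverse translation in tests (one codon per residue).
CODON_OF = {
    "A": "GCA", "C": "UGC", "D": "GAU", "E": "GAA", "F": "UUC", "G": "GGA",
    "H": "CAU", "I": "AUC", "K": "AAA", "L": "CUG", "M": "AUG", "N": "AAU",
    "P": "CCG", "Q": "CAA", "R": "CGU", "S": "AGC", "T": "ACU", "V": "GUC",
    "W": "UGG", "Y": "UAC", "*": "UAA",
}


def reverse_translate(peptide: str) -> str:
    return "".join(CODON_OF[aa] for aa in peptide)
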