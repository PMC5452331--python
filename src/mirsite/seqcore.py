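"""Nucleotide alphabets, translation and transcript I/O.

Coordinates throughout the package are 1-based and inclusive on the mRNA,
read 5'->3'. The canonical internal alphabet is RNA: DNA input is converted
on read, because the miRNA:mRNA duplex is an RNA-level object.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_BASES = frozenset("ACGU")
DNA_BASES = frozenset("ACGT")

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

# Standard genetic code over RNA codons; stops emitted as '*'.
_STANDARD_TABLE = CodonTable.unambiguous_rna_by_name["Standard"]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR)


def normalize(seq: str, target: str = "rna") -> str:
    """Normalize a nucleotide string to one canonical alphabet.

    Uppercases, interconverts T/U according to ``target`` ("rna" or "dna"),
    and collapses every other letter to the ambiguity class 'N'.
    """
    if not seq:
        raise ValueError("empty sequence")
    if target not in ("rna", "dna"):
        raise ValueError(f"unknown target alphabet: {target!r}")
    out = seq.upper()
    if target == "rna":
        out = out.replace("T", "U")
        allowed = RNA_BASES
    else:
        out = out.replace("U", "T")
        allowed = DNA_BASES
    return "".join(c if c in allowed else "N" for c in out)


def reverse_complement(seq: str) -> str:
    """Antiparallel complement of a normalized RNA string, 5'->3'. N maps to N."""
    norm = normalize(seq, "rna")
    return norm.translate(_RNA_COMPLEMENT)[::-1]


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate a normalized RNA string in one codon phasing.

    ``frame_offset`` (0, 1 or 2) skips that many leading nucleotides; a
    trailing partial codon is dropped. Stop codons are emitted as '*' and
    translation continues past them — the presence of an internal stop is
    itself a reportable feature of a reading frame. Any codon containing a
    non-{A,C,G,U} character yields 'X', even when the ambiguity would not
    change the encoded residue.

    Fewer than three usable nucleotides gives the empty peptide.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    body = seq[frame_offset:]
    residues = []
    for i in range(0, len(body) - len(body) % 3, 3):
        codon = body[i : i + 3]
        residues.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(residues)


@dataclasses.dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, written 5'->3' over {A,C,G,U}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize(self.sequence, "rna")
        if set(seq) - RNA_BASES:
            bad = sorted(set(seq) - RNA_BASES)
            raise ValueError(f"miRNA {self.id!r}: ambiguous letters {bad} not allowed")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def perfect_site(self) -> str:
        """The complete complementary binding site (reverse complement)."""
        return reverse_complement(self.sequence)


@dataclasses.dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA with a 1-based inclusive CDS interval.

    The CDS interval partitions the transcript into three regions:
    5UTR = [1, cds_start-1], CDS = [cds_start, cds_end],
    3UTR = [cds_end+1, len]. Leader and trailer may be empty.
    """

    transcript_id: str
    gene: str
    species: str
    sequence: str
    cds_start: int
    cds_end: int
    cds_complete: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize(self.sequence, "rna"))
        n = len(self.sequence)
        if not (1 <= self.cds_start <= self.cds_end <= n):
            raise ValueError(
                f"transcript {self.transcript_id!r}: CDS [{self.cds_start}, "
                f"{self.cds_end}] violates 1 <= start <= end <= {n}"
            )
        if self.cds_complete and (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError(
                f"transcript {self.transcript_id!r}: complete CDS length "
                f"{self.cds_end - self.cds_start + 1} not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        """Region name -> (start, end), 1-based inclusive; empty as (a, a-1)."""
        return {
            REGION_5UTR: (1, self.cds_start - 1),
            REGION_CDS: (self.cds_start, self.cds_end),
            REGION_3UTR: (self.cds_end + 1, len(self.sequence)),
        }

    def region_of(self, pos: int) -> str:
        if not 1 <= pos <= len(self.sequence):
            raise ValueError(f"position {pos} outside [1, {len(self.sequence)}]")
        if pos < self.cds_start:
            return REGION_5UTR
        if pos <= self.cds_end:
            return REGION_CDS
        return REGION_3UTR

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice of the transcript sequence."""
        return self.sequence[start - 1 : end]

    @property
    def cds_sequence(self) -> str:
        return self.subseq(self.cds_start, self.cds_end)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs; sequences normalized to RNA."""
    records = [(r.id, normalize(str(r.seq), "rna")) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_transcript_table(fasta_path: str | Path, table_path: str | Path) -> list[TranscriptRecord]:
    """Join a transcript FASTA with its annotation TSV into TranscriptRecords.

    The TSV has columns id, gene, species, cds_start, cds_end; every row's
    id must resolve to a FASTA record. Records are validated against the
    TranscriptRecord invariants.
    """
    seqs = dict(read_fasta(fasta_path))
    table = pd.read_csv(table_path, sep="\t", dtype={"id": str, "gene": str, "species": str})
    required = {"id", "gene", "species", "cds_start", "cds_end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table {table_path} lacks columns {sorted(missing)}")
    out = []
    for row in table.itertuples(index=False):
        if row.id not in seqs:
            raise ValueError(f"annotation row id {row.id!r} has no FASTA record")
        out.append(
            TranscriptRecord(
                transcript_id=row.id,
                gene=row.gene,
                species=row.species,
                sequence=seqs[row.id],
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return out


def write_transcript_table(path: str | Path, transcripts: Iterable[TranscriptRecord]) -> None:
    frame = pd.DataFrame(
        [
            {
                "id": t.transcript_id,
                "gene": t.gene,
                "species": t.species,
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
            }
            for t in transcripts
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
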