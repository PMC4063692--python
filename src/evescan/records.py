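"""Sequence records and plain-text sequence I/O.

A thin, validated wrapper around strings is used throughout the package so
that DNA and protein sequences cannot be confused silently.  FASTA/FASTQ
round-tripping goes through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

DNA_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence with an explicit alphabet tag.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header token).
    seq : str
        Residues; upper-cased on construction.
    alphabet : {"dna", "protein"}
        Alphabet tag; DNA residues are restricted to ``ACGTN``.
    description : str
        Free-text description carried through I/O.
    """

    id: str
    seq: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        if self.alphabet == "dna":
            bad = set(self.seq) - DNA_CHARS
            if bad:
                raise ValueError(
                    f"record {self.id!r}: non-DNA characters {sorted(bad)}"
                )
        elif self.alphabet != "protein":
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "dna":
            raise ValueError("reverse complement is defined for DNA only")
        return SequenceRecord(
            id=self.id, seq=revcomp(self.seq), alphabet="dna",
            description=self.description,
        )


def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    return [
        SequenceRecord(r.id, str(r.seq), alphabet=alphabet,
                       description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def write_fastq(records, path, quality: int = 40) -> None:
    """Write reads with a constant Phred+33 quality."""
    bio = []
    for r in records:
        b = _BioRecord(Seq(r.seq), id=r.id, description=r.description)
        b.letter_annotations["phred_quality"] = [quality] * len(r.seq)
        bio.append(b)
    SeqIO.write(bio, str(path), "fastq")


def read_fastq(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(r.id, str(r.seq), alphabet="dna",
                       description=r.description)
        for r in SeqIO.parse(str(path), "fastq")
    ]
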