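import numpy as np
import pytest

from Bio.Data.CodonTable import standard_dna_table

from evescan import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_BACKTABLE: dict[str, str] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _BACKTABLE.setdefault(aa, codon)


def back_translate(protein: str) -> str:
    """One deterministic codon per residue (no stops)."""
    return "".join(_BACKTABLE[a] for a in protein)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def dna_record(rng):
    return SequenceRecord("contig", random_dna(rng, 600))
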