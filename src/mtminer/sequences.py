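"""Core sequence containers and nucleotide/protein utilities.

The package works with two molecule types: genomic/coding nucleotide
sequences (alphabet A, C, G, T plus N for ambiguity) and translated
proteins (the 20 standard amino acids plus X for unknown and ``*`` for a
stop).  :class:`SequenceRecord` is the single container both are carried
in; everything downstream (ORF scanning, spliced alignment, distance
computation) consumes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence, nucleotide or protein.

    Parameters
    ----------
    id : str
        Non-empty identifier without whitespace.
    residues : str
        The sequence itself; case-folded to upper on construction.
    moltype : {"nucleotide", "protein"}
        Alphabet the residues are validated against.
    description : str
        Free-text description (FASTA header remainder).
    """

    id: str
    residues: str
    moltype: str = "nucleotide"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.moltype == "nucleotide":
            alphabet = NUCLEOTIDE_ALPHABET
        elif self.moltype == "protein":
            alphabet = PROTEIN_ALPHABET
        else:
            raise ValueError(f"unknown moltype {self.moltype!r}")
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} not in "
                f"{self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Translation stops at the first stop codon; the stop is not included
    in the returned protein.  A length that is not a multiple of three is
    tolerated with a warning: the trailing partial codon is dropped.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3:
        warnings.warn(
            f"CDS length {len(cds)} not divisible by 3; trailing "
            "partial codon ignored",
            stacklevel=2,
        )
        cds = cds[: 3 * (len(cds) // 3)]
    return str(Seq(cds).translate(to_stop=True))


def translate_full(cds: str) -> str:
    """Translate every complete codon, keeping internal stops as ``*``."""
    cds = cds.upper()
    cds = cds[: 3 * (len(cds) // 3)]
    return str(Seq(cds).translate())
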