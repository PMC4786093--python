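"""In-frame coding sequences and the standard bacterial genetic code.

The package works on frame-0 CDS. Sequences are normalised to the DNA
alphabet internally; codons are reported in the RNA alphabet in user-facing
outputs, matching the convention of codon-usage literature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable

_BACTERIAL = CodonTable.unambiguous_dna_by_id[11]

#: DNA codon -> one-letter amino acid (sense codons only).
CODON_TO_AA: dict[str, str] = dict(_BACTERIAL.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_BACTERIAL.stop_codons)

#: amino acid -> tuple of synonymous DNA codons (the codon family).
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

_VALID = re.compile(r"^[ACGT]*$")

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class AlphabetError(ValueError):
    """Sequence contains a character outside the unambiguous nucleotide alphabet."""


class InternalStopError(ValueError):
    """Sequence contains a stop codon before its final position."""


def normalize_nt(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return normalize_nt(codon)


def amino_acid_of(codon: str) -> str:
    """One-letter amino acid of a sense codon (accepts DNA or RNA alphabet)."""
    c = to_dna(codon)
    try:
        return CODON_TO_AA[c]
    except KeyError:
        if c in STOP_CODONS:
            raise ValueError(f"{to_rna(codon)} is a stop codon") from None
        raise ValueError(f"{to_rna(codon)} is not a valid codon") from None


@dataclass(frozen=True)
class CodingSequence:
    """A frame-0 coding sequence with codon-level accessors.

    Validation enforces: unambiguous nucleotides only, length divisible by
    three, and no internal stop codon under the bacterial genetic code.
    A terminal stop codon is permitted but not required.
    """

    id: str
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        norm = normalize_nt(self.seq)
        object.__setattr__(self, "seq", norm)
        if not _VALID.match(norm):
            pos = next(i for i, ch in enumerate(norm) if ch not in "ACGT")
            raise AlphabetError(
                f"{self.id}: ambiguous or invalid nucleotide {norm[pos]!r} at position {pos + 1}"
            )
        if len(norm) % 3 != 0:
            raise FrameError(f"{self.id}: length {len(norm)} is not divisible by 3")
        codons = self.codons
        for i, codon in enumerate(codons[:-1]):
            if codon in STOP_CODONS:
                raise InternalStopError(
                    f"{self.id}: internal stop codon {to_rna(codon)} at codon {i + 1}"
                )

    @property
    def codons(self) -> list[str]:
        """Consecutive non-overlapping triplets (DNA alphabet)."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def translate(self) -> str:
        """Protein sequence; a terminal stop is dropped."""
        prot = "".join(
            CODON_TO_AA.get(c, "*") for c in self.codons
        )
        return prot[:-1] if prot.endswith("*") else prot

    def with_codons(self, codons: list[str], id: str | None = None) -> "CodingSequence":
        return CodingSequence(id=id or self.id, seq="".join(codons))
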