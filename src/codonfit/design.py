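"""Systematic synonymous-codon replacement with a protected 5' prefix.

An allele design replaces, within a chosen region of a parent CDS and
beyond a protected N-terminal prefix, every codon of one or more targeted
amino acids by a fixed synonymous codon.  The protein sequence is preserved
by construction and verified.  N, the number of codons that differ from the
parent, is always reported from the actual codon-level diff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

from .sequences import (
    AA_THREE_TO_ONE,
    CODON_TO_AA,
    STOP_CODONS,
    CodingSequence,
    amino_acid_of,
    to_dna,
    to_rna,
)

DEFAULT_PROTECTED_PREFIX = 40

Region = str | tuple[int, int]


@dataclass(frozen=True)
class Substitution:
    """One codon-level difference (1-based codon index, RNA-alphabet codons)."""

    index: int
    original: str
    new: str


@dataclass(frozen=True)
class DesignSpec:
    """Rules for building a synonymous allele.

    replacements maps amino acid (one- or three-letter) to the target
    synonymous codon.  source_filter optionally restricts replacement to a
    single source codon per amino acid (e.g. only CGU -> CGG).  region is
    "full", "first_half", "second_half" or an explicit 1-based inclusive
    codon interval.  boundary sets the last codon index of the first half;
    None means the midpoint of the editable range.
    """

    replacements: dict[str, str]
    source_filter: dict[str, str] = field(default_factory=dict)
    region: Region = "full"
    protected_prefix: int = DEFAULT_PROTECTED_PREFIX
    boundary: int | None = None

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for aa, codon in self.replacements.items():
            one = AA_THREE_TO_ONE.get(aa.capitalize(), aa.upper())
            if amino_acid_of(codon) != one:
                raise ValueError(f"target codon {codon} does not encode {aa}")
            norm[one] = to_dna(codon)
        object.__setattr__(self, "replacements", norm)
        filt: dict[str, str] = {}
        for aa, codon in self.source_filter.items():
            one = AA_THREE_TO_ONE.get(aa.capitalize(), aa.upper())
            if one not in norm:
                raise ValueError(f"source_filter lists {aa} without a replacement target")
            if amino_acid_of(codon) != one:
                raise ValueError(f"source codon {codon} does not encode {aa}")
            filt[one] = to_dna(codon)
        object.__setattr__(self, "source_filter", filt)
        if self.protected_prefix < 0:
            raise ValueError("protected_prefix must be >= 0")


@dataclass(frozen=True)
class SynonymousAllele:
    """A designed allele with its codon-level substitution record."""

    seq: CodingSequence
    substitutions: tuple[Substitution, ...]

    @property
    def N(self) -> int:
        """Number of codons differing from the parent (from the actual diff)."""
        return len(self.substitutions)


def _editable_range(parent: CodingSequence, prefix: int) -> tuple[int, int]:
    """1-based inclusive codon range beyond the prefix, excluding a final stop."""
    last = parent.n_codons
    if parent.codons[-1] in STOP_CODONS:
        last -= 1
    start = prefix + 1
    if start > last:
        raise ValueError(
            f"{parent.id}: protected prefix {prefix} leaves no editable codons"
        )
    return start, last


def _resolve_region(parent: CodingSequence, spec: DesignSpec) -> tuple[int, int]:
    start, last = _editable_range(parent, spec.protected_prefix)
    if spec.region == "full":
        return start, last
    if spec.region in ("first_half", "second_half"):
        boundary = spec.boundary
        if boundary is None:
            boundary = start + (last - start) // 2
        if not start <= boundary < last:
            raise ValueError(f"boundary {boundary} outside editable range [{start}, {last})")
        return (start, boundary) if spec.region == "first_half" else (boundary + 1, last)
    lo, hi = spec.region
    if lo < 1 or hi > parent.n_codons or lo > hi:
        raise ValueError(f"region ({lo}, {hi}) outside gene of {parent.n_codons} codons")
    return max(lo, start), min(hi, last)


def design_allele(
    parent: CodingSequence, spec: DesignSpec, id: str | None = None
) -> SynonymousAllele:
    """Apply the replacement rules and return the allele with its diff.

    Replacement happens only inside the resolved region and never within the
    protected prefix or at a stop codon; the translated protein is verified
    identical to the parent's.
    """
    lo, hi = _resolve_region(parent, spec)
    codons = parent.codons
    subs: list[Substitution] = []
    for idx in range(lo, hi + 1):
        codon = codons[idx - 1]
        if codon in STOP_CODONS:
            continue
        aa = CODON_TO_AA[codon]
        target = spec.replacements.get(aa)
        if target is None:
            continue
        source = spec.source_filter.get(aa)
        if source is not None and codon != source:
            continue
        if codon != target:
            subs.append(Substitution(idx, to_rna(codon), to_rna(target)))
            codons[idx - 1] = target
    allele = parent.with_codons(codons, id=id or f"{parent.id}_designed")
    if allele.translate() != parent.translate():
        raise AssertionError("designed allele changed the protein sequence")
    return SynonymousAllele(seq=allele, substitutions=tuple(subs))


def split_regions(
    parent: CodingSequence, spec: DesignSpec, boundary: int | None = None
) -> tuple[DesignSpec, DesignSpec]:
    """Split a full-region spec into first-half / second-half specs.

    The two regions partition the editable codon range at ``boundary`` (last
    codon of the first half; defaults to the midpoint), so the designed
    halves always satisfy N_first + N_second = N_full.
    """
    start, last = _editable_range(parent, spec.protected_prefix)
    if last - start < 1:
        raise ValueError("need at least 2 editable codons to split")
    if boundary is None:
        boundary = spec.boundary if spec.boundary is not None else start + (last - start) // 2
    first = dc_replace(spec, region="first_half", boundary=boundary)
    second = dc_replace(spec, region="second_half", boundary=boundary)
    return first, second


def diff_alleles(allele: CodingSequence, parent: CodingSequence) -> list[Substitution]:
    """Codon-level differences of ``allele`` relative to ``parent``.

    ``diff_alleles(design_allele(p, s).seq, p)`` reproduces the recorded
    substitution list exactly.
    """
    if len(allele.seq) != len(parent.seq):
        raise ValueError(
            f"length mismatch: {allele.id} has {len(allele.seq)} nt, "
            f"{parent.id} has {len(parent.seq)} nt"
        )
    return [
        Substitution(i + 1, to_rna(cp), to_rna(ca))
        for i, (ca, cp) in enumerate(zip(allele.codons, parent.codons))
        if ca != cp
    ]
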