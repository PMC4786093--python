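"""Codon counting, relative synonymous codon usage (RSCU) and relative adaptiveness.

RSCU of a codon is its observed count divided by the count expected under
uniform usage within its synonymous family.  Relative adaptiveness is

    wa = RSCU_syn / RSCU_wt

where RSCU_wt belongs to the family's reference (preferred) codon, so the
reference codon has wa = 1 and log(wa) = 0.  log(wa) is reported in base 10.
Counting excludes a configurable N-terminal prefix (default 40 codons) to
reduce the influence of N-terminal codon bias, and stop codons are tallied
separately, outside any family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .sequences import (
    CODON_TO_AA,
    FAMILIES,
    STOP_CODONS,
    CodingSequence,
    to_rna,
)

DEFAULT_EXCLUDE_FIRST = 40


@dataclass
class CodonCountTable:
    """Codon counts aggregated over a gene set, with N-terminal exclusion."""

    counts: dict[str, int]
    stop_counts: dict[str, int]
    excluded_prefix: int

    def family_total(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in FAMILIES[aa])

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if self.excluded_prefix != other.excluded_prefix:
            raise ValueError("cannot merge tables with different excluded prefixes")
        merged = {c: self.counts.get(c, 0) + other.counts.get(c, 0) for c in CODON_TO_AA}
        stops = {
            c: self.stop_counts.get(c, 0) + other.stop_counts.get(c, 0)
            for c in STOP_CODONS
        }
        return CodonCountTable(merged, stops, self.excluded_prefix)


@dataclass
class RelativeAdaptivenessTable:
    """Per-codon RSCU, wa and log10(wa), with one reference codon per family.

    Codons of families that were never observed carry ``math.nan`` for all
    three statistics.
    """

    rscu: dict[str, float]
    wa: dict[str, float] = field(default_factory=dict)
    log_wa: dict[str, float] = field(default_factory=dict)
    reference_codon: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with codons in the RNA alphabet."""
        rows = []
        for aa, codons in sorted(FAMILIES.items()):
            for c in codons:
                rows.append(
                    {
                        "codon": to_rna(c),
                        "amino_acid": aa,
                        "rscu": self.rscu.get(c, math.nan),
                        "wa": self.wa.get(c, math.nan),
                        "log_wa": self.log_wa.get(c, math.nan),
                    }
                )
        return pd.DataFrame(rows)


def count_codons(
    genes: list[CodingSequence], exclude_first: int = DEFAULT_EXCLUDE_FIRST
) -> CodonCountTable:
    """Tally codons of every gene from codon ``exclude_first + 1`` onwards.

    Every gene must extend at least one codon beyond the excluded prefix.
    Stop codons are counted apart and never enter synonymous families.
    """
    if exclude_first < 0:
        raise ValueError("exclude_first must be >= 0")
    counts = {c: 0 for c in CODON_TO_AA}
    stops = {c: 0 for c in STOP_CODONS}
    for gene in genes:
        codons = gene.codons
        if len(codons) < exclude_first + 1:
            raise ValueError(
                f"{gene.id}: only {len(codons)} codons, cannot exclude the first {exclude_first}"
            )
        for codon in codons[exclude_first:]:
            if codon in STOP_CODONS:
                stops[codon] += 1
            else:
                counts[codon] += 1
    return CodonCountTable(counts, stops, exclude_first)


def compute_rscu(table: CodonCountTable) -> RelativeAdaptivenessTable:
    """RSCU per codon: observed count / (family total / family size).

    A family with zero total yields ``nan`` for each member, so that the
    family-sum invariant (sum of RSCU = family size) holds exactly wherever
    it is defined.
    """
    rscu: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        total = sum(table.counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                rscu[c] = math.nan
            continue
        expected = total / len(codons)
        for c in codons:
            rscu[c] = table.counts.get(c, 0) / expected
    return RelativeAdaptivenessTable(rscu=rscu)


def compute_wa(
    table: RelativeAdaptivenessTable,
    reference: dict[str, str] | None = None,
) -> RelativeAdaptivenessTable:
    """Fill in wa = RSCU/RSCU(reference) and log10(wa).

    ``reference`` maps amino acid -> reference codon (DNA or RNA alphabet);
    families not listed default to their maximum-RSCU codon.  A reference
    codon with zero or undefined RSCU is an error.
    """
    reference = {aa: c for aa, c in (reference or {}).items()}
    wa: dict[str, float] = {}
    log_wa: dict[str, float] = {}
    ref_out: dict[str, str] = {}
    for aa, codons in FAMILIES.items():
        values = {c: table.rscu.get(c, math.nan) for c in codons}
        if all(math.isnan(v) for v in values.values()):
            for c in codons:
                wa[c] = math.nan
                log_wa[c] = math.nan
            continue
        if aa in reference:
            ref = reference[aa].upper().replace("U", "T")
            if ref not in values:
                raise ValueError(f"reference codon {reference[aa]} does not encode {aa}")
        else:
            ref = max(values, key=lambda c: values[c])
        ref_rscu = values[ref]
        if not ref_rscu > 0:
            raise ValueError(
                f"reference codon {to_rna(ref)} for {aa} has zero or undefined RSCU"
            )
        ref_out[aa] = ref
        for c in codons:
            w = values[c] / ref_rscu
            wa[c] = w
            log_wa[c] = math.log10(w) if w > 0 else -math.inf
        wa[ref] = 1.0
        log_wa[ref] = 0.0
    return RelativeAdaptivenessTable(
        rscu=dict(table.rscu), wa=wa, log_wa=log_wa, reference_codon=ref_out
    )


def relative_adaptiveness(
    genes: list[CodingSequence],
    exclude_first: int = DEFAULT_EXCLUDE_FIRST,
    reference: dict[str, str] | None = None,
) -> RelativeAdaptivenessTable:
    """Convenience chain: count, RSCU, wa from a reference gene set."""
    return compute_wa(compute_rscu(count_codons(genes, exclude_first)), reference)
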