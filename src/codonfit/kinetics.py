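"""Translation-time differences from tRNA abundance.

The decoding speed of a codon is taken to be proportional to the summed
intracellular concentration of all tRNA species that recognise it (its
decoding pool n, in µM).  The increase in translation time when a wild-type
codon is replaced by a synonymous one is

    delta_t = 1/n_syn - 1/n_wt

reported in µM^-1; only the relative scale is used downstream, so no
conversion to seconds is attempted.  Wobble recognition sets are data, not
code: the bundled table may be overridden per species.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .sequences import to_rna

_DEFAULT_TABLE = "trna_abundance_synthetic.tsv"


@dataclass(frozen=True)
class TRNASpecies:
    trna_id: str
    concentration_uM: float
    codons: frozenset[str]  # RNA alphabet


@dataclass(frozen=True)
class TranslationTimeDelta:
    codon_syn: str
    codon_wt: str
    delta_t: float


class TRNAAbundanceTable:
    """tRNA species with concentrations and wobble-aware recognition sets."""

    def __init__(self, species: list[TRNASpecies]):
        if not species:
            raise ValueError("empty tRNA table")
        for sp in species:
            if not sp.concentration_uM > 0:
                raise ValueError(f"{sp.trna_id}: concentration must be positive")
        self.species = list(species)
        pool: dict[str, float] = {}
        for sp in species:
            for codon in sp.codons:
                pool[codon] = pool.get(codon, 0.0) + sp.concentration_uM
        self._pool = pool

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TRNAAbundanceTable":
        species = [
            TRNASpecies(
                trna_id=str(row.trna_id),
                concentration_uM=float(row.concentration_uM),
                codons=frozenset(
                    to_rna(c.strip()) for c in str(row.codons).split(",") if c.strip()
                ),
            )
            for row in df.itertuples()
        ]
        return cls(species)

    @classmethod
    def from_tsv(cls, path) -> "TRNAAbundanceTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def default(cls) -> "TRNAAbundanceTable":
        """The bundled synthetic stand-in abundance table (see its header)."""
        ref = resources.files("codonfit.data").joinpath(_DEFAULT_TABLE)
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def codon_pool(self, codon: str) -> float:
        """Summed concentration (µM) of every species recognising ``codon``."""
        key = to_rna(codon)
        try:
            return self._pool[key]
        except KeyError:
            raise KeyError(f"no tRNA species recognises codon {key}") from None

    def delta_t_trans(self, codon_syn: str, codon_wt: str) -> TranslationTimeDelta:
        """Increase in translation time for codon_syn relative to codon_wt."""
        n_syn = self.codon_pool(codon_syn)
        n_wt = self.codon_pool(codon_wt)
        return TranslationTimeDelta(
            codon_syn=to_rna(codon_syn),
            codon_wt=to_rna(codon_wt),
            delta_t=1.0 / n_syn - 1.0 / n_wt,
        )


def codon_pool(table: TRNAAbundanceTable, codon: str) -> float:
    return table.codon_pool(codon)


def delta_t_trans(
    table: TRNAAbundanceTable, codon_syn: str, codon_wt: str
) -> TranslationTimeDelta:
    return table.delta_t_trans(codon_syn, codon_wt)
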