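"""Anti-Shine-Dalgarno hexamer scanning and folding free-energy ingestion.

Internal Shine-Dalgarno-like motifs can pair with the 3' tail of 16S rRNA
(the anti-SD sequence) and stall elongating ribosomes.  The scanner slides
a 6-nt window over a CDS at every offset (all three frames) and counts
windows whose precomputed duplex energy against the anti-SD falls strictly
below each threshold (typically -4 and -6 kcal/mol).

mRNA folding free-energy differences (ddG of an allele vs wild type) are an
external prediction; they are consumed from a table, never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .sequences import CodingSequence, to_rna

logger = logging.getLogger(__name__)

DEFAULT_ANTI_SD = "CACCUCCUUA"
DEFAULT_THRESHOLDS = (-4.0, -6.0)
_DEFAULT_ENERGIES = "hexamer_antisd_energies.tsv"


@dataclass
class HexamerAffinityModel:
    """anti-SD sequence plus a hexamer -> duplex ΔG (kcal/mol) lookup.

    The bundled default covers all 4^6 RNA hexamers, scored once with an
    RNA-RNA duplex minimum-free-energy calculation against the default
    anti-SD tail and frozen as package data.
    """

    anti_sd: str = DEFAULT_ANTI_SD
    energy: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "HexamerAffinityModel":
        ref = resources.files("codonfit.data").joinpath(_DEFAULT_ENERGIES)
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#")
        return cls(energy=dict(zip(df["hexamer"], df["energy_kcal_mol"].astype(float))))

    def lookup(self, hexamer: str) -> float:
        key = to_rna(hexamer)
        try:
            return self.energy[key]
        except KeyError:
            raise KeyError(f"hexamer {key} absent from the affinity model") from None


@dataclass
class AntiSDScanResult:
    counts: dict[float, int]
    positions: list[tuple[int, str, float]]  # (0-based offset, hexamer, ΔG)


@dataclass
class FreeEnergyRecord:
    allele: str
    ddg: float


def scan_anti_sd(
    seq: CodingSequence | str,
    model: HexamerAffinityModel,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> AntiSDScanResult:
    """Count 6-nt windows with anti-SD duplex energy strictly below each threshold."""
    nt = seq.seq if isinstance(seq, CodingSequence) else seq
    if len(nt) < 6:
        raise ValueError("sequence shorter than one hexamer window")
    rna = to_rna(nt)
    counts = {t: 0 for t in thresholds}
    positions: list[tuple[int, str, float]] = []
    for off in range(len(rna) - 5):
        hexamer = rna[off : off + 6]
        dg = model.lookup(hexamer)
        hit = False
        for t in thresholds:
            if dg < t:
                counts[t] += 1
                hit = True
        if hit:
            positions.append((off, hexamer, dg))
    return AntiSDScanResult(counts=counts, positions=positions)


def load_ddg(source) -> list[FreeEnergyRecord]:
    """Read allele -> ddG records from a TSV path or DataFrame.

    Signed values are accepted as supplied (published tables occasionally
    print negative "absolute" changes).  Rows without an allele id are
    dropped with a warning; duplicate ids resolve last-wins with a warning.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    records: dict[str, FreeEnergyRecord] = {}
    for i, row in df.iterrows():
        allele = row.get("allele")
        if allele is None or (isinstance(allele, float) and pd.isna(allele)) or str(allele) == "":
            logger.warning("ddG row %d has no allele id; skipped", i)
            continue
        allele = str(allele)
        if allele in records:
            logger.warning("duplicate ddG record for %s; keeping the last", allele)
        records[allele] = FreeEnergyRecord(allele=allele, ddg=float(row["ddg"]))
    return list(records.values())
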