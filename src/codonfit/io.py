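"""FASTA and TSV plumbing shared by the pipeline stages.

All tabular interchange is tab-separated with a header row and '.' decimal
separator; writers keep a stable column order and readers reject malformed
rows naming the row number.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import CodingSequence

logger = logging.getLogger(__name__)


def read_fasta(path) -> list[CodingSequence]:
    """Read a multi-FASTA of CDS into validated coding sequences.

    Sequences are uppercased and U is normalised to T (flagged in the log);
    an empty file or duplicate record ids are errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or unparseable FASTA")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if raw != raw.upper() or "U" in raw.upper():
            logger.info("%s: normalising case/alphabet of %s", path.name, rec.id)
        out.append(CodingSequence(id=rec.id, seq=raw))
    return out


def write_fasta(sequences: list[CodingSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: malformed value in column {col!r}, row {bad[0] + 2}")
    return df


def write_tsv(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    if columns is not None:
        df = df[columns]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
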