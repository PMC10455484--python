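"""Reading and writing the pipeline's external formats.

Amino-acid FASTA goes through Bio.SeqIO; tab-separated tables through pandas.
Sequences are normalised on input: uppercased, terminal stop codons ('*')
stripped, and restricted to the 20 canonical residues plus X.  Ambiguity codes
other than X are rejected because motif scanning is defined only on that
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathType = Union[str, PathLike]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_AA = CANONICAL_AA | {"X"}

LIFESTYLES = ("SAP", "ECM")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty sequence, bad residue, dup id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence tagged with the species it came from."""

    id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALLOWED_AA
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: non-canonical residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpeciesMeta:
    """Species key, human-readable name and lifestyle label (SAP or ECM)."""

    species_id: str
    display_name: str
    lifestyle: str

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(
                f"lifestyle must be one of {LIFESTYLES}, got {self.lifestyle!r}")


def _normalise(seq: str, record_id: str) -> str:
    seq = seq.upper()
    while seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise FastaParseError(f"record {record_id!r}: empty sequence")
    return seq


def read_fasta(path: PathType, species_id: str = "") -> list[ProteinRecord]:
    """Parse a multi-record amino-acid FASTA file.

    Sequences are uppercased and terminal '*' stop symbols removed.  Duplicate
    ids or residues outside the canonical alphabet (plus X) raise
    :class:`FastaParseError` naming the offending record.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(
            id=rec.id,
            species_id=species_id,
            sequence=_normalise(str(rec.seq), rec.id),
        ))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathType) -> None:
    """Write records to FASTA (60-column wrap, id-only headers)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_species_table(path: PathType) -> list[SpeciesMeta]:
    """Read a species metadata TSV: species_id, display_name, lifestyle."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "display_name", "lifestyle"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    return [
        SpeciesMeta(row.species_id, row.display_name, row.lifestyle)
        for row in df.itertuples()
    ]


def write_tsv(df: pd.DataFrame, path: PathType, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
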