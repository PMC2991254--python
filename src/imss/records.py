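"""Protein records and FASTA input/output.

Sequences are plain uppercase amino-acid strings over the 20 standard
residues plus ``X`` for ambiguity.  All residue coordinates used anywhere in
this package are 1-based and inclusive, matching the mutation notation used
for the family screens this package analyses (``S61R`` mutates residue 61).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One family member: identifier, species tag and amino-acid sequence."""

    id: str
    sequence: str
    species: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid protein id {self.id!r}")
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"protein {self.id}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique(records: list[ProteinRecord]) -> list[ProteinRecord]:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
    return records


def read_fasta(path: str | Path | io.TextIOBase) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The first whitespace-separated token of the header is the id; an optional
    ``species=<tag>`` key in the remainder of the header sets the species.
    Sequences are uppercased.  Duplicate ids and illegal residues are errors.
    """
    records = []
    for entry in SeqIO.parse(path, "fasta"):
        species = "unspecified"
        for token in entry.description.split()[1:]:
            if token.startswith("species="):
                species = token[len("species="):]
        records.append(
            ProteinRecord(id=entry.id, sequence=str(entry.seq).upper(), species=species)
        )
    return _check_unique(records)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, 60 columns per sequence line."""
    seq_records = []
    for rec in records:
        description = "" if rec.species == "unspecified" else f"species={rec.species}"
        seq_records.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=description))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)


def records_by_id(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {rec.id: rec for rec in _check_unique(list(records))}
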