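"""Mutation notation: parsing and in-silico application.

The notation is the one used to name site-directed mutants of family
members: ``S61R`` substitutes the serine at residue 61 by arginine;
``SIPK62-65MQD`` replaces the four residues 62-65 (which must read SIPK) by
MQD, shortening the protein by one.  Coordinates are 1-based inclusive.
Double mutants are written with ``/`` (``V66I/N150Y``) and applied
right-to-left so earlier coordinates stay valid under length changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .records import VALID_RESIDUES, ProteinRecord

_MUTATION_RE = re.compile(r"^([A-Z]+)(\d+)(?:-(\d+))?([A-Z]+)$")


@dataclass(frozen=True)
class MutationSpec:
    """A replacement of residues [start, end] (1-based inclusive)."""

    original: str
    start: int
    end: int
    replacement: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.original):
            raise ValueError(
                f"range {self.start}-{self.end} does not span "
                f"{len(self.original)} residues ({self.original!r})"
            )
        if self.start < 1:
            raise ValueError("coordinates are 1-based")
        for s in (self.original, self.replacement):
            bad = set(s) - VALID_RESIDUES
            if bad:
                raise ValueError(f"invalid residues {sorted(bad)} in {s!r}")

    @property
    def is_deletion(self) -> bool:
        return self.replacement == ""

    @property
    def length_change(self) -> int:
        return len(self.replacement) - len(self.original)

    @property
    def text(self) -> str:
        if self.start == self.end:
            return f"{self.original}{self.start}{self.replacement}"
        return f"{self.original}{self.start}-{self.end}{self.replacement}"


def parse_mutation(text: str) -> MutationSpec:
    """Parse ``<orig><pos><new>`` or ``<orig><start>-<end><new>``."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparsable mutation string {text!r}")
    original, start_s, end_s, replacement = m.groups()
    start = int(start_s)
    end = int(end_s) if end_s is not None else start + len(original) - 1
    return MutationSpec(original=original, start=start, end=end, replacement=replacement)


def parse_mutations(text: str) -> list[MutationSpec]:
    """Parse a '/'-separated multi-site mutation string."""
    return [parse_mutation(part) for part in text.split("/")]


def apply_mutation(record: ProteinRecord, spec: MutationSpec) -> ProteinRecord:
    """Apply one mutation, returning a new record with a suffixed id.

    The residues currently at [start, end] must equal ``spec.original``;
    a mismatch is reported explicitly to guard against off-by-one
    coordinate conventions.
    """
    seq = record.sequence
    if spec.end > len(seq):
        raise ValueError(
            f"{record.id}: mutation {spec.text} past sequence end ({len(seq)})"
        )
    found = seq[spec.start - 1 : spec.end]
    if found != spec.original:
        raise ValueError(
            f"{record.id}: expected {spec.original!r} at {spec.start}-{spec.end}, "
            f"found {found!r}"
        )
    mutated = seq[: spec.start - 1] + spec.replacement + seq[spec.end :]
    return ProteinRecord(
        id=f"{record.id}_{spec.text}", sequence=mutated, species=record.species
    )


def apply_mutations(record: ProteinRecord, specs: list[MutationSpec]) -> ProteinRecord:
    """Apply multiple mutations; sites are applied from the C-terminus first."""
    text = "/".join(s.text for s in specs)
    mutated = record
    for spec in sorted(specs, key=lambda s: -s.start):
        mutated = ProteinRecord(record.id, mutated.sequence, record.species)
        mutated = apply_mutation(mutated, spec)
    return ProteinRecord(
        id=f"{record.id}_{text}", sequence=mutated.sequence, species=record.species
    )
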