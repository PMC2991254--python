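"""Labeled protein-protein interaction data.

An :class:`InteractionDataset` holds unordered protein pairs labeled
``interacting`` / ``non_interacting`` / ``unknown``, mirroring a matrix-based
yeast two-hybrid screen.  Pairs are canonicalized as ``(min(id), max(id))``
so (A, B) and (B, A) are one pair; homodimers (A, A) are allowed.  Unknown
labels are retained but excluded from training and scoring unless explicitly
requested.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator


class Label(Enum):
    INTERACTING = "interacting"
    NON_INTERACTING = "non_interacting"
    UNKNOWN = "unknown"


_TSV_CODE = {Label.INTERACTING: "1", Label.NON_INTERACTING: "0", Label.UNKNOWN: "?"}
_CODE_TSV = {v: k for k, v in _TSV_CODE.items()}

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Order-insensitive pair key: lexicographically sorted ids."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionDataset:
    """Registered proteins plus labeled unordered pairs."""

    proteins: list[str]
    pairs: dict[Pair, Label] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein ids")
        known = set(self.proteins)
        for (a, b) in self.pairs:
            if a not in known or b not in known:
                raise ValueError(f"pair ({a},{b}) references unregistered protein")

    def add_pair(self, a: str, b: str, label: Label) -> None:
        known = set(self.proteins)
        if a not in known or b not in known:
            raise ValueError(f"pair ({a},{b}) references unregistered protein")
        key = canonical_pair(a, b)
        existing = self.pairs.get(key)
        if existing is not None and existing is not label:
            raise ValueError(
                f"conflicting label for pair ({key[0]},{key[1]}): "
                f"{existing.value} vs {label.value}"
            )
        self.pairs[key] = label

    def label_of(self, a: str, b: str) -> Label:
        return self.pairs.get(canonical_pair(a, b), Label.UNKNOWN)

    def count(self, label: Label) -> int:
        return sum(1 for v in self.pairs.values() if v is label)

    @property
    def n_interacting(self) -> int:
        return self.count(Label.INTERACTING)

    @property
    def n_non_interacting(self) -> int:
        return self.count(Label.NON_INTERACTING)

    @property
    def n_unknown(self) -> int:
        return self.count(Label.UNKNOWN)

    def labeled_pairs(self) -> Iterator[tuple[Pair, Label]]:
        """Pairs with a definite label, in deterministic sorted order."""
        for key in sorted(self.pairs):
            label = self.pairs[key]
            if label is not Label.UNKNOWN:
                yield key, label

    def pairs_with(self, label: Label) -> list[Pair]:
        return [k for k in sorted(self.pairs) if self.pairs[k] is label]

    def partners_of(self, pid: str) -> list[str]:
        """Interacting partners of ``pid`` (includes ``pid`` for homodimers)."""
        out = []
        for (a, b), lab in self.pairs.items():
            if lab is Label.INTERACTING and pid in (a, b):
                out.append(b if a == pid else a)
        return sorted(out)

    def copy(self) -> "InteractionDataset":
        return InteractionDataset(list(self.proteins), dict(self.pairs))


def read_interactions(path: str | Path, proteins: Iterable[str]) -> InteractionDataset:
    """Read a pair-label TSV (columns protein_a, protein_b, label in {1,0,?}).

    Rows are de-duplicated regardless of order; conflicting duplicate labels
    and references to unregistered proteins are errors.
    """
    data = InteractionDataset(list(proteins))
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"protein_a", "protein_b", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"interaction TSV must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            code = (row["label"] or "").strip()
            if code not in _CODE_TSV:
                raise ValueError(f"line {lineno}: malformed label {code!r}")
            data.add_pair(row["protein_a"].strip(), row["protein_b"].strip(), _CODE_TSV[code])
    return data


def write_interactions(data: InteractionDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_a", "protein_b", "label"])
        for (a, b) in sorted(data.pairs):
            writer.writerow([a, b, _TSV_CODE[data.pairs[(a, b)]]])
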