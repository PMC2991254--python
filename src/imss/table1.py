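"""Packaged mutant interaction-matrix fixture.

The published matrix yeast two-hybrid screen of seven wild-type MADS
domain proteins and fifteen site-directed mutants against 32 family
members, encoded verbatim as Y/N rows.  Combinations not listed in the
matrix are non-interacting by the table's own convention (applied here to
wild-type combinations; mutants were screened only against the listed
columns).

The printed loss/gain columns are also packaged.  Recomputing deltas from
the Y/N cells reproduces the printed numbers for 14 of the 15 mutants; for
the CAL N150Y row the cells give 18 gains where the printed column says 16
(a documented discrepancy of the source table, kept as printed here and
pinned as recomputed in the tests).
"""

from __future__ import annotations

from .interactions import InteractionDataset, Label, canonical_pair
from .predict import InteractionDelta, interaction_delta

PARTNERS = [
    "AG", "SEP1", "SEP2", "SEP3", "SEP4i", "SEP4ii", "SHP1", "SHP2",
    "AGL6", "AP1", "FUL", "CAL", "STK", "XAL1", "AGL13", "AGL14",
    "AGL15", "AGL16", "AGL17", "AGL19", "SOC1", "AGL21", "SVP1", "SVP2",
    "AGL24", "FLC", "MAF2", "ABSI", "ABSIi", "AGL42", "ANR1", "AGL71",
]

WILDTYPES = ["SVP1", "AGL24", "AGL14", "SOC1", "AP1", "CAL", "AG"]

# (wild type, mutation string) in table order
MUTANTS = [
    ("SVP1", "C58S"),
    ("SVP1", "S61R"),
    ("SVP1", "C58S/S61R"),
    ("SVP1", "EFCSSS56-61D"),
    ("SVP1", "SS227-228MF"),
    ("AGL24", "R61S"),
    ("AGL14", "SIPK62-65MQD"),
    ("SOC1", "MQD62-64SIPK"),
    ("AP1", "I66V"),
    ("AP1", "Y148N"),
    ("AP1", "I66V/Y148N"),
    ("CAL", "V66I"),
    ("CAL", "N150Y"),
    ("CAL", "V66I/N150Y"),
    ("AG", "Q126H"),
]

ROWS = {
    "SVP1":              "YYYYYYYYYYYNNNNYNYYYYYYYNYNNNYYN",
    "SVP1 C58S":         "YYYYNYYYNYYNNNNYNYYNYYNYNYNNNYNN",
    "SVP1 S61R":         "YYYYNNNNNYNNNNNNNNNNYYNNNNNNNNNN",
    "SVP1 C58S/S61R":    "NNNYNNNNNNNNNNNNNYNYYYNNNNNNNNNN",
    "SVP1 EFCSSS56-61D": "NNNNNNNNNNNNNNNNNNNNYYNNNNNNNNNN",
    "SVP1 SS227-228MF":  "YYYYYYYYNYYYNNYYNYYNYYNYNYYNNYYN",
    "AGL24":             "YYNYNNYNYYYNNNNYYYNNYYNNYNNNNNNN",
    "AGL24 R61S":        "YYYYNYYYNYYNYNNYNYNNYYNNYNYNNYNN",
    "AGL14":             "NNNNNNNNNNYNNNNNNYNNYNYYYNNNNNNN",
    "AGL14 SIPK62-65MQD": "NNYYNNNYNYYNNYYNNYNNYNYYYNNNNNYN",
    "SOC1":              "NYYYYYYYYYYYNYYYYYYYYYYYYNNNNYYY",
    "SOC1 MQD62-64SIPK": "NYNYNNNNNNNNNNNNNNNNYYYNYNNNNNNN",
    "AP1":               "NYNYNYNNYNNNNNNNYYNNYYYYYNNNNNNN",
    "AP1 I66V":          "NYYYNNNNNNNNNNNNNYNNYNNNNNNNNNNN",
    "AP1 Y148N":         "NYYYNNNNNYYNNNYNNYNNYNYYYNNNNNNN",
    "AP1 I66V/Y148N":    "NNNNNYNNNNNNNNNNNNNNNNNNNNNNNNNN",
    "CAL":               "NNNNNNNNNNNNNNNNNNNNYNNNNNNNNNNN",
    "CAL V66I":          "NYYYNNNYNYYNNYYNNYNNYNYYYNNNNNNN",
    "CAL N150Y":         "YYYYNYYYNYYNNNYYNYYYYNYYYNNNNYNN",
    "CAL V66I/N150Y":    "NNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNN",
    "AG":                "NYYYNNNNNNYNNNYNYYNNNYYYYNNNNNNN",
    "AG Q126H":          "NYYYNNNNNNNNNNNNNYNNNNNNNNNNNNNN",
}

# loss/gain columns as printed in the source table
PRINTED_DELTAS = {
    "SVP1 C58S": (5, 0),
    "SVP1 S61R": (15, 0),
    "SVP1 C58S/S61R": (17, 0),
    "SVP1 EFCSSS56-61D": (20, 0),
    "SVP1 SS227-228MF": (3, 3),
    "AGL24 R61S": (2, 6),
    "AGL14 SIPK62-65MQD": (0, 7),
    "SOC1 MQD62-64SIPK": (20, 0),
    "AP1 I66V": (7, 1),
    "AP1 Y148N": (4, 4),
    "AP1 I66V/Y148N": (10, 0),
    "CAL V66I": (0, 12),
    "CAL N150Y": (0, 16),  # recomputes to 18 from the Y/N cells
    "CAL V66I/N150Y": (1, 0),
    "AG Q126H": (7, 0),
}


def mutant_name(wildtype: str, mutation: str) -> str:
    return f"{wildtype} {mutation}"


def row_labels(name: str) -> list[bool]:
    """Y/N cells of one bait row as booleans over PARTNERS."""
    row = ROWS[name]
    if len(row) != len(PARTNERS):
        raise AssertionError(f"row {name} has {len(row)} cells")
    return [c == "Y" for c in row]


def table1_fixture() -> tuple[InteractionDataset, list[str]]:
    """The matrix as an :class:`InteractionDataset`, plus mutant names.

    Proteins are the 32 partners and the 15 mutants; every listed bait x
    prey cell contributes its printed label, and unlisted wild-type
    combinations are filled in as non-interacting per the table's
    convention.  Mutant-mutant combinations (never screened) are left
    unknown.
    """
    mutant_ids = [mutant_name(w, m) for w, m in MUTANTS]
    proteins = PARTNERS + mutant_ids
    data = InteractionDataset(list(proteins))
    for name, row in ROWS.items():
        for partner, cell in zip(PARTNERS, row):
            data.add_pair(
                name, partner,
                Label.INTERACTING if cell == "Y" else Label.NON_INTERACTING,
            )
    for i, a in enumerate(PARTNERS):
        for b in PARTNERS[i:]:
            if canonical_pair(a, b) not in data.pairs:
                data.add_pair(a, b, Label.NON_INTERACTING)
    return data, mutant_ids


def table1_delta(wildtype: str, mutation: str) -> InteractionDelta:
    """Loss/gain of a mutant versus its wild type, recomputed from cells."""
    name = mutant_name(wildtype, mutation)
    return interaction_delta(
        row_labels(wildtype),
        row_labels(name),
        PARTNERS,
        reference_id=wildtype,
        variant_id=name,
    )
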