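"""Acidic-wall census over an alignment of PHD-finger reader domains.

A subclass of PHD fingers binds the histone H3 N-terminal tail in a helical
folded-back conformation.  Its sequence signature is an Asp/Glu residue
("acidic wall") on the short helical turn preceding the first beta-strand
— the position of E1689 in BAZ2A — often reinforced by a second,
sequence-adjacent acidic residue (a "double acidic patch", e.g. BAZ2A
D1688/E1689).  The acidic wall tends to be mutually exclusive with the
conserved tryptophan of the aromatic cage that reads methylated K4.

Given a multiple sequence alignment (computed elsewhere) and two anchor
positions — the wall column and the Trp column, each located via a
reference row with known construct numbering — this module flags every row
and tabulates the mutual-exclusivity census.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import AlignIO

ACIDIC = {"D", "E"}
VALID_SYMBOLS = set("ACDEFGHIKLMNPQRSTVWY-X")


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]  # aligned, upper-case, '-' gaps

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for rid, row in zip(self.ids, self.rows):
            for col, ch in enumerate(row, start=1):
                if ch not in VALID_SYMBOLS:
                    raise ValueError(
                        f"illegal symbol {ch!r} in row {rid!r} column {col}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"no row with id {rid!r}") from None


@dataclass
class ReferenceAnchor:
    """Locates an alignment column via a residue number in a reference row."""

    row_id: str
    first_residue_number: int  # number of the reference construct's first residue
    target_residue_number: int  # e.g. 1689 for the BAZ2A acidic wall


@dataclass
class PhdClassification:
    row_id: str
    has_acidic_wall: bool
    has_trp: bool
    has_double_patch: bool

    @property
    def category(self) -> str:
        if self.has_acidic_wall and self.has_trp:
            return "both"
        if self.has_acidic_wall:
            return "wall-only"
        if self.has_trp:
            return "trp-only"
        return "neither"


@dataclass
class CensusSummary:
    n_total: int
    n_acidic_wall: int
    n_trp: int
    n_both: int
    n_double_patch: int
    contingency: pd.DataFrame | None = None  # 2x2 wall x trp


def read_alignment(path: str | Path, fmt: str | None = None) -> Msa:
    """Read an aligned FASTA or Clustal file into a validated Msa.

    Lower-case letters are upper-cased and '.' gaps normalized to '-'.
    Format is sniffed from the first line when not given.
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:30].upper()
        fmt = "clustal" if head.startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    return Msa(ids, rows)


def map_reference_position(msa: Msa, anchor: ReferenceAnchor) -> int:
    """1-based alignment column holding the anchor's target residue.

    Walks the reference row's ungapped sequence with construct numbering
    starting at ``first_residue_number``.
    """
    row = msa.row(anchor.row_id)
    if row.count("-") == len(row):
        raise ValueError(f"reference row {anchor.row_id!r} is gap-only")
    number = anchor.first_residue_number
    for col, ch in enumerate(row, start=1):
        if ch == "-":
            continue
        if number == anchor.target_residue_number:
            return col
        number += 1
    raise ValueError(
        f"residue {anchor.target_residue_number} outside reference row "
        f"{anchor.row_id!r} (numbered {anchor.first_residue_number}..{number - 1})"
    )


def column_residue(msa: Msa, row_id: str, col: int) -> str:
    return msa.row(row_id)[col - 1]


def detect_double_patch(sequence: str, wall_position: int, window: int = 1) -> bool:
    """At least two adjacent acidic residues at the wall (ungapped numbering).

    True iff the residue at 1-based ``wall_position`` is D/E and any
    neighbour within ``window`` positions is also D/E.
    """
    if not 1 <= wall_position <= len(sequence):
        raise ValueError("wall position outside sequence")
    if sequence[wall_position - 1] not in ACIDIC:
        return False
    for off in range(1, window + 1):
        for pos in (wall_position - off, wall_position + off):
            if 1 <= pos <= len(sequence) and sequence[pos - 1] in ACIDIC:
                return True
    return False


def classify_rows(msa: Msa, wall_col: int, trp_col: int,
                  patch_window: int = 1) -> list[PhdClassification]:
    """Flag every row for acidic wall, K4me Trp, and double acidic patch.

    A gap at a diagnostic column scores as absent.  The double patch is
    evaluated on the ungapped sequence around the wall residue.
    """
    if wall_col == trp_col:
        raise ValueError("wall and Trp columns must differ")
    for col in (wall_col, trp_col):
        if not 1 <= col <= msa.length:
            raise ValueError(f"column {col} outside alignment of length {msa.length}")
    out = []
    for rid, row in zip(msa.ids, msa.rows):
        wall_res = row[wall_col - 1]
        has_wall = wall_res in ACIDIC
        has_trp = row[trp_col - 1] == "W"
        has_patch = False
        if has_wall:
            ungapped = row.replace("-", "")
            wall_pos = wall_col - row[:wall_col].count("-")
            has_patch = detect_double_patch(ungapped, wall_pos, window=patch_window)
        out.append(PhdClassification(rid, has_wall, has_trp, has_patch))
    return out


def census_summary(classifications: list[PhdClassification]) -> CensusSummary:
    """Counts plus the 2x2 wall-by-Trp mutual-exclusivity table."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    n_wall = sum(c.has_acidic_wall for c in classifications)
    n_trp = sum(c.has_trp for c in classifications)
    n_both = sum(c.has_acidic_wall and c.has_trp for c in classifications)
    n_patch = sum(c.has_double_patch for c in classifications)
    n = len(classifications)
    contingency = pd.DataFrame(
        [[n_both, n_wall - n_both], [n_trp - n_both, n - n_wall - n_trp + n_both]],
        index=pd.Index(["wall", "no wall"], name=""),
        columns=["trp", "no trp"],
    )
    return CensusSummary(n, n_wall, n_trp, n_both, n_patch, contingency)


def classifications_frame(classifications: list[PhdClassification]) -> pd.DataFrame:
    return pd.DataFrame([
        {"id": c.row_id, "has_acidic_wall": c.has_acidic_wall,
         "has_trp": c.has_trp, "has_double_patch": c.has_double_patch,
         "category": c.category}
        for c in classifications
    ])
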