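"""Core sequence, alignment and taxonomy record types.

Residue coordinates are 1-based inclusive everywhere in this package,
matching the author-style numbering used for crystal structures
(e.g. "residues 250 to 260").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: canonical residues plus the ambiguity code X
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence with a unique accession-like id."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be nonempty")
        if not self.residues:
            raise ValueError(f"SequenceRecord {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"SequenceRecord {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int, new_id: Optional[str] = None) -> "SequenceRecord":
        """Residues ``start..end`` (1-based inclusive) as a new record."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(f"interval [{start},{end}] outside 1..{len(self.residues)}")
        return SequenceRecord(new_id or f"{self.id}/{start}-{end}",
                              self.residues[start - 1:end], self.description)


@dataclass
class AlignmentBlock:
    """A multiple alignment: equal-width rows that may contain ``-`` gaps."""

    rows: list  # list[tuple[str, str]] of (id, gapped residues)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        widths = {len(r[1]) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment: row widths {sorted(widths)}")
        ids = [r[0] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate row ids in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list:
        return [r[0] for r in self.rows]

    def row(self, rid: str) -> str:
        for i, s in self.rows:
            if i == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> SequenceRecord:
        return SequenceRecord(rid, self.row(rid).replace(GAP, ""))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class TaxonRecord:
    """Per-proteome metadata used for quality filtering and the
    photosynthesis classifier (GO:0015979 protein counts)."""

    organism: str
    genus: str
    superkingdom: str
    go_photosynthesis_count: int
    proteome_flags: frozenset = field(default_factory=frozenset)
    busco_completeness: Optional[float] = None  # percent, None = missing

    VALID_SUPERKINGDOMS = frozenset({"Archaea", "Bacteria", "Eukaryota"})
    VALID_FLAGS = frozenset({"reference", "nonredundant"})

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError("genus must be nonempty")
        if self.superkingdom not in self.VALID_SUPERKINGDOMS:
            raise ValueError(f"unknown superkingdom {self.superkingdom!r}")
        if self.go_photosynthesis_count < 0:
            raise ValueError("GO count must be >= 0")
        object.__setattr__(self, "proteome_flags", frozenset(self.proteome_flags))
        bad = self.proteome_flags - self.VALID_FLAGS
        if bad:
            raise ValueError(f"unknown proteome flags {sorted(bad)}")
        if self.busco_completeness is not None and not (0 <= self.busco_completeness <= 100):
            raise ValueError("BUSCO completeness must lie in [0,100]")


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate id {r.id!r}")
        seen.add(r.id)
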