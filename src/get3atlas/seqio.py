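"""FASTA / aligned-FASTA and taxonomy-TSV readers and writers.

FASTA parsing and writing go through Biopython; this module enforces the
package-level contracts on top (unique ids, upper-casing, ``*`` terminator
stripping, ``.`` gaps normalised to ``-``).
"""
from __future__ import annotations

import io
import os
from typing import List, Union

import pandas as pd
from Bio import SeqIO

from .records import GAP, AlignmentBlock, SequenceRecord, TaxonRecord

PathOrText = Union[str, os.PathLike]


def _as_handle(path_or_text: PathOrText):
    s = os.fspath(path_or_text) if isinstance(path_or_text, os.PathLike) else path_or_text
    if isinstance(s, str) and (not s or "\n" in s or s.lstrip().startswith(">")):
        return io.StringIO(s)
    return open(s)


def read_fasta(path_or_text: PathOrText) -> List[SequenceRecord]:
    """Read FASTA from a path or literal text into SequenceRecords.

    Order is preserved; residues are upper-cased and trailing ``*``
    terminators stripped. Raises on empty input or duplicate ids.
    """
    records = []
    seen = set()
    with _as_handle(path_or_text) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id!r}")
            seen.add(rec.id)
            residues = str(rec.seq).upper().rstrip("*")
            desc = rec.description[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise ValueError("no records in FASTA input")
    return records


def write_fasta(records, width: int = 60) -> str:
    out = []
    for r in records:
        header = f">{r.id} {r.description}".rstrip() if isinstance(r, SequenceRecord) else f">{r[0]}"
        seq = r.residues if isinstance(r, SequenceRecord) else r[1]
        out.append(header)
        for i in range(0, len(seq), width):
            out.append(seq[i:i + width])
    return "\n".join(out) + "\n"


def read_alignment(path_or_text: PathOrText) -> AlignmentBlock:
    """Read aligned FASTA. ``.`` gaps are normalised to ``-``."""
    rows = []
    seen = set()
    with _as_handle(path_or_text) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id!r}")
            seen.add(rec.id)
            rows.append((rec.id, str(rec.seq).upper().replace(".", GAP).rstrip("*")))
    if not rows:
        raise ValueError("no records in alignment input")
    return AlignmentBlock(rows)


def write_alignment(block: AlignmentBlock, width: int = 60) -> str:
    out = []
    for rid, seq in block.rows:
        out.append(f">{rid}")
        for i in range(0, len(seq), width):
            out.append(seq[i:i + width])
    return "\n".join(out) + "\n"


TAXONOMY_COLUMNS = ["organism", "genus", "superkingdom", "go_photosynthesis_count",
                    "proteome_flags", "busco_completeness"]


def read_taxonomy_table(path_or_text: PathOrText) -> List[TaxonRecord]:
    """Read the per-proteome metadata TSV.

    Required columns: organism, genus, superkingdom, go_photosynthesis_count,
    proteome_flags (comma-separated subset of reference/nonredundant),
    busco_completeness (blank = missing, parsed as missing, never zero).
    """
    with _as_handle(path_or_text) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        flags = frozenset(f for f in row["proteome_flags"].split(",") if f)
        busco = row["busco_completeness"].strip()
        records.append(TaxonRecord(
            organism=row["organism"],
            genus=row["genus"],
            superkingdom=row["superkingdom"],
            go_photosynthesis_count=int(row["go_photosynthesis_count"]),
            proteome_flags=flags,
            busco_completeness=float(busco) if busco else None,
        ))
    return records


def write_taxonomy_table(records) -> str:
    rows = []
    for t in records:
        rows.append({
            "organism": t.organism,
            "genus": t.genus,
            "superkingdom": t.superkingdom,
            "go_photosynthesis_count": t.go_photosynthesis_count,
            "proteome_flags": ",".join(sorted(t.proteome_flags)),
            "busco_completeness": "" if t.busco_completeness is None else f"{t.busco_completeness:g}",
        })
    df = pd.DataFrame(rows, columns=TAXONOMY_COLUMNS)
    return df.to_csv(sep="\t", index=False)
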