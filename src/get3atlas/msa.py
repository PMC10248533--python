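"""Seed-anchored progressive alignment and keep-length addition.

The seed alignment (a stand-in for a structure-based alignment of solved
folds) is treated as frozen homology: new sequences are aligned to the
profile of the growing alignment, so seed rows never lose their mutual
gap pattern — insertions only ever add shared all-gap columns.
"""
from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from ._align import nw_profile
from .harvest import MASK_SCORE, X_IDX, _AA_INDEX, encode_for_profile
from .records import GAP, AlignmentBlock, SequenceRecord

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def _msa_pssm(rows: Sequence[Tuple[str, str]], pseudocount: float = 1.0) -> np.ndarray:
    """Per-column log-odds scores (width, 22) over every column of an
    alignment (unlike match-state profiles, no column is dropped)."""
    width = len(rows[0][1])
    counts = np.zeros((width, 20))
    for _, row in rows:
        for col, c in enumerate(row):
            i = _AA_INDEX.get(c)
            if i is not None and i < 20:
                counts[col, i] += 1
    total = counts.sum()
    bg = (counts.sum(axis=0) + 1.0) / (total + 20.0)
    n = counts.sum(axis=1, keepdims=True)
    lo = np.log2((counts + pseudocount * bg) / ((n + pseudocount) * bg))
    out = np.empty((width, 22))
    out[:, :20] = lo
    out[:, X_IDX] = 0.0
    out[:, 21] = MASK_SCORE
    return out


def profile_score(seed: AlignmentBlock, seq: SequenceRecord) -> float:
    """Global-alignment score of a sequence against the seed profile,
    used to order sequences for progressive addition."""
    pssm = _msa_pssm(seed.rows)
    cell = pssm[:, encode_for_profile(seq.residues)]
    score, _ = nw_profile(cell, GAP_OPEN, GAP_EXTEND)
    return float(score)


def align_to_seed(seqs: Sequence[SequenceRecord], seed: AlignmentBlock) -> AlignmentBlock:
    """Progressively align sequences to the seed alignment.

    Sequences are added in decreasing order of profile score to the seed;
    each addition aligns the sequence to the current alignment profile.
    Insertions open new all-gap columns shared by all earlier rows, so the
    seed's homology columns are never rearranged.
    """
    order = sorted(seqs, key=lambda s: (-profile_score(seed, s), s.id))
    rows: List[Tuple[str, str]] = list(seed.rows)
    for seq in order:
        pssm = _msa_pssm(rows)
        cell = pssm[:, encode_for_profile(seq.residues)]
        _, path = nw_profile(cell, GAP_OPEN, GAP_EXTEND)
        new_row = []
        col_expansion: List[Tuple[int, int]] = []   # (old col or -1, n/a)
        for col, pos in path:
            if col >= 0 and pos >= 0:
                col_expansion.append((col, 0))
                new_row.append(seq.residues[pos])
            elif col >= 0:
                col_expansion.append((col, 0))
                new_row.append(GAP)
            else:
                col_expansion.append((-1, 0))
                new_row.append(seq.residues[pos])
        rebuilt = []
        for rid, row in rows:
            out = []
            for col, _ in col_expansion:
                out.append(row[col] if col >= 0 else GAP)
            rebuilt.append((rid, "".join(out)))
        rebuilt.append((seq.id, "".join(new_row)))
        rows = rebuilt
    return AlignmentBlock(rows)


def add_keeplength(msa: AlignmentBlock, query: SequenceRecord) -> Tuple[str, List[Tuple[int, str]]]:
    """Align a query to the alignment profile without changing its width.

    Residues that fall in insertions relative to the alignment are dropped
    from the returned row and reported as (1-based position, residue).
    """
    pssm = _msa_pssm(msa.rows)
    cell = pssm[:, encode_for_profile(query.residues)]
    _, path = nw_profile(cell, GAP_OPEN, GAP_EXTEND)
    row = [GAP] * msa.width
    discarded: List[Tuple[int, str]] = []
    for col, pos in path:
        if col >= 0 and pos >= 0:
            row[col] = query.residues[pos]
        elif col < 0 and pos >= 0:
            discarded.append((pos + 1, query.residues[pos]))
    return "".join(row), discarded
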