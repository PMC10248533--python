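"""Greedy identity clustering with paired-half retention.

Identity is computed from a global alignment (BLOSUM62, gap open 11,
extend 1) as identical aligned pairs over aligned columns; terminal gaps
count in the denominator. Clustering is centroid-greedy: sequences are
visited longest first (ties by id) and join the first existing
representative reaching the identity threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set

from Bio import Align
from Bio.Align import substitution_matrices

from .records import SequenceRecord


def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    return a


_ALIGNER = _make_aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical residue pairs over aligned columns."""
    aln = _ALIGNER.align(a.residues, b.residues)[0]
    ra, rb = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    cols = sum(1 for x, y in zip(ra, rb) if not (x == "-" and y == "-"))
    return ident / cols if cols else 0.0


@dataclass
class ClusterSet:
    clusters: Dict[str, List[str]]      # representative id -> member ids
    threshold: float
    group: str = ""

    @property
    def representatives(self) -> List[str]:
        return list(self.clusters)

    def members(self) -> List[str]:
        return [m for ms in self.clusters.values() for m in ms]

    def verify(self, seqs: Mapping[str, SequenceRecord]) -> bool:
        """Post-hoc check: every member reaches the threshold identity to
        its representative."""
        for rep, members in self.clusters.items():
            for m in members:
                if m == rep:
                    continue
                if pairwise_identity(seqs[rep], seqs[m]) < self.threshold:
                    return False
        return True


def greedy_cluster(seqs: Sequence[SequenceRecord], threshold: float,
                   group: str = "") -> ClusterSet:
    """Deterministic greedy clustering at a minimum identity threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    order = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    clusters: Dict[str, List[str]] = {}
    reps: List[SequenceRecord] = []
    for s in order:
        placed = False
        for rep in reps:
            if pairwise_identity(rep, s) >= threshold:
                clusters[rep.id].append(s.id)
                placed = True
                break
        if not placed:
            clusters[s.id] = [s.id]
            reps.append(s)
    return ClusterSet(clusters, threshold, group)


def keep_pair_halves(reps: Iterable[str], pair_map: Mapping[str, str]) -> Set[str]:
    """Close a representative set under pseudodimer partnership: where one
    half of a pair is a representative, the other half is kept as well."""
    for a, b in pair_map.items():
        if pair_map.get(b) != a:
            raise ValueError(f"pair map not symmetric at {a!r}<->{b!r}")
    out = set(reps)
    frontier = list(out)
    while frontier:
        nxt = [pair_map[x] for x in frontier
               if x in pair_map and pair_map[x] not in out]
        out.update(nxt)
        frontier = nxt
    return out


def tiered_cluster(groups: Mapping[str, Sequence[SequenceRecord]],
                   thresholds: Mapping[str, float],
                   pair_map: Mapping[str, str] = (),
                   always_keep: Iterable[str] = ()) -> Set[str]:
    """Cluster each named group at its own identity threshold and pool the
    representatives, then close under pseudodimer pairs and forced keeps
    (e.g. anchor proteins and those with solved structures)."""
    reps: Set[str] = set()
    for name, seqs in groups.items():
        cs = greedy_cluster(seqs, thresholds[name], group=name)
        reps.update(cs.representatives)
    reps.update(always_keep)
    if pair_map:
        reps = keep_pair_halves(reps, dict(pair_map))
    return reps
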