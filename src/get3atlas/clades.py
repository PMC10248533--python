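"""From a rooted tree plus metadata to biological summaries: subfamily
assignment by anchor proteins, monophyly tests, genus-level
presence/absence, the photosynthesis classifier, and copy-number tallies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .records import TaxonRecord
from .tree import Phylogeny, test_monophyly  # noqa: F401  (re-exported here)

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AnchorSet:
    """A subfamily label with the leaf ids that define its clade,
    e.g. the A. thaliana paralog for each plant Get3 subfamily."""

    label: str
    anchor_ids: frozenset

    def __init__(self, label: str, anchor_ids: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "anchor_ids", frozenset(anchor_ids))
        if not self.anchor_ids:
            raise ValueError("anchor set must be nonempty")


class AnchorsNotSeparableError(ValueError):
    pass


def assign_clades(rooted_tree: Phylogeny,
                  anchors: Sequence[AnchorSet]) -> Dict[str, str]:
    """Label every leaf by the anchor-defined clade containing it.

    A label's clade is the largest clade containing every anchor of that
    set and no anchor of any other set; leaves in no such clade are
    "unassigned". Raises AnchorsNotSeparableError when even the anchors'
    MRCA clade contains a foreign anchor.
    """
    labels = [a.label for a in anchors]
    if len(labels) != len(set(labels)):
        raise ValueError("anchor labels must be unique")
    leaf_names = set(rooted_tree.leaf_names())
    for a in anchors:
        missing = a.anchor_ids - leaf_names
        if missing:
            raise KeyError(f"anchors not in tree: {sorted(missing)}")
    foreign: Dict[str, set] = {
        a.label: set().union(*(b.anchor_ids for b in anchors if b is not a))
        for a in anchors}

    out = {name: UNASSIGNED for name in leaf_names}
    for a in anchors:
        node = rooted_tree.mrca(a.anchor_ids)
        if rooted_tree.leaf_set(node) & foreign[a.label]:
            raise AnchorsNotSeparableError(
                f"anchors of {a.label!r} are interleaved with other anchors")
        # expand to the largest clade free of foreign anchors
        while node.parent is not None:
            parent_set = rooted_tree.leaf_set(node.parent)
            if parent_set & foreign[a.label]:
                break
            node = node.parent
        for name in rooted_tree.leaf_set(node):
            out[name] = a.label
    return out


def classify_photosynthetic(taxon: TaxonRecord) -> bool:
    """Putatively photosynthetic: proteome has more than 10 proteins
    annotated with the photosynthesis GO term (strictly greater)."""
    return taxon.go_photosynthesis_count > 10


def proteome_quality_filter(taxa: Iterable[TaxonRecord]) -> List[TaxonRecord]:
    """Keep proteomes flagged reference or nonredundant, or with BUSCO
    completeness strictly above 75% (missing BUSCO does not qualify)."""
    out = []
    for t in taxa:
        if ("reference" in t.proteome_flags
                or "nonredundant" in t.proteome_flags
                or (t.busco_completeness is not None and t.busco_completeness > 75)):
            out.append(t)
    return out


def genus_presence_matrix(leaf_labels: Mapping[str, str],
                          taxonomy: Sequence[TaxonRecord],
                          leaf_to_organism: Mapping[str, str],
                          subfamilies: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Boolean genus x subfamily matrix: a cell is True iff at least one
    leaf with that label maps to an organism of that genus.

    Leaves without taxonomy are logged and excluded; "unassigned" leaves
    are not part of the matrix.
    """
    genus_of = {t.organism: t.genus for t in taxonomy}
    if subfamilies is None:
        subfamilies = sorted({l for l in leaf_labels.values() if l != UNASSIGNED})
    genera = sorted({t.genus for t in taxonomy})
    mat = pd.DataFrame(False, index=genera, columns=list(subfamilies))
    for leaf, label in leaf_labels.items():
        if label == UNASSIGNED or label not in mat.columns:
            continue
        org = leaf_to_organism.get(leaf)
        genus = genus_of.get(org)
        if genus is None:
            log.warning("leaf %s: no taxonomy for organism %r; skipped", leaf, org)
            continue
        mat.loc[genus, label] = True
    mat.index.name = "genus"
    return mat


def copy_number_tally(leaf_labels: Mapping[str, str],
                      leaf_to_organism: Mapping[str, str]) -> pd.DataFrame:
    """Organism x subfamily counts of labelled leaves (group-by tally),
    rows ordered by organism name."""
    rows = []
    for leaf, label in leaf_labels.items():
        if label == UNASSIGNED:
            continue
        org = leaf_to_organism.get(leaf)
        if org is None:
            log.warning("leaf %s: no organism mapping; skipped", leaf)
            continue
        rows.append((org, label))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["organism", "subfamily"])
    tally = df.groupby(["organism", "subfamily"]).size().unstack(fill_value=0)
    return tally.sort_index()


@dataclass
class CladeAtlas:
    """Leaf labels plus the derived genus presence and copy-count tables."""

    leaf_labels: Dict[str, str]
    presence: pd.DataFrame
    copy_counts: pd.DataFrame

    @classmethod
    def build(cls, rooted_tree: Phylogeny, anchors: Sequence[AnchorSet],
              taxonomy: Sequence[TaxonRecord],
              leaf_to_organism: Mapping[str, str]) -> "CladeAtlas":
        labels = assign_clades(rooted_tree, anchors)
        return cls(labels,
                   genus_presence_matrix(labels, taxonomy, leaf_to_organism,
                                         [a.label for a in anchors]),
                   copy_number_tally(labels, leaf_to_organism))
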