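"""The end-to-end family analysis: harvest -> tiered clustering ->
seed-anchored alignment -> ML phylogeny with bootstrap -> MRCA rooting ->
70% support collapse -> evolutionary placement of non-representatives ->
anchor-based clade assignment -> presence/absence and copy-number tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping

import numpy as np

from .clades import (AnchorSet, CladeAtlas, UNASSIGNED, assign_clades,
                     classify_photosynthetic, copy_number_tally,
                     genus_presence_matrix, proteome_quality_filter)
from .cluster import tiered_cluster
from .harvest import (DomainRecord, build_profile, calibrate_score_threshold,
                      harvest_domains)
from .models import load_model
from .msa import add_keeplength, align_to_seed
from .placement import PlacementResult, epa_place
from .records import AlignmentBlock, SequenceRecord
from .synth import FamilySimulation
from .tree import Phylogeny, collapse_low_support, root_at_mrca
from .treebuild import bootstrap_supports, infer_ml_tree

log = logging.getLogger(__name__)

#: minimum identity per clustering tier, as in the focused reconstruction:
#: plants, aCD-bearing photosynthetic bacteria, other photosynthetic
#: bacteria, everything else
TIER_THRESHOLDS = {"plants": 0.85, "acd_photo_bacteria": 0.70,
                   "photo_bacteria": 0.65, "other": 0.60}


@dataclass
class PipelineResult:
    domains: List[DomainRecord]
    score_threshold: float
    acd_threshold: float
    representatives: List[str]
    msa: AlignmentBlock
    ml_tree: Phylogeny                 # with bootstrap supports
    rooted_tree: Phylogeny
    collapsed_tree: Phylogeny
    placements: Dict[str, PlacementResult]
    labels: Dict[str, str]             # every domain id -> subfamily label
    atlas: CladeAtlas


def _placement_label(ref_tree: Phylogeny, placement: PlacementResult,
                     leaf_labels: Mapping[str, str]) -> str:
    """Label for a placed query: the unanimous label of the leaves on one
    side of its best attachment edge (tried child side, then the rest)."""
    edges = ref_tree.edges()
    node = edges[placement.best_edge]
    side = ref_tree.leaf_set(node)
    other = frozenset(ref_tree.leaf_names()) - side
    for leaves in (side, other):
        labels = {leaf_labels.get(l, UNASSIGNED) for l in leaves}
        if len(labels) == 1 and UNASSIGNED not in labels:
            return labels.pop()
    return UNASSIGNED


def run_family_analysis(sim: FamilySimulation, model_name: str = "VT",
                        frequencies: str = "model",
                        bootstrap_replicates: int = 30,
                        collapse_threshold: float = 70.0,
                        search_iterations: int = 3,
                        coverage: float = 0.90,
                        seed: int = 0) -> PipelineResult:
    """Run the full analysis on a synthetic family and build the atlas."""
    rng = np.random.default_rng(seed)
    log.info("pipeline start: seed=%d, model=%s", seed, model_name)

    # --- domain harvest ---------------------------------------------------
    profile = build_profile(sim.seed_alignment)
    thr = calibrate_score_threshold(profile, sim.proteins,
                                    seed=int(rng.integers(2 ** 31)))
    acd_profile = build_profile(sim.acd_seed_alignment)
    acd_thr = calibrate_score_threshold(acd_profile, sim.proteins,
                                        seed=int(rng.integers(2 ** 31)))
    domains = harvest_domains(profile, sim.proteins, thr,
                              iterations=search_iterations, coverage=coverage,
                              acd_profile=acd_profile, acd_threshold=acd_thr)
    dom_by_id = {d.id: d for d in domains}
    dom_seqs = {d.id: d.to_sequence_record() for d in domains}

    def species_of(domain_id: str) -> str:
        parts = domain_id.split("|")
        return parts[1] if len(parts) >= 2 else ""

    # --- tiered clustering ------------------------------------------------
    taxa_ok = proteome_quality_filter(sim.taxonomy)
    photo = {t.organism for t in taxa_ok if classify_photosynthetic(t)}
    kingdom = {t.organism: t.superkingdom for t in taxa_ok}
    groups: Dict[str, List[SequenceRecord]] = {k: [] for k in TIER_THRESHOLDS}
    for d in domains:
        sp = species_of(d.id)
        if kingdom.get(sp) == "Eukaryota" and sp in photo:
            groups["plants"].append(dom_seqs[d.id])
        elif kingdom.get(sp) == "Bacteria" and sp in photo and d.has_acd:
            groups["acd_photo_bacteria"].append(dom_seqs[d.id])
        elif kingdom.get(sp) == "Bacteria" and sp in photo:
            groups["photo_bacteria"].append(dom_seqs[d.id])
        else:
            groups["other"].append(dom_seqs[d.id])
    pair_map = {d.id: d.partner_id for d in domains
                if d.partner_id and d.partner_id in dom_by_id}
    always_keep = set(sim.anchor_domains.values()) | set(sim.rooting_anchors)
    always_keep &= set(dom_by_id)
    reps = tiered_cluster({k: v for k, v in groups.items() if v},
                          TIER_THRESHOLDS, pair_map, always_keep)
    reps &= set(dom_by_id)
    log.info("clustering: %d domains -> %d representatives", len(domains), len(reps))

    # --- seed-anchored alignment -----------------------------------------
    msa = align_to_seed([dom_seqs[r] for r in sorted(reps)], sim.seed_alignment)

    # --- phylogeny --------------------------------------------------------
    model = load_model(model_name, frequencies,
                       alignment=msa if frequencies == "empirical" else None)
    ml_tree = infer_ml_tree(msa, model)
    ml_tree = bootstrap_supports(msa, model, bootstrap_replicates,
                                 seed=int(rng.integers(2 ** 31)), tree=ml_tree)
    rooted = root_at_mrca(ml_tree, *(a for a in sim.rooting_anchors))
    collapsed = collapse_low_support(rooted, collapse_threshold)

    # --- clade assignment on the collapsed tree ---------------------------
    anchors = [AnchorSet(label, {dom_id})
               for label, dom_id in sim.anchor_domains.items()
               if dom_id in dom_by_id]
    leaf_labels = assign_clades(collapsed, anchors)

    # --- evolutionary placement of non-representatives --------------------
    placements: Dict[str, PlacementResult] = {}
    labels: Dict[str, str] = dict(leaf_labels)
    for d in domains:
        if d.id in reps:
            continue
        row, discarded = add_keeplength(msa, dom_seqs[d.id])
        if discarded:
            log.info("keeplength: %s discarded %d residues", d.id, len(discarded))
        pr = epa_place(d.id, row, ml_tree, msa, model)
        placements[d.id] = pr
        labels[d.id] = _placement_label(ml_tree, pr, leaf_labels)
    labels = {k: v for k, v in labels.items() if k in dom_by_id}

    # --- atlas ------------------------------------------------------------
    leaf_to_org = {d.id: species_of(d.id) for d in domains}
    presence = genus_presence_matrix(labels, taxa_ok, leaf_to_org,
                                     subfamilies=[a.label for a in anchors])
    copies = copy_number_tally(labels, leaf_to_org)
    atlas = CladeAtlas(labels, presence, copies)

    return PipelineResult(domains, thr, acd_thr, sorted(reps), msa, ml_tree,
                          rooted, collapsed, placements, labels, atlas)


def evaluate_against_truth(sim: FamilySimulation,
                           result: PipelineResult) -> Dict[str, float]:
    """Compare a pipeline run with the generator's truth tables.

    Returns label recovery (fraction of harvested true domains labelled
    with their true subfamily), domain recall, and the fraction of forced
    absences correctly shown as absent in the presence matrix.
    """
    truth = sim.domain_truth
    found = [d for d in result.domains if d.id in truth]
    recall = len(found) / len(truth) if truth else 1.0
    correct = sum(1 for d in found if result.labels.get(d.id) == truth[d.id])
    label_recovery = correct / len(truth) if truth else 1.0

    cfg = sim.config
    absent_ok, absent_total = 0, 0
    genus_of = {t.organism: t.genus for t in sim.taxonomy}
    for subfam, clade in cfg.forced_loss.items():
        for sp in cfg.clades[clade]:
            absent_total += 1
            g = genus_of.get(sp, sp)
            pres = result.atlas.presence
            if subfam not in pres.columns or g not in pres.index:
                absent_ok += 1
            elif not bool(pres.loc[g, subfam]):
                absent_ok += 1
    return {
        "label_recovery": label_recovery,
        "domain_recall": recall,
        "forced_absence_recovery": absent_ok / absent_total if absent_total else 1.0,
    }
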