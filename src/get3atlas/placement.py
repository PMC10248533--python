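"""Evolutionary placement of query sequences onto a fixed reference tree.

A query row (already aligned to the reference alignment width, e.g. the
output of keep-length addition) is attached at the midpoint of every edge
in turn by a pendant branch whose length is the only free parameter; the
edge maximizing the log-likelihood wins.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import BRANCH_MAX, BRANCH_MIN, SiteData, TreeLikelihood
from .models import SubstitutionModel
from .records import AlignmentBlock, GAP
from .tree import Phylogeny


@dataclass
class PlacementResult:
    query_id: str
    best_edge: int                      # index into edge_names
    pendant_length: float
    log_likelihood: float
    edge_names: List[str]               # edge label = child-side leaf-set tag
    edge_log_likelihoods: np.ndarray
    edge_pendant_lengths: np.ndarray


def _edge_label(tree: Phylogeny, node) -> str:
    names = sorted(tree.leaf_set(node))
    return names[0] if len(names) == 1 else f"clade({names[0]}+{len(names) - 1})"


def epa_place(query_id: str, query_row: str, ref_tree: Phylogeny,
              ref_msa: AlignmentBlock, model: SubstitutionModel) -> PlacementResult:
    """Place one gapped query row (width = reference alignment width)."""
    if len(query_row) != ref_msa.width:
        raise ValueError("query row width must equal the reference alignment width")
    if all(c == GAP or c == "X" for c in query_row):
        raise ValueError("query is all gaps")

    joint = AlignmentBlock(list(ref_msa.rows) + [(query_id, query_row)])
    data_all = SiteData.from_alignment(joint, model)
    ref_data = SiteData(ref_msa.ids,
                        data_all.patterns[:-1], data_all.weights, model.k)
    qpart = SiteData([query_id], data_all.patterns[-1:], data_all.weights,
                     model.k).leaf_partial(query_id)

    tl = TreeLikelihood(ref_tree, ref_data, model)
    tl.compute_down()
    up = tl.compute_up()

    edges = ref_tree.edges()
    lnls = np.empty(len(edges))
    pendants = np.empty(len(edges))
    w = ref_data.weights
    for e, node in enumerate(edges):
        half = max(node.length, 0.0) / 2.0
        Ph = model.transition_matrix(half)
        below = Ph @ tl._down[id(node)]
        u, us = up[id(node)]
        above = Ph.T @ u
        mid = below * above                    # (k, npat), state at midpoint
        scale = tl._down_scale[id(node)] + us

        def lnl_at(tq: float) -> float:
            Pq = model.transition_matrix(tq)
            site = np.einsum("kp,kp->p", mid, Pq @ qpart)
            return float(w @ (np.log(np.maximum(site, 1e-300)) + scale))

        res = minimize_scalar(lambda t: -lnl_at(t),
                              bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
                              options={"xatol": 1e-6, "maxiter": 30})
        lnls[e] = -res.fun
        pendants[e] = float(res.x)

    best = int(np.argmax(lnls))
    return PlacementResult(
        query_id=query_id,
        best_edge=best,
        pendant_length=float(pendants[best]),
        log_likelihood=float(lnls[best]),
        edge_names=[_edge_label(ref_tree, n) for n in edges],
        edge_log_likelihoods=lnls,
        edge_pendant_lengths=pendants,
    )
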