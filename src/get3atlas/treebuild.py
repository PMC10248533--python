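"""Tree search: neighbor-joining start trees, NNI hill climbing,
nonparametric bootstrap supports.

The search is deliberately desk-scale: NJ on maximum-likelihood pairwise
distances, per-branch length optimization, and best-improving NNI moves.
"""
from __future__ import annotations

from typing import List, Optional

import numpy as np

from .likelihood import SiteData, TreeLikelihood, ml_distance_matrix
from .models import SubstitutionModel
from .records import AlignmentBlock
from .tree import Node, Phylogeny


def nj_start_tree(distances: np.ndarray, names: List[str]) -> Phylogeny:
    """Neighbor-joining with negative branch lengths clamped to zero.

    Ties in the Q criterion break deterministically toward the pair whose
    (sorted) cluster ids are smallest; a cluster's id is the smallest leaf
    name it contains. The result is unrooted (trifurcating virtual root).
    """
    D = np.asarray(distances, dtype=float)
    n = len(names)
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")

    nodes = [Node(name) for name in names]
    ids = list(names)                     # tie-break id per active cluster
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((ids[active[i]], ids[active[j]]))), i, j)
            for i, j in cand if i < j)
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        ci, cj = nodes[ai], nodes[aj]
        ci.length, cj.length = li, lj
        parent.add(ci)
        parent.add(cj)
        # distances from the new cluster to the rest
        new_row = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D[ai, :] = new_row
        D[:, ai] = new_row
        D[ai, ai] = 0.0
        nodes[ai] = parent
        ids[ai] = min(ids[ai], ids[aj])
        active.remove(aj)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node()
    for idx, l in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(l, 0.0)
        root.add(nodes[idx])
    return Phylogeny(root, rooted=False)


def optimize_branch_lengths(tree: Phylogeny, msa: AlignmentBlock,
                            model: SubstitutionModel, tol: float = 1e-4,
                            max_sweeps: int = 20) -> Phylogeny:
    """Optimize every branch length in place (copy returned)."""
    t = tree.copy()
    data = SiteData.from_alignment(msa, model)
    TreeLikelihood(t, data, model).optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps)
    return t


# ------------------------------------------------------------------- NNI
def _node_path(tree: Phylogeny, node: Node) -> List[int]:
    path = []
    n = node
    while n.parent is not None:
        path.append(n.parent.children.index(n))
        n = n.parent
    return list(reversed(path))


def _locate(tree: Phylogeny, path: List[int]) -> Node:
    n = tree.root
    for i in path:
        n = n.children[i]
    return n


def _nni_neighbors(tree: Phylogeny, node: Node) -> List[Phylogeny]:
    """The two NNI rearrangements around the edge above ``node``.

    ``node`` must be internal with two children and a parent with at least
    one other child; subtrees keep their own branch lengths when swapped.
    """
    if node.is_leaf or node.parent is None or len(node.children) != 2:
        return []
    parent = node.parent
    others = [c for c in parent.children if c is not node]
    if not others:
        return []
    x_idx = parent.children.index(others[0])
    v_path = _node_path(tree, node)
    out = []
    for child_idx in (0, 1):
        t = tree.copy()
        v = _locate(t, v_path)
        p = v.parent
        a = v.children[child_idx]
        x = p.children[x_idx]
        v.children[child_idx] = x
        x.parent = v
        p.children[x_idx] = a
        a.parent = p
        out.append(Phylogeny(t.root, t.rooted))
    return out


def _evaluate_nni_moves(tree: Phylogeny, data: SiteData,
                        model: SubstitutionModel):
    """Score both NNI alternatives at every eligible internal edge using
    one set of cached partials (current branch lengths throughout).

    Returns (current_lnl, moves) with moves = [(lnl, node, child_idx)],
    where the move swaps node.children[child_idx] with the first other
    child of node's parent.
    """
    tl = TreeLikelihood(tree, data, model)
    tl.compute_down()
    up = tl.compute_up()
    pi = model.freqs
    w = data.weights
    npat = w.shape[0]
    cur = tl.log_likelihood()
    moves = []
    for v in tree.internal_edges():
        if len(v.children) != 2:
            continue
        p = v.parent
        others = [c for c in p.children if c is not v]
        if not others:
            continue
        x = others[0]
        rest = [c for c in p.children if c is not v and c is not x]
        if p.parent is None:
            upvec = np.repeat(pi[:, None], npat, axis=1)
            upsc = np.zeros(npat)
        else:
            upvec, upsc = up[id(p)]
        base = upvec
        base_sc = upsc.copy()
        for r in rest:
            base = base * tl._mdown[id(r)]
            base_sc = base_sc + tl._down_scale[id(r)]
        a, b = v.children
        Pv = model.transition_matrix(v.length)
        for child_idx, keep, move in ((0, b, a), (1, a, b)):
            # swap `move` with x: v' = {keep, x}, p gains `move`
            dv = tl._mdown[id(keep)] * tl._mdown[id(x)]
            dv_sc = tl._down_scale[id(keep)] + tl._down_scale[id(x)]
            m = dv.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            dv, dv_sc = dv / m, dv_sc + np.log(m)
            site = np.einsum("kp,kp->p",
                             base * tl._mdown[id(move)], Pv @ dv)
            logs = (np.log(np.maximum(site, 1e-300)) + base_sc + dv_sc
                    + tl._down_scale[id(move)])
            moves.append((float(w @ logs), v, child_idx))
    return cur, moves


def _apply_nni(node, child_idx: int) -> None:
    p = node.parent
    x = [c for c in p.children if c is not node][0]
    a = node.children[child_idx]
    xi = p.children.index(x)
    node.children[child_idx] = x
    x.parent = node
    p.children[xi] = a
    a.parent = p


def nni_search(tree: Phylogeny, msa: AlignmentBlock, model: SubstitutionModel,
               max_rounds: int = 30, optimize_after_move: bool = True) -> Phylogeny:
    """Best-improving nearest-neighbor-interchange hill climb.

    Each round evaluates both alternatives at every eligible internal edge
    at current branch lengths, accepts the single best improving move, and
    (optionally) runs one branch-length sweep; stops when no move improves
    the log-likelihood. lnL is non-decreasing across accepted moves.
    """
    data = SiteData.from_alignment(msa, model)
    current = tree.copy()
    for _ in range(max_rounds):
        cur_lnl, moves = _evaluate_nni_moves(current, data, model)
        if not moves:
            break
        best = max(moves, key=lambda m: m[0])
        if best[0] <= cur_lnl + 1e-9:
            break
        _apply_nni(best[1], best[2])
        if optimize_after_move:
            TreeLikelihood(current, data, model).optimize_branch_lengths(
                tol=1e-3, max_sweeps=2)
    return current


# -------------------------------------------------------------- pipeline
def infer_ml_tree(msa: AlignmentBlock, model: SubstitutionModel,
                  tol: float = 1e-3, max_nni_rounds: int = 20) -> Phylogeny:
    """NJ start on ML distances, branch-length optimization, NNI search."""
    data = SiteData.from_alignment(msa, model)
    D = ml_distance_matrix(data, model)
    t = nj_start_tree(D, data.taxa)
    TreeLikelihood(t, data, model).optimize_branch_lengths(tol=tol, max_sweeps=8)
    t = nni_search(t, msa, model, max_rounds=max_nni_rounds)
    TreeLikelihood(t, data, model).optimize_branch_lengths(tol=tol, max_sweeps=4)
    return t


def bootstrap_supports(msa: AlignmentBlock, model: SubstitutionModel,
                       replicates: int, seed: int,
                       tree: Optional[Phylogeny] = None) -> Phylogeny:
    """Nonparametric bootstrap supports on the ML tree.

    Columns are resampled with replacement; each replicate is inferred with
    a fast recipe (NJ on ML distances, one branch-length sweep, one NNI
    round) and the support of an internal edge is the percentage of
    replicates whose tree contains the same bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    data = SiteData.from_alignment(msa, model)
    if tree is None:
        tree = infer_ml_tree(msa, model)
    counts: dict = {}
    for _ in range(replicates):
        rdata = data.resample(rng)
        D = ml_distance_matrix(rdata, model)
        rt = nj_start_tree(D, rdata.taxa)
        TreeLikelihood(rt, rdata, model).optimize_branch_lengths(tol=1e-2, max_sweeps=1)
        rt = _nni_one_round(rt, rdata, model)
        for bp in rt.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    out = tree.copy()
    all_leaves = frozenset(out.leaf_names())
    anchor = min(all_leaves)
    for n in out.internal_edges():
        side = out.leaf_set(n)
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            n.support = 100.0 * counts.get(side, 0) / replicates
    return out


def _nni_one_round(tree: Phylogeny, data: SiteData, model: SubstitutionModel) -> Phylogeny:
    cur_lnl, moves = _evaluate_nni_moves(tree, data, model)
    if not moves:
        return tree
    best = max(moves, key=lambda m: m[0])
    if best[0] > cur_lnl + 1e-9:
        _apply_nni(best[1], best[2])
    return tree
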