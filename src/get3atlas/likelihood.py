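"""Felsenstein pruning likelihood over site patterns, branch-length
optimization, and maximum-likelihood pairwise distances.

Alignment columns are compressed to unique patterns with multiplicities;
gaps and unknown residues are missing data (partial vector of ones).
Partial likelihoods are rescaled per node and pattern to avoid underflow.
"""
from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .models import SubstitutionModel
from .records import AlignmentBlock
from .tree import Node, Phylogeny

BRANCH_MIN = 1e-8
BRANCH_MAX = 20.0


class SiteData:
    """Pattern-compressed alignment columns for a fixed taxon set."""

    def __init__(self, taxa: List[str], patterns: np.ndarray, weights: np.ndarray,
                 n_states: int):
        self.taxa = list(taxa)
        self.patterns = patterns          # (ntaxa, npatterns), -1 = missing
        self.weights = weights            # (npatterns,) column multiplicities
        self.n_states = n_states
        self.index = {t: i for i, t in enumerate(taxa)}

    @classmethod
    def from_alignment(cls, msa: AlignmentBlock, model: SubstitutionModel) -> "SiteData":
        mat = np.stack([model.encode(row) for _, row in msa.rows])
        cols, counts = np.unique(mat.T, axis=0, return_counts=True)
        return cls(msa.ids, cols.T.copy(), counts.astype(float), model.k)

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    def resample(self, rng: np.random.Generator) -> "SiteData":
        """Nonparametric bootstrap: resample columns with replacement."""
        n = self.n_sites
        new_w = rng.multinomial(n, self.weights / n).astype(float)
        keep = new_w > 0
        return SiteData(self.taxa, self.patterns[:, keep], new_w[keep], self.n_states)

    def leaf_partial(self, taxon: str) -> np.ndarray:
        """One-hot partial likelihoods (k, npatterns); missing = ones."""
        codes = self.patterns[self.index[taxon]]
        k = self.n_states
        out = np.zeros((k, codes.shape[0]))
        miss = codes < 0
        out[:, miss] = 1.0
        obs = ~miss
        out[codes[obs], np.nonzero(obs)[0]] = 1.0
        return out


class TreeLikelihood:
    """Pruning machinery bound to one (tree, data, model) triple.

    The tree topology must not change while an instance is in use; branch
    lengths may be updated through :meth:`optimize_branch_lengths`.
    """

    def __init__(self, tree: Phylogeny, data: SiteData, model: SubstitutionModel):
        self.tree = tree
        self.data = data
        self.model = model
        missing = set(tree.leaf_names()) - set(data.taxa)
        if missing:
            raise ValueError(f"leaves without alignment rows: {sorted(missing)}")
        for n in tree.edges():
            if n.length is None:
                raise ValueError("all branch lengths must be set")
        self._down: Dict[int, np.ndarray] = {}
        self._down_scale: Dict[int, np.ndarray] = {}
        self._mdown: Dict[int, np.ndarray] = {}
        self._stale = True

    # ------------------------------------------------------------- partials
    def _compute_mdown(self, node: Node) -> None:
        P = self.model.transition_matrix(max(node.length, 0.0))
        self._mdown[id(node)] = P @ self._down[id(node)]

    def compute_down(self) -> None:
        npat = self.data.weights.shape[0]
        for node in self.tree.postorder():
            if node.is_leaf:
                self._down[id(node)] = self.data.leaf_partial(node.name)
                self._down_scale[id(node)] = np.zeros(npat)
            else:
                part = None
                scale = np.zeros(npat)
                for c in node.children:
                    self._compute_mdown(c)
                    contrib = self._mdown[id(c)]
                    part = contrib if part is None else part * contrib
                    scale += self._down_scale[id(c)]
                m = part.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                self._down[id(node)] = part / m
                self._down_scale[id(node)] = scale + np.log(m)
        self._stale = False

    def log_likelihood(self) -> float:
        if self._stale:
            self.compute_down()
        root = self.tree.root
        site = self.model.freqs @ self._down[id(root)]
        logs = np.log(site) + self._down_scale[id(root)]
        return float(self.data.weights @ logs)

    # ------------------------------------------------- per-edge likelihoods
    def _edge_lnl(self, up: np.ndarray, up_scale: np.ndarray, node: Node,
                  t: float) -> float:
        P = self.model.transition_matrix(t)
        site = np.einsum("kp,kp->p", up, P @ self._down[id(node)])
        logs = np.log(np.maximum(site, 1e-300)) + up_scale + self._down_scale[id(node)]
        return float(self.data.weights @ logs)

    def _sibling_product(self, parent: Node, skip: Node):
        part = None
        scale = 0.0
        for s in parent.children:
            if s is skip:
                continue
            part = self._mdown[id(s)] if part is None else part * self._mdown[id(s)]
            scale = scale + self._down_scale[id(s)]
        npat = self.data.weights.shape[0]
        if part is None:
            part = np.ones((self.model.k, npat))
            scale = np.zeros(npat)
        return part, scale

    def optimize_branch_lengths(self, tol: float = 1e-4, max_sweeps: int = 20,
                                max_iter_per_branch: int = 30) -> float:
        """Sweeps of exact one-dimensional optimizations, one per branch,
        until the log-likelihood improves by less than ``tol``.
        Returns the final log-likelihood; lnL is non-decreasing."""
        last = -np.inf
        for _ in range(max_sweeps):
            self.compute_down()
            self._sweep_once(max_iter_per_branch)
            self.compute_down()
            cur = self.log_likelihood()
            if cur - last < tol:
                break
            last = cur
        return self.log_likelihood()

    def _sweep_once(self, max_iter: int) -> None:
        """Preorder pass; each branch is optimized against exact partials
        (ancestor edges already updated this sweep, descendant and sibling
        subtrees untouched, so every evaluation is the true current lnL)."""
        root = self.tree.root
        pi = self.model.freqs

        def optimize_edge(node: Node, up: np.ndarray, up_scale: np.ndarray) -> None:
            res = minimize_scalar(
                lambda t: -self._edge_lnl(up, up_scale, node, t),
                bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
                options={"xatol": 1e-6, "maxiter": max_iter})
            cur = self._edge_lnl(up, up_scale, node, node.length)
            if -res.fun >= cur:
                node.length = float(res.x)
            self._compute_mdown(node)   # siblings processed later need it

        def recurse(node: Node, up: np.ndarray, up_scale: np.ndarray) -> None:
            # up is the rootward partial at node's parent (pi included)
            optimize_edge(node, up, up_scale)
            if node.is_leaf:
                return
            for child in node.children:
                sib, sib_scale = self._sibling_product(node, child)
                P = self.model.transition_matrix(node.length)
                trans = P.T @ up
                part = trans * sib
                m = part.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                recurse(child, part / m, up_scale + sib_scale + np.log(m))

        for child in root.children:
            sib, sib_scale = self._sibling_product(root, child)
            part = pi[:, None] * sib
            m = part.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            recurse(child, part / m, sib_scale + np.log(m))
        self._stale = True

    # -------------------------------------------------------- up partials
    def compute_up(self) -> Dict[int, tuple]:
        """Rootward partials (pi included) keyed by edge child-node id."""
        if self._stale:
            self.compute_down()
        out: Dict[int, tuple] = {}
        pi = self.model.freqs

        def recurse(node: Node, up: np.ndarray, up_scale: np.ndarray) -> None:
            out[id(node)] = (up, up_scale)
            if node.is_leaf:
                return
            P = self.model.transition_matrix(node.length)
            trans = P.T @ up
            for child in node.children:
                sib, sib_scale = self._sibling_product(node, child)
                part = trans * sib
                m = part.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                recurse(child, part / m, up_scale + sib_scale + np.log(m))

        for child in self.tree.root.children:
            sib, sib_scale = self._sibling_product(self.tree.root, child)
            part = pi[:, None] * sib
            m = part.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            recurse(child, part / m, sib_scale + np.log(m))
        return out


def log_likelihood(tree: Phylogeny, msa: AlignmentBlock, model: SubstitutionModel,
                   gamma_categories: Optional[int] = None,
                   gamma_alpha: float = 1.0) -> float:
    """Tree log-likelihood under the model; gaps are missing data.

    With ``gamma_categories`` set, site rates follow a discrete-gamma
    mixture (category medians, mean one) and site likelihoods average over
    categories; the default is rate homogeneity.
    """
    data = SiteData.from_alignment(msa, model)
    if gamma_categories is None:
        return TreeLikelihood(tree, data, model).log_likelihood()
    from scipy.stats import gamma as gamma_dist
    m = gamma_categories
    qs = (np.arange(m) + 0.5) / m
    rates = gamma_dist.ppf(qs, a=gamma_alpha, scale=1.0 / gamma_alpha)
    rates = rates / rates.mean()
    per_cat = []
    for r in rates:
        scaled = tree.copy()
        for n in scaled.edges():
            n.length = n.length * r
        tl = TreeLikelihood(scaled, data, model)
        tl.compute_down()
        site = model.freqs @ tl._down[id(scaled.root)]
        per_cat.append(np.log(np.maximum(site, 1e-300))
                       + tl._down_scale[id(scaled.root)])
    stacked = np.stack(per_cat)            # (m, npat)
    mx = stacked.max(axis=0)
    mix = mx + np.log(np.exp(stacked - mx).mean(axis=0))
    return float(data.weights @ mix)


# ----------------------------------------------------- pairwise ML distances
def _pair_lnl(model: SubstitutionModel, counts: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """lnL of each pair at its own candidate time (up to a pair constant);
    counts (p,k,k) flattened-compatible, ts (p,)."""
    E = np.exp(np.outer(ts, model._eigvals))            # (p, k)
    P = np.einsum("ik,pk,kj->pij", model._right, E, model._left)
    np.clip(P, 1e-300, None, out=P)
    np.log(P, out=P)
    return np.einsum("pij,pij->p", counts, P)


def ml_distance_matrix(data: SiteData, model: SubstitutionModel,
                       grid_size: int = 40, refine_iters: int = 14) -> np.ndarray:
    """Pairwise maximum-likelihood distances under the model
    (coarse geometric grid + golden-section refinement, vectorized).

    The equilibrium-frequency term of the pair likelihood does not depend
    on t, so the optimization drops it."""
    taxa = data.taxa
    n = len(taxa)
    k = model.k
    pats = data.patterns
    w = data.weights
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = np.zeros((len(pairs), k, k))
    for p, (i, j) in enumerate(pairs):
        a, b = pats[i], pats[j]
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts[p], (a[ok], b[ok]), w[ok])

    # grid phase: all pairs share each candidate t, one matmul scores all
    grid = np.geomspace(1e-4, BRANCH_MAX, grid_size)
    logP = np.log(np.clip(model.transition_matrices(grid), 1e-300, None))
    scores = counts.reshape(len(pairs), -1) @ logP.reshape(grid_size, -1).T
    best = scores.argmax(axis=1)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid_size - 1)]
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo.copy(), hi.copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _pair_lnl(model, counts, c)
    fd = _pair_lnl(model, counts, d)
    for _ in range(refine_iters):
        take_c = fc > fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c_new = b - invphi * (b - a)
        d_new = a + invphi * (b - a)
        fc_new = np.where(take_c, _pair_lnl(model, counts, c_new), fd)
        fd_new = np.where(take_c, fc, _pair_lnl(model, counts, d_new))
        c, d, fc, fd = c_new, d_new, fc_new, fd_new
    t_opt = (a + b) / 2
    D = np.zeros((n, n))
    for p, (i, j) in enumerate(pairs):
        D[i, j] = D[j, i] = t_opt[p]
    return D
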