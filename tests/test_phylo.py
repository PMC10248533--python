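"""Maximum-likelihood machinery: substitution models, pruning likelihood,
distances, NJ, branch-length optimization, NNI, bootstrap, placement."""
import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import get3atlas as g
from get3atlas.likelihood import SiteData, TreeLikelihood, ml_distance_matrix
from get3atlas.treebuild import _nni_neighbors

from conftest import random_tree


class TestModels:
    @pytest.mark.parametrize("name", ["LG", "VT", "TOY3"])
    def test_rate_matrix_contracts(self, name):
        m = g.load_model(name)
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
        # normalised: one expected substitution per unit time
        assert np.dot(m.freqs, np.diag(m.Q)) == pytest.approx(-1.0, abs=1e-12)
        # detailed balance
        flux = m.freqs[:, None] * m.Q
        assert np.allclose(flux, flux.T, atol=1e-12)
        for t in (0.01, 0.1, 1.0, 10.0):
            P = m.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.allclose(P, expm(m.Q * t), atol=1e-8)

    def test_empirical_frequencies_counted(self):
        msa = g.AlignmentBlock([("a", "AAA-"), ("b", "AARR")])
        m = g.load_model("LG", frequencies="empirical", alignment=msa)
        assert m.freqs[0] > m.freqs[1] > 0   # A more frequent than R


def brute_force_lnl(tree, msa, model):
    """Exhaustive sum over internal-state assignments (tiny trees only)."""
    rows = dict(msa.rows)
    code = {c: i for i, c in enumerate(model.alphabet)}
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for site in range(msa.width):
        p_site = 0.0
        for states in itertools.product(range(model.k), repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, states)}
            p = model.freqs[assign[id(tree.root)]]
            for n in tree.postorder():
                if n.parent is None:
                    continue
                parent_state = assign[id(n.parent)]
                if n.is_leaf:
                    obs = rows[n.name][site]
                    if obs in code:
                        p *= model.transition_matrix(n.length)[parent_state, code[obs]]
                else:
                    p *= model.transition_matrix(n.length)[parent_state, assign[id(n)]]
            p_site += p
        total += np.log(p_site)
    return total


class TestLikelihood:
    def test_matches_enumeration_three_taxa(self, toy3):
        msa = g.AlignmentBlock([("A", "ACDA"), ("B", "CCDA"), ("C", "AADC")])
        tree = g.read_newick("((A:0.3,B:0.4):0.2,C:0.5);")
        assert g.log_likelihood(tree, msa, toy3) == pytest.approx(
            brute_force_lnl(tree, msa, toy3), abs=1e-9)

    def test_matches_enumeration_four_taxa_with_gaps(self, toy3):
        msa = g.AlignmentBlock([("A", "AC-D"), ("B", "CCDA"),
                                ("C", "AADC"), ("D", "DDCA")])
        tree = g.read_newick("((A:0.2,B:0.6):0.15,(C:0.4,D:0.3):0.25);")
        assert g.log_likelihood(tree, msa, toy3) == pytest.approx(
            brute_force_lnl(tree, msa, toy3), abs=1e-9)

    def test_zero_branch_limit_is_frequency_product(self, toy3):
        msa = g.AlignmentBlock([("A", "ACDA"), ("B", "ACDA")])
        tree = g.read_newick(f"(A:{1e-9},B:{1e-9});")
        expect = sum(np.log(toy3.freqs[toy3.alphabet.index(c)]) for c in "ACDA")
        assert g.log_likelihood(tree, msa, toy3) == pytest.approx(expect, abs=1e-5)

    @pytest.mark.parametrize("seed", range(20))
    def test_pulley_principle(self, toy3, seed):
        """Likelihood of an unrooted tree is invariant to root placement."""
        from get3atlas.tree import root_at_edge, unroot
        rng = np.random.default_rng(seed)
        t = random_tree(int(rng.integers(4, 9)), seed=seed + 40)
        seqs = g.evolve_sequences(t, 60, toy3, seed=seed)
        msa = g.AlignmentBlock([(s.id, s.residues) for s in seqs])
        base = g.log_likelihood(t, msa, toy3)
        u = unroot(t)
        edge = u.edges()[int(rng.integers(len(u.edges())))]
        rerooted = root_at_edge(u, edge)
        assert g.log_likelihood(rerooted, msa, toy3) == pytest.approx(base, abs=1e-8)

    def test_all_gap_column_has_no_effect(self, toy3):
        tree = g.read_newick("((A:0.3,B:0.4):0.2,C:0.5);")
        msa1 = g.AlignmentBlock([("A", "ACD"), ("B", "CCD"), ("C", "AAD")])
        msa2 = g.AlignmentBlock([("A", "ACD-"), ("B", "CCD-"), ("C", "AAD-")])
        assert g.log_likelihood(tree, msa2, toy3) == pytest.approx(
            g.log_likelihood(tree, msa1, toy3), abs=1e-10)

    def test_leaf_without_row_raises(self, toy3):
        tree = g.read_newick("((A:0.3,B:0.4):0.2,C:0.5);")
        msa = g.AlignmentBlock([("A", "ACD"), ("B", "CCD")])
        with pytest.raises(ValueError, match="without alignment rows"):
            g.log_likelihood(tree, msa, toy3)

    def test_gamma_mixture_runs_and_differs(self, toy3, toy3_msa):
        tree, msa = toy3_msa
        plain = g.log_likelihood(tree, msa, toy3)
        mixed = g.log_likelihood(tree, msa, toy3, gamma_categories=4, gamma_alpha=0.5)
        assert np.isfinite(mixed) and mixed != pytest.approx(plain)


class TestNeighborJoining:
    def test_exact_recovery_from_additive_distances(self):
        true = g.read_newick(
            "(((A:0.1,B:0.2):0.15,(C:0.1,D:0.3):0.1):0.2,(E:0.2,F:0.1):0.05);")
        names = true.leaf_names()
        D = np.array([[true.path_length(a, b) if a != b else 0.0
                       for b in names] for a in names])
        nj = g.nj_start_tree(D, names)
        assert nj.bipartitions() == true.bipartitions()
        # additive distances are reproduced exactly
        for a in names:
            for b in names:
                if a < b:
                    assert nj.path_length(a, b) == pytest.approx(
                        true.path_length(a, b), abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        t = g.nj_start_tree(D, ["a", "b", "c"])
        lengths = {n.name: n.length for n in t.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_deterministic_under_ties(self):
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        t1 = g.nj_start_tree(D, ["a", "b", "c", "d"])
        t2 = g.nj_start_tree(D, ["a", "b", "c", "d"])
        assert g.write_newick(t1) == g.write_newick(t2)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            g.nj_start_tree(D, list("abc"))


class TestBranchLengths:
    def test_two_taxon_matches_grid_scan(self, toy3):
        tree = g.read_newick("(A:0.1,B:0.1);")
        seqs = g.evolve_sequences(
            g.read_newick("(A:0.25,B:0.25);"), 2000, toy3, seed=3)
        msa = g.AlignmentBlock([(s.id, s.residues) for s in seqs])
        data = SiteData.from_alignment(msa, toy3)
        tl = TreeLikelihood(tree, data, toy3)
        tl.optimize_branch_lengths(tol=1e-8)
        t_hat = sum(n.length for n in tree.root.children)
        # independent oracle: dense grid scan of the pair likelihood
        grid = np.linspace(1e-4, 3.0, 30001)
        code = {c: i for i, c in enumerate(toy3.alphabet)}
        a = np.array([code[c] for c in msa.row("A")])
        b = np.array([code[c] for c in msa.row("B")])
        C = np.zeros((3, 3))
        np.add.at(C, (a, b), 1.0)
        lnls = [np.sum(C * np.log(toy3.freqs[:, None] * toy3.transition_matrix(t)))
                for t in grid]
        assert t_hat == pytest.approx(grid[int(np.argmax(lnls))], abs=1e-3)

    def test_fixed_point_at_optimum(self, toy3, toy3_msa):
        tree, msa = toy3_msa
        data = SiteData.from_alignment(msa, toy3)
        t1 = tree.copy()
        TreeLikelihood(t1, data, toy3).optimize_branch_lengths(tol=1e-8)
        before = {tuple(sorted(t1.leaf_set(n))): n.length for n in t1.edges()}
        TreeLikelihood(t1, data, toy3).optimize_branch_lengths(tol=1e-8)
        after = {tuple(sorted(t1.leaf_set(n))): n.length for n in t1.edges()}
        for key in before:
            assert after[key] == pytest.approx(before[key], abs=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_lnl_never_decreases(self, toy3, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(int(rng.integers(4, 8)), seed=seed + 77)
        seqs = g.evolve_sequences(t, 120, toy3, seed=seed)
        msa = g.AlignmentBlock([(s.id, s.residues) for s in seqs])
        start = t.copy()
        for n in start.edges():
            n.length = float(rng.uniform(0.01, 1.0))
        data = SiteData.from_alignment(msa, toy3)
        tl = TreeLikelihood(start, data, toy3)
        before = tl.log_likelihood()
        after = tl.optimize_branch_lengths()
        assert after >= before - 1e-9


class TestNNI:
    def test_recovers_single_swap(self, toy3):
        true = g.read_newick(
            "(((A:0.15,B:0.2):0.2,(C:0.15,D:0.2):0.2):0.1,(E:0.2,F:0.15):0.1);")
        seqs = g.evolve_sequences(true, 1500, toy3, seed=9)
        msa = g.AlignmentBlock([(s.id, s.residues) for s in seqs])
        perturbed = _nni_neighbors(true.copy(), true.copy().internal_edges()[0])
        start = _nni_neighbors(true, true.internal_edges()[0])[0]
        out = g.nni_search(start, msa, toy3)
        assert out.bipartitions() == true.bipartitions()

    def test_optimal_tree_unchanged(self, toy3, toy3_msa):
        tree, msa = toy3_msa
        opt = g.optimize_branch_lengths(tree, msa, toy3)
        out = g.nni_search(opt, msa, toy3)
        assert out.bipartitions() == opt.bipartitions()


class TestBootstrap:
    def test_diagnostic_columns_full_support(self, toy3):
        # columns perfectly diagnostic for {A,B,C} vs {D,E,F}
        msa = g.AlignmentBlock([(n, ("A" if n in "ABC" else "C") * 40 +
                                 {"A": "ACD" * 7 + "A", "B": "CAD" * 7 + "C",
                                  "C": "DCA" * 7 + "D", "D": "ADC" * 7 + "A",
                                  "E": "CDA" * 7 + "C", "F": "DAC" * 7 + "D"}[n])
                                for n in "ABCDEF"])
        bt = g.bootstrap_supports(msa, toy3, replicates=25, seed=4)
        split = frozenset({"A", "B", "C"})
        anchor = min(bt.leaf_names())
        seen = False
        for n in bt.internal_edges():
            side = bt.leaf_set(n)
            if side == split or side == frozenset("DEF"):
                assert n.support == 100.0
                seen = True
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0
        assert seen

    def test_support_grows_with_alignment_length(self, toy3):
        true = g.read_newick(
            "(((A:0.3,B:0.3):0.12,C:0.4):0.05,(D:0.3,E:0.4):0.1);")
        target = frozenset({"A", "B"})

        def support_at(n_sites, seed):
            seqs = g.evolve_sequences(true, n_sites, toy3, seed=seed)
            msa = g.AlignmentBlock([(s.id, s.residues) for s in seqs])
            bt = g.bootstrap_supports(msa, toy3, replicates=50, seed=seed,
                                      tree=true.copy())
            for n in bt.internal_edges():
                side = bt.leaf_set(n)
                if side == target or side == frozenset("CDE"):
                    return n.support
            return 0.0

        assert support_at(2000, 7) >= support_at(200, 7)

    def test_replicates_validated(self, toy3, toy3_msa):
        _, msa = toy3_msa
        with pytest.raises(ValueError):
            g.bootstrap_supports(msa, toy3, replicates=0, seed=1)


class TestPlacement:
    def test_identical_leaf_query_lands_on_its_pendant_edge(self, toy3, toy3_msa):
        tree, msa = toy3_msa
        opt = g.optimize_branch_lengths(tree, msa, toy3)
        pr = g.epa_place("q", msa.row("C"), opt, msa, toy3)
        best = opt.edges()[pr.best_edge]
        assert opt.leaf_set(best) == frozenset({"C"})
        assert len(pr.edge_log_likelihoods) == len(opt.edges())
        assert pr.edge_log_likelihoods[pr.best_edge] == pr.log_likelihood

    def test_all_gap_query_rejected(self, toy3, toy3_msa):
        tree, msa = toy3_msa
        with pytest.raises(ValueError, match="all gaps"):
            g.epa_place("q", "-" * msa.width, tree, msa, toy3)


class TestDistances:
    def test_two_sequence_distance_near_truth(self, toy3):
        true = g.read_newick("(A:0.2,B:0.2);")
        seqs = g.evolve_sequences(true, 5000, toy3, seed=21)
        msa = g.AlignmentBlock([(s.id, s.residues) for s in seqs])
        D = ml_distance_matrix(SiteData.from_alignment(msa, toy3), toy3)
        assert D[0, 1] == pytest.approx(0.4, abs=0.06)
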