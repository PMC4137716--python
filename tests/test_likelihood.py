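"""Pruning likelihood, matrix exponentials, branch-length and GTR fitting."""

import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm

from kcm import (CodonAlignment, CodonFrequencies, Phylogeny, PruningEngine,
                 build_m0_Q, fit_positional_gtr, log_likelihood,
                 transition_matrix)
from kcm.likelihood import LikelihoodError, spectral_decomposition

from conftest import brute_force_loglik, random_kcm


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, code, rng):
        Q = random_kcm(rng, code)
        assert np.abs(transition_matrix(Q, 0.0) - np.eye(61)).max() < 1e-12

    def test_rows_are_distributions(self, code, rng):
        Q = random_kcm(rng, code)
        P = transition_matrix(Q, 0.37)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0

    def test_ergodic_limit_reaches_stationary(self, code, rng):
        Q = random_kcm(rng, code)
        P = transition_matrix(Q, 500.0)
        assert np.abs(P - Q.pi[None, :]).max() < 1e-6

    def test_matches_scaling_and_squaring_oracle(self, code, rng):
        Q = random_kcm(rng, code)
        P = transition_matrix(Q, 0.3)
        assert np.abs(P - scipy_expm(Q.Q * 0.3)).max() < 1e-9

    def test_negative_time_rejected(self, code, rng):
        with pytest.raises(LikelihoodError):
            transition_matrix(random_kcm(rng, code), -0.1)

    def test_chapman_kolmogorov(self, code):
        for seed in range(5):
            r = np.random.default_rng(seed)
            Q = random_kcm(r, code)
            s, t = r.uniform(0.05, 0.8, 2)
            lhs = transition_matrix(Q, s) @ transition_matrix(Q, t)
            assert np.abs(lhs - transition_matrix(Q, s + t)).max() < 1e-8

    def test_spectral_decomposition_rejects_irreversible(self):
        Q = np.array([[-1.0, 1.0], [0.5, -0.5]])
        pi = np.array([0.9, 0.1])  # wrong stationary vector: not reversible
        assert spectral_decomposition(Q, pi) is None


class TestPruningLikelihood:
    def test_two_taxon_closed_form(self, code, rng):
        Q = random_kcm(rng, code)
        c = code.sense_index["TTC"]
        t1, t2 = 0.2, 0.5
        tree = Phylogeny.from_newick(f"(a:{t1},b:{t2});")
        aln = CodonAlignment.from_sequences(["a", "b"], ["TTC", "TTC"], code=code)
        P1, P2 = transition_matrix(Q, t1), transition_matrix(Q, t2)
        expected = np.log((Q.pi * P1[:, c] * P2[:, c]).sum())
        assert log_likelihood(tree, aln, Q) == pytest.approx(expected, abs=1e-10)

    def test_zero_length_two_taxon_gives_pi(self, code, rng):
        Q = random_kcm(rng, code)
        tree = Phylogeny.from_newick("(a:0.0,b:0.0);")
        aln = CodonAlignment.from_sequences(["a", "b"], ["TTC", "TTC"], code=code)
        expected = np.log(Q.pi[code.sense_index["TTC"]])
        assert log_likelihood(tree, aln, Q) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_three_taxa(self, code, three_taxon_case):
        tree, aln = three_taxon_case
        for seed in range(3):
            Q = random_kcm(np.random.default_rng(seed), code)
            assert log_likelihood(tree, aln, Q) == pytest.approx(
                brute_force_loglik(tree, aln, Q), abs=1e-10)

    def test_matches_brute_force_four_taxa(self, code):
        tree = Phylogeny.from_newick("((a:0.1,b:0.4):0.2,(c:0.3,d:0.15):0.1);")
        aln = CodonAlignment.from_sequences(
            ["a", "b", "c", "d"],
            ["TTTAAA", "TTCAAG", "CTTAAA", "TTTGAA"], code=code)
        Q = random_kcm(np.random.default_rng(7), code)
        assert log_likelihood(tree, aln, Q) == pytest.approx(
            brute_force_loglik(tree, aln, Q), abs=1e-10)

    def test_column_duplication_doubles_loglik(self, code, three_taxon_case):
        tree, aln = three_taxon_case
        Q = random_kcm(np.random.default_rng(3), code)
        doubled = CodonAlignment(taxa=aln.taxa,
                                 codes=np.hstack([aln.codes, aln.codes]),
                                 code=code)
        assert log_likelihood(tree, doubled, Q) == pytest.approx(
            2 * log_likelihood(tree, aln, Q), abs=1e-9)

    def test_missing_codon_site_contributes_nothing(self, code, rng):
        Q = random_kcm(rng, code)
        tree = Phylogeny.from_newick("((a:0.2,b:0.3):0.1,c:0.4);")
        base = CodonAlignment.from_sequences(
            ["a", "b", "c"], ["TTT", "TTC", "CTT"], code=code)
        padded = CodonAlignment.from_sequences(
            ["a", "b", "c"], ["TTTNNN", "TTC---", "CTTNNN"], code=code)
        assert log_likelihood(tree, padded, Q) == pytest.approx(
            log_likelihood(tree, base, Q), abs=1e-9)

    def test_rerooting_invariance(self, code):
        import dendropy
        newick = "((a:0.2,b:0.35):0.15,(c:0.3,(d:0.1,e:0.25):0.2):0.05);"
        aln = CodonAlignment.from_sequences(
            list("abcde"),
            ["TTTAAAGGG", "TTCAAGGGA", "CTTAAAGGT", "TTTCAAGGG", "ATTAAAGGC"],
            code=code)
        Q = random_kcm(np.random.default_rng(11), code)
        ref = log_likelihood(Phylogeny.from_newick(newick), aln, Q)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        edges = [e for e in tree.preorder_edge_iter()
                 if e.length and e.head_node.parent_node is not None]
        rng = np.random.default_rng(0)
        for e in rng.choice(len(edges), size=5, replace=False):
            t = dendropy.Tree(tree)
            edge = [x for x in t.preorder_edge_iter()
                    if x.length and x.head_node.parent_node is not None][e]
            t.reroot_at_edge(edge, length1=edge.length / 2,
                             length2=edge.length / 2)
            assert log_likelihood(Phylogeny.from_dendropy(t), aln, Q) == \
                pytest.approx(ref, abs=1e-8)

    def test_taxon_mismatch_raises(self, code, rng):
        Q = random_kcm(rng, code)
        tree = Phylogeny.from_newick("((a:0.2,b:0.3):0.1,c:0.4);")
        aln = CodonAlignment.from_sequences(["a", "b", "x"],
                                            ["TTT", "TTC", "CTT"], code=code)
        with pytest.raises(Exception, match="mismatch"):
            log_likelihood(tree, aln, Q)


class TestBranchLengthOptimisation:
    def test_profile_sweeps_reach_a_local_optimum(self, code, rng):
        from kcm.simulate import random_tree, simulate_alignment
        tree = random_tree(8, rng=rng)
        Q = random_kcm(np.random.default_rng(5), code, equal_freqs=True)
        aln = simulate_alignment(tree, Q, 100, rng=rng)
        engine = PruningEngine(tree, aln)
        engine.set_model(Q)
        start = tree.lengths * rng.uniform(0.5, 2.0, tree.n_nodes)
        start[tree.root] = 0.0
        before = engine.loglik(start)
        opt = engine.optimize_branch_lengths(start, n_sweeps=6)
        best = engine.loglik(opt)
        assert best >= before
        # coordinate-wise perturbations cannot improve the optimum
        for v in range(tree.n_nodes):
            if tree.parent[v] < 0:
                continue
            for eps in (0.99, 1.01):
                trial = opt.copy()
                trial[v] = max(opt[v] * eps, 1e-9)
                assert engine.loglik(trial) <= best + 1e-4


class TestPositionalGTR:
    def _simulate_nucleotide_position(self, rates, pi, tree, n_sites, rng,
                                      position, code):
        """Simulate 4-state data and pack it into codon position `position`."""
        from kcm.likelihood import _gtr_Q
        Q = _gtr_Q(np.asarray(rates, dtype=float), pi)
        states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
        states[tree.root] = rng.choice(4, size=n_sites, p=pi)
        order = [tree.root]
        stack = list(tree.children[tree.root])
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(tree.children[v])
        for v in order:
            if v == tree.root:
                continue
            P = transition_matrix(Q, tree.lengths[v], pi=pi)
            cum = np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)
            u = rng.random(n_sites)
            states[v] = np.minimum((u[:, None] > cum[states[tree.parent[v]]])
                                   .sum(axis=1), 3)
        # embed: nucleotide at `position`, T elsewhere (TTT/CTT/ATT/GTT etc.
        # are all sense codons when the varying position carries the state)
        carrier = {1: "{}TT", 2: "T{}T", 3: "TT{}"}[position]
        codons = [carrier.format(n) for n in "TCAG"]
        idx = np.array([code.sense_index[c] for c in codons])
        return CodonAlignment(taxa=list(tree.taxon_labels),
                              codes=idx[states[:tree.n_taxa]], code=code)

    def test_parameter_recovery(self, code):
        from kcm.model import PAIR_ORDER
        from kcm.simulate import random_tree
        rng = np.random.default_rng(42)
        tree = random_tree(20, bl_mean=0.3, bl_sd=0.1, rng=rng)
        true = dict(zip(PAIR_ORDER, [2.0, 1.0, 1.0, 1.0, 2.0, 1.0]))
        pi = np.array([0.3, 0.25, 0.25, 0.2])
        aln = self._simulate_nucleotide_position(
            [true[p] for p in PAIR_ORDER], pi, tree, 2000, rng, 3, code)
        g = fit_positional_gtr(aln, tree, 3)
        ref = true["TG"]
        for pair in PAIR_ORDER:
            assert g.rates[pair] == pytest.approx(true[pair] / ref, rel=0.15)
        assert g.rates["TG"] == 1.0

    def test_position_out_of_range(self, code, three_taxon_case):
        tree, aln = three_taxon_case
        with pytest.raises(LikelihoodError):
            fit_positional_gtr(aln, tree, 4)

    def test_identical_sequences_warn(self, code):
        tree = Phylogeny.from_newick("((a:0.2,b:0.3):0.1,c:0.4);")
        aln = CodonAlignment.from_sequences(
            ["a", "b", "c"], ["TTTAAA"] * 3, code=code)
        g = fit_positional_gtr(aln, tree, 1)
        assert any("invariant" in w for w in g.warnings)
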