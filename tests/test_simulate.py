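"""Random trees, scheme generators, and sequence simulation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from kcm import (CodonFrequencies, Phylogeny, build_scheme_matrix,
                 multi_hit_fraction, random_tree, simulate_alignment,
                 simulate_gillespie, write_matrix)
from kcm.model import ParameterError
from kcm.simulate import SimulationScheme, lognormal_log_params

from conftest import random_kcm


class TestRandomTree:
    def test_leaf_and_branch_counts(self):
        tree = random_tree(15, seed=1)
        assert tree.n_taxa == 15
        assert int((tree.parent >= 0).sum()) == 2 * 15 - 2
        assert sorted(tree.taxon_labels) == sorted(f"t{i+1}" for i in range(15))

    def test_deterministic_newick(self):
        assert random_tree(12, seed=9).to_newick() == \
            random_tree(12, seed=9).to_newick()

    def test_too_few_taxa(self):
        with pytest.raises(ParameterError):
            random_tree(2, seed=0)

    def test_branch_length_moments(self):
        # arithmetic mean/SD of drawn lengths match the requested 0.41/0.34
        rng = np.random.default_rng(4)
        draws = np.concatenate([
            random_tree(15, rng=rng).lengths for _ in range(400)])
        draws = draws[draws > 0]
        n = draws.size
        assert abs(draws.mean() - 0.41) < 3 * 0.34 / np.sqrt(n)
        sd = draws.std()
        assert abs(sd - 0.34) < 4 * sd / np.sqrt(2 * n)

    def test_log_parameter_mode(self):
        rng = np.random.default_rng(5)
        draws = np.concatenate([
            random_tree(15, bl_mean=0.41, bl_sd=0.34, bl_params="log",
                        rng=rng).lengths for _ in range(400)])
        logs = np.log(draws[draws > 0])
        assert abs(logs.mean() - 0.41) < 3 * 0.34 / np.sqrt(logs.size)

    def test_lognormal_parameter_conversion(self):
        meanlog, sdlog = lognormal_log_params(0.41, 0.34)
        mean = np.exp(meanlog + sdlog ** 2 / 2)
        var = (np.exp(sdlog ** 2) - 1) * np.exp(2 * meanlog + sdlog ** 2)
        assert mean == pytest.approx(0.41)
        assert np.sqrt(var) == pytest.approx(0.34)


class TestSchemeMatrices:
    def test_scheme_a_has_no_multi_hit_flux(self):
        for factor in (0.1, 1.0, 10.0):
            Q = build_scheme_matrix("A", factor, seed=0)
            assert multi_hit_fraction(Q) == 0.0

    def test_scheme_b_mean_multi_hit_flux(self):
        fr = [multi_hit_fraction(build_scheme_matrix("B", 1.0, seed=s))
              for s in range(50)]
        assert np.mean(fr) == pytest.approx(0.11, abs=0.015)

    def test_scheme_ordering_b_c_d(self):
        # heavier perturbations give more multi-hit flux at matched seeds
        for s in range(5):
            fb = multi_hit_fraction(build_scheme_matrix("B", 1.0, seed=s))
            fc = multi_hit_fraction(build_scheme_matrix("C", 1.0, seed=s))
            fd = multi_hit_fraction(build_scheme_matrix("D", 1.0, seed=s))
            assert fd > fb
            assert fc > fb

    def test_generator_invariants(self, code):
        from test_model import check_generator_invariants
        for name in "ABCD":
            check_generator_invariants(build_scheme_matrix(name, 0.7, seed=3))

    def test_omega_factor_scales_nonsynonymous_single_hits(self, code):
        q1 = build_scheme_matrix("A", 1.0, seed=0)
        q2 = build_scheme_matrix("A", 2.0, seed=0)
        syn = code.synonymous_matrix
        single = code.ndiff_matrix == 1
        ratio = (q2.Q[single & ~syn] / q1.Q[single & ~syn]
                 * q2.scale_factor / q1.scale_factor)
        assert np.allclose(ratio, 2.0)

    def test_external_scheme_roundtrip(self, tmp_path, code, rng):
        Q0 = random_kcm(rng, code, equal_freqs=True, omega=1.0)
        path = tmp_path / "ext.txt"
        write_matrix(path, Q0.Q)
        sch = SimulationScheme.from_name("EXTERNAL",
                                         external_matrix_path=path)
        Q = build_scheme_matrix(sch, 1.0, freqs=CodonFrequencies.equal(),
                                code=code, seed=0)
        off = ~np.eye(61, dtype=bool)
        assert np.allclose(Q.Q[off], Q0.Q[off], atol=1e-8)

    def test_external_requires_path(self):
        with pytest.raises(ParameterError):
            SimulationScheme.from_name("EXTERNAL")

    def test_unknown_scheme(self):
        with pytest.raises(ParameterError):
            SimulationScheme.from_name("Z")


class TestSimulateAlignment:
    def test_root_distribution_on_zero_length_star(self, code, rng):
        # all-zero branch lengths: every sequence equals the root draw and
        # codon frequencies follow the stationary distribution
        parent = np.array([3, 3, 3, -1])
        tree = Phylogeny(taxon_labels=["a", "b", "c"], parent=parent,
                         lengths=np.zeros(4))
        Q = random_kcm(rng, code)
        aln = simulate_alignment(tree, Q, 50_000, rng=rng)
        assert np.array_equal(aln.codes[0], aln.codes[1])
        counts = np.bincount(aln.codes[0], minlength=61)
        _stat, p = chisquare(counts, Q.pi * 50_000)
        assert p > 0.01

    def test_long_branch_decorrelates_taxa(self, code, rng):
        tree = Phylogeny.from_newick("(a:100.0,b:100.0);")
        Q = random_kcm(rng, code, equal_freqs=True)
        aln = simulate_alignment(tree, Q, 30_000, rng=rng)
        p_same = (aln.codes[0] == aln.codes[1]).mean()
        expected = float((Q.pi ** 2).sum())
        se = np.sqrt(expected * (1 - expected) / 30_000)
        assert abs(p_same - expected) < 3 * se

    def test_byte_identical_given_seed(self, code):
        tree = random_tree(6, seed=2)
        Q = build_scheme_matrix("A", 1.0, seed=0)
        a1 = simulate_alignment(tree, Q, 60, seed=5)
        a2 = simulate_alignment(tree, Q, 60, seed=5)
        assert np.array_equal(a1.codes, a2.codes)

    def test_invalid_site_count(self, code, rng):
        tree = random_tree(4, rng=rng)
        with pytest.raises(ParameterError):
            simulate_alignment(tree, random_kcm(rng, code), 0, rng=rng)


class TestGillespie:
    def test_event_multiplicities_match_flux_expectation(self, code):
        rng = np.random.default_rng(31)
        tree = random_tree(6, rng=rng)
        Q = build_scheme_matrix("B", 1.0, seed=8)
        _aln, hits = simulate_gillespie(tree, Q, 400, rng=rng)
        total = sum(hits.values())
        frac = (hits[2] + hits[3]) / total
        expected = multi_hit_fraction(Q)
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(frac - expected) < 3 * se

    def test_agrees_with_matrix_sampling_distribution(self, code):
        # same generator, two samplers: per-branch state distributions agree
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        tree = Phylogeny.from_newick("(a:0.5,b:0.8);")
        Q = random_kcm(np.random.default_rng(3), code, equal_freqs=True)
        n = 20_000
        a1 = simulate_alignment(tree, Q, n, rng=rng1)
        a2, _ = simulate_gillespie(tree, Q, n, rng=rng2)
        p1 = (a1.codes[0] == a1.codes[1]).mean()
        p2 = (a2.codes[0] == a2.codes[1]).mean()
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(p1 - p2) < 4 * se


class TestEndToEndRecovery:
    def test_kcm19x_recovery_on_long_alignment(self, code):
        """Simulate under KCM19x with known parameters, refit, recover."""
        from kcm import NucleotideExchangeMatrix, build_kcm_Q, corrected_omega, fit
        rng = np.random.default_rng(60)
        true_omega = 0.6
        qs = [NucleotideExchangeMatrix((1.0, 0.5, 0.8, 1.5, 0.7, 2.0), position=1),
              NucleotideExchangeMatrix((2.0, 0.6, 1.2, 0.9, 0.5, 1.1), position=2),
              NucleotideExchangeMatrix((1.5, 1.0, 0.4, 1.3, 0.8, 0.6), position=3)]
        Q = build_kcm_Q(*qs, CodonFrequencies.equal(), true_omega, 1, code)
        tree = random_tree(8, rng=rng)
        aln = simulate_alignment(tree, Q, 1000, rng=rng)
        result = fit(aln, tree, "KCM19x", seed=1, n_starts=1,
                     freqs=CodonFrequencies.equal())
        assert result.omega == pytest.approx(true_omega, rel=0.25)
        # the corrected ratio of the fit should recover the corrected ratio
        # implied by the true generating parameters
        from kcm import corrected_omega_from_matrices
        target = corrected_omega_from_matrices(
            *qs, CodonFrequencies.equal(), true_omega, 1, code).omega_kcm
        fs = corrected_omega(result)
        assert fs.omega_kcm == pytest.approx(target, rel=0.2)
        # fitted positional rates correlate strongly with the truth
        fitted = np.concatenate([
            list(result.params["rates"][f"q{p+1}"].values()) for p in range(3)])
        truth = np.concatenate([qs[p].rates for p in range(3)])
        fitted /= fitted.mean()
        truth = truth / truth.mean()
        assert np.corrcoef(np.log(fitted), np.log(truth))[0, 1] > 0.9
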