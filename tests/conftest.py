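import itertools

import numpy as np
import pytest

from kcm import (CodonAlignment, CodonFrequencies, FrequencyMode,
                 NucleotideExchangeMatrix, Phylogeny, build_kcm_Q,
                 build_standard_code, transition_matrix)


@pytest.fixture(scope="session")
def code():
    return build_standard_code()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_exchange(rng, position=1, lo=0.2, hi=3.0):
    return NucleotideExchangeMatrix(tuple(rng.uniform(lo, hi, 6)),
                                    position=position)


def random_freqs(rng):
    pi = rng.dirichlet(np.full(61, 5.0))
    return CodonFrequencies(FrequencyMode.F61, pi / pi.sum())


def random_kcm(rng, code, alpha=1, omega=None, equal_freqs=False):
    qs = [random_exchange(rng, p + 1) for p in range(3)]
    freqs = CodonFrequencies.equal() if equal_freqs else random_freqs(rng)
    omega = omega if omega is not None else rng.uniform(0.2, 2.0)
    return build_kcm_Q(*qs, freqs, omega=omega, alpha=alpha, code=code)


@pytest.fixture(scope="session")
def three_taxon_case(code):
    tree = Phylogeny.from_newick("((a:0.2,b:0.35):0.15,c:0.4);")
    aln = CodonAlignment.from_sequences(
        ["a", "b", "c"], ["TTTAAAGGG", "TTCAAGGGA", "CTTAAAGGT"], code=code)
    return tree, aln


def brute_force_loglik(tree, aln, Q):
    """Exhaustive marginalisation over internal-node states (small trees)."""
    P = {v: transition_matrix(Q, tree.lengths[v]) for v in range(tree.n_nodes)}
    cols, wts = aln.patterns()
    order = tree.leaf_order(aln.taxa)
    tip = np.zeros((tree.n_taxa, cols.shape[1]), dtype=int)
    tip[order] = cols
    internal = list(tree.postorder_internal())
    n = Q.Q.shape[0]
    total = 0.0
    for p in range(cols.shape[1]):
        s = 0.0
        for assign in itertools.product(range(n), repeat=len(internal)):
            state = dict(zip(internal, assign))
            term = Q.pi[state[tree.root]]
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                child_state = state[v] if v in state else tip[v, p]
                term *= P[v][state[tree.parent[v]], child_state]
            s += term
        total += wts[p] * np.log(s)
    return total
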