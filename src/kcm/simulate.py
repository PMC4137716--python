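"""Synthetic data: random trees, scheme generators, sequence simulation.

The simulation study emulated here: 15-taxon random trees (uniform topology
by recursive random splitting, branch lengths lognormal with mean 0.41 and
SD 0.34 expected substitutions per codon), 150-codon alignments, 50
replicates per condition, and four generator schemes --

* ``A``  : the single-hit M0 generator (transition/transversion ratio
  ``base_kappa``, codon frequencies equal, omega = the scheme factor);
* ``B/C/D``: scheme A's generator augmented with one random multi-hit
  exchangeability per codon pair differing at 2-3 positions, drawn from a
  normal distribution (B: N(0.0001, 0.03); C: N(0.001, 0.1);
  D: N(0.1, 0.1)) whose magnitude (absolute value) is used as the rate --
  yielding on average roughly 11%, 30% and 39% multi-hit substitution flux;
* ``EXTERNAL``: a user-supplied 61x61/64x64 rate matrix whose nonsynonymous
  entries are multiplied by the omega factor.

The default ``base_kappa`` of 1.5 and the absolute-value rule are the pair
of choices under which the B/C/D multi-hit percentages above hold
simultaneously; see docs/methods.md for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .codons import GeneticCode, build_standard_code, is_transition
from .model import (CodonFrequencies, CodonRateMatrix, ParameterError,
                    _finalize, read_matrix)
from .trees import Phylogeny, TreeError

#: default dimensions of the replicate study
DEFAULT_N_TAXA = 15
DEFAULT_N_CODONS = 150
DEFAULT_N_REPS = 50
OMEGA_FACTORS = (0.1, 0.5, 1.0, 2.0, 10.0)


@dataclass(frozen=True)
class SimulationScheme:
    """One simulation condition: base M0 settings plus multi-hit perturbation."""

    name: str
    base_kappa: float = 1.5
    perturbation: tuple | None = None  # (mean, sd) of the normal draw
    external_matrix_path: str | None = None

    _TABLE = {
        "A": None,
        "B": (0.0001, 0.03),
        "C": (0.001, 0.1),
        "D": (0.1, 0.1),
    }

    @classmethod
    def from_name(cls, name: str, base_kappa: float = 1.5,
                  external_matrix_path=None) -> "SimulationScheme":
        name = name.upper()
        if name == "EXTERNAL":
            if external_matrix_path is None:
                raise ParameterError("EXTERNAL scheme needs a matrix path")
            return cls(name=name, base_kappa=base_kappa,
                       external_matrix_path=str(external_matrix_path))
        if name not in cls._TABLE:
            raise ParameterError(f"unknown scheme {name!r}")
        return cls(name=name, base_kappa=base_kappa,
                   perturbation=cls._TABLE[name])


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def lognormal_log_params(mean: float, sd: float) -> tuple:
    """(meanlog, sdlog) of the lognormal with arithmetic mean/SD as given."""
    if mean <= 0 or sd < 0:
        raise ParameterError("mean must be > 0 and sd >= 0")
    var_log = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - var_log / 2.0), float(np.sqrt(var_log))


def random_tree(n_taxa: int, bl_mean: float = 0.41, bl_sd: float = 0.34,
                bl_params: str = "arithmetic", seed=None,
                rng: np.random.Generator | None = None,
                labels=None) -> Phylogeny:
    """Random rooted binary tree with lognormal branch lengths.

    The topology is drawn by recursive random splitting: each clade's taxon
    set is split into a left part of uniform random size and a random
    complement.  Every one of the ``2 n - 2`` branches gets an independent
    lognormal length.  By default ``bl_mean``/``bl_sd`` are the arithmetic
    mean and SD of the branch-length distribution (in expected substitutions
    per codon); pass ``bl_params="log"`` to treat them as the lognormal's
    meanlog/sdlog instead.
    """
    if n_taxa < 3:
        raise ParameterError(f"need at least 3 taxa, got {n_taxa}")
    if bl_params == "arithmetic":
        meanlog, sdlog = lognormal_log_params(bl_mean, bl_sd)
    elif bl_params == "log":
        meanlog, sdlog = bl_mean, bl_sd
    else:
        raise ParameterError("bl_params must be 'arithmetic' or 'log'")
    rng = _as_rng(rng if rng is not None else seed)
    labels = list(labels) if labels is not None else [
        f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ParameterError("labels length must equal n_taxa")
    parent = np.full(2 * n_taxa - 1, -1, dtype=np.int64)
    next_internal = [n_taxa]

    def split(members) -> int:
        if len(members) == 1:
            return int(members[0])
        k = int(rng.integers(1, len(members)))
        perm = rng.permutation(members)
        left = split(perm[:k])
        right = split(perm[k:])
        node = next_internal[0]
        next_internal[0] += 1
        parent[left] = node
        parent[right] = node
        return node

    split(np.arange(n_taxa))
    lengths = np.zeros(2 * n_taxa - 1)
    nonroot = parent >= 0
    lengths[nonroot] = rng.lognormal(meanlog, sdlog, int(nonroot.sum()))
    return Phylogeny(taxon_labels=labels, parent=parent, lengths=lengths)


def build_scheme_matrix(scheme: SimulationScheme | str, omega_factor: float,
                        freqs: CodonFrequencies | None = None,
                        code: GeneticCode | None = None, seed=None,
                        rng: np.random.Generator | None = None,
                        scale_multi_by_omega: bool = True
                        ) -> CodonRateMatrix:
    """Generator for one simulation condition.

    Single-hit exchangeabilities are ``base_kappa`` for transitions and 1
    for transversions; every entry is multiplied by the target frequency
    and, for amino-acid-changing pairs, by ``omega_factor``.  For B/C/D one
    normal value is drawn per unordered multi-difference sense-codon pair
    and its absolute value installed symmetrically as that pair's
    exchangeability, with amino-acid-changing multi-hit entries also
    multiplied by ``omega_factor`` (disable via ``scale_multi_by_omega``).
    Finally the diagonal is fixed and the generator scaled to unit mean
    rate.  EXTERNAL loads a rate matrix from disk and multiplies its
    nonsynonymous entries by ``omega_factor``.
    """
    if isinstance(scheme, str):
        scheme = SimulationScheme.from_name(scheme)
    if omega_factor <= 0:
        raise ParameterError(f"omega factor must be > 0, got {omega_factor}")
    code = code or build_standard_code()
    freqs = freqs or CodonFrequencies.equal()
    rng = _as_rng(rng if rng is not None else seed)
    syn = code.synonymous_matrix
    ndiff = code.ndiff_matrix

    if scheme.name == "EXTERNAL":
        Q = read_matrix(scheme.external_matrix_path, code).astype(float)
        Q[~syn] *= omega_factor
        Q, scale = _finalize(Q, freqs.pi)
        return CodonRateMatrix(Q=Q, freqs=freqs, omega=omega_factor,
                               alpha=1, scale_factor=scale, code=code)

    # exchangeability matrix on the raw M0 scale (transversion = 1)
    S = np.zeros((61, 61))
    single = ndiff == 1
    for i, ci in enumerate(code.sense_order_61):
        for j in range(i + 1, 61):
            if single[i, j]:
                cj = code.sense_order_61[j]
                a, b = next((x, y) for x, y in zip(ci, cj) if x != y)
                S[i, j] = S[j, i] = scheme.base_kappa if is_transition(a, b) else 1.0
    Q = S * freqs.pi[None, :]
    Q[~syn] *= omega_factor
    if scheme.perturbation is not None:
        mean, sd = scheme.perturbation
        M = np.zeros((61, 61))
        iu = np.triu_indices(61, k=1)
        sel = ndiff[iu] > 1
        vals = np.zeros(len(iu[0]))
        vals[sel] = np.abs(rng.normal(mean, sd, int(sel.sum())))
        M[iu] = vals
        M += M.T
        if scale_multi_by_omega:
            M[~syn] *= omega_factor
        Q += M * freqs.pi[None, :]
    Q, scale = _finalize(Q, freqs.pi)
    alpha = 0 if scheme.perturbation is None else 1
    return CodonRateMatrix(Q=Q, freqs=freqs, omega=omega_factor, alpha=alpha,
                           scale_factor=scale, code=code)


def simulate_alignment(tree: Phylogeny, Q: CodonRateMatrix, n_codons: int,
                       seed=None, rng: np.random.Generator | None = None
                       ) -> CodonAlignment:
    """Evolve ``n_codons`` independent sites along the tree under ``Q``.

    The root codon of each site is drawn from the stationary distribution;
    each descendant state is drawn from the parent's row of ``P(t)``
    (transition-matrix sampling, as sequence simulators do).
    """
    if n_codons < 1:
        raise ParameterError("n_codons must be >= 1")
    rng = _as_rng(rng if rng is not None else seed)
    from .likelihood import transition_matrix
    states = np.empty((tree.n_nodes, n_codons), dtype=np.int64)
    root = tree.root
    states[root] = rng.choice(61, size=n_codons, p=Q.pi / Q.pi.sum())
    order = _preorder(tree)  # parents before children
    for v in order:
        if v == root:
            continue
        P = transition_matrix(Q, tree.lengths[v])
        P = P / P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_codons)
        parent_states = states[tree.parent[v]]
        states[v] = np.minimum(
            (u[:, None] > cum[parent_states]).sum(axis=1), 60)
    return CodonAlignment(taxa=list(tree.taxon_labels),
                          codes=states[:tree.n_taxa].copy(), code=Q.code)


def _preorder(tree: Phylogeny):
    order, stack = [], [tree.root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(tree.children[v])
    return order


def simulate_gillespie(tree: Phylogeny, Q: CodonRateMatrix, n_codons: int,
                       seed=None, rng: np.random.Generator | None = None):
    """Exact event-by-event simulation; also counts per-event hit sizes.

    Returns ``(alignment, hit_counts)`` where ``hit_counts[d]`` is the
    number of substitution events that changed ``d`` nucleotides (d = 1, 2,
    3) over the whole tree.  Used to validate that the realised multi-hit
    proportion matches the flux expectation.
    """
    if n_codons < 1:
        raise ParameterError("n_codons must be >= 1")
    rng = _as_rng(rng if rng is not None else seed)
    ndiff = Q.code.ndiff_matrix
    rates = -np.diag(Q.Q)
    jump = Q.Q / rates[:, None]
    np.fill_diagonal(jump, 0.0)
    jump_cum = np.cumsum(jump, axis=1)
    hit_counts = {1: 0, 2: 0, 3: 0}
    states = np.empty((tree.n_nodes, n_codons), dtype=np.int64)
    states[tree.root] = rng.choice(61, size=n_codons, p=Q.pi / Q.pi.sum())
    for v in _preorder(tree):
        if v == tree.root:
            continue
        t_branch = tree.lengths[v]
        cur = states[tree.parent[v]].copy()
        for site in range(n_codons):
            s, t = cur[site], 0.0
            while True:
                t += rng.exponential(1.0 / rates[s])
                if t >= t_branch:
                    break
                nxt = int(np.searchsorted(jump_cum[s], rng.random()))
                nxt = min(nxt, 60)
                hit_counts[int(ndiff[s, nxt])] += 1
                s = nxt
            cur[site] = s
        states[v] = cur
    aln = CodonAlignment(taxa=list(tree.taxon_labels),
                         codes=states[:tree.n_taxa].copy(), code=Q.code)
    return aln, hit_counts
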