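"""Construction of KCM and M0 codon rate matrices.

A KCM generator is built in four steps:

1. three symmetric 4x4 positional nucleotide matrices ``q1, q2, q3`` with
   unit diagonal (the diagonal 1s make the Kronecker entry for a codon pair
   equal the product of the positional rates at the *changed* positions
   only);
2. their Kronecker product ``q1 (x) q2 (x) q3`` restricted to the 61 sense
   codons (the Kronecker kernel);
3. right-multiplication by the diagonal matrix of codon frequencies, an
   ``omega`` multiplier on every amino-acid-changing entry, and a binary
   ``alpha`` multiplier on every entry changing more than one nucleotide;
4. the diagonal is set to minus the row sums and the matrix is rescaled so
   the mean substitution rate at equilibrium is 1 (branch lengths are then
   expected substitutions per codon, with double/triple changes counted as
   single events).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .alignment import MISSING, CodonAlignment
from .codons import NUCLEOTIDES, NUC_INDEX, GeneticCode, is_transition

#: canonical order of the six unordered nucleotide pairs
PAIR_ORDER = ("TC", "TA", "TG", "CA", "CG", "AG")
_PAIR_IDX = {frozenset(p): i for i, p in enumerate(PAIR_ORDER)}

#: indices into PAIR_ORDER of the two transitions (T<->C, A<->G)
TRANSITION_PAIRS = tuple(i for i, p in enumerate(PAIR_ORDER)
                         if is_transition(p[0], p[1]))


class ParameterError(ValueError):
    """Invalid model parameter (omega <= 0, negative rate, ...)."""


class DegenerateMatrixError(ValueError):
    """Generator with no off-diagonal mass."""


@dataclass(frozen=True)
class NucleotideExchangeMatrix:
    """Symmetric 4x4 nucleotide exchangeability matrix with unit diagonal.

    ``rates`` are the six off-diagonal exchangeabilities in
    :data:`PAIR_ORDER`; ``position`` records which codon position (1-3) the
    matrix describes.
    """

    rates: tuple
    position: int = 1

    def __post_init__(self):
        if len(self.rates) != 6:
            raise ParameterError("expected six pair rates")
        if any(r < 0 for r in self.rates):
            raise ParameterError(f"negative exchangeability in {self.rates}")
        if self.position not in (1, 2, 3):
            raise ParameterError(f"position must be 1-3, got {self.position}")

    @classmethod
    def from_dict(cls, d: dict, position: int = 1):
        return cls(tuple(d["".join(sorted(p, key=NUC_INDEX.get))] for p in PAIR_ORDER),
                   position=position)

    def rate(self, n1: str, n2: str) -> float:
        if n1 == n2:
            return 1.0
        return self.rates[_PAIR_IDX[frozenset((n1, n2))]]

    def to_matrix(self) -> np.ndarray:
        m = np.ones((4, 4))
        for (a, b), r in zip(PAIR_ORDER, self.rates):
            i, j = NUC_INDEX[a], NUC_INDEX[b]
            m[i, j] = m[j, i] = r
        return m


def m0_exchange_matrix(kappa: float, position: int = 1) -> NucleotideExchangeMatrix:
    """Positional matrix with rate ``kappa`` for transitions and 1 otherwise."""
    rates = [kappa if i in TRANSITION_PAIRS else 1.0 for i in range(6)]
    return NucleotideExchangeMatrix(tuple(rates), position=position)


class FrequencyMode(str, Enum):
    EQUAL = "EQUAL"
    F3X4 = "F3X4"
    F61 = "F61"


@dataclass
class CodonFrequencies:
    """Equilibrium codon frequencies over the 61 sense codons."""

    mode: FrequencyMode
    pi: np.ndarray
    position_freqs: np.ndarray | None = None  # 3x4, F3X4 only

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (61,):
            raise ParameterError("pi must have 61 entries")
        if np.any(self.pi <= 0):
            raise ParameterError("all codon frequencies must be > 0")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ParameterError("pi must sum to 1")

    @classmethod
    def equal(cls) -> "CodonFrequencies":
        return cls(FrequencyMode.EQUAL, np.full(61, 1.0 / 61.0))


def estimate_frequencies(aln: CodonAlignment, mode: FrequencyMode | str,
                         code: GeneticCode, pseudocount: float = 0.5
                         ) -> CodonFrequencies:
    """Empirical codon frequencies from an alignment.

    EQUAL ignores the data; F3X4 forms per-position nucleotide frequencies
    over all sequences and multiplies them, renormalising over sense codons;
    F61 uses observed sense-codon proportions, with ``pseudocount`` added to
    zero-count codons so no stationary frequency vanishes.
    """
    mode = FrequencyMode(mode)
    if mode == FrequencyMode.EQUAL:
        return CodonFrequencies.equal()
    obs = aln.codes[aln.codes != MISSING]
    if obs.size == 0:
        raise ParameterError("alignment has no unambiguous codons")
    if mode == FrequencyMode.F61:
        counts = np.bincount(obs, minlength=61).astype(float)
        counts[counts == 0] += pseudocount
        return CodonFrequencies(mode, counts / counts.sum())
    # F3X4
    nuc_idx = np.array([[NUC_INDEX[n] for n in c] for c in code.sense_order_61])
    pos_counts = np.zeros((3, 4))
    for p in range(3):
        pos_counts[p] = np.bincount(nuc_idx[obs, p], minlength=4)
    pos_counts[pos_counts == 0] += pseudocount
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = (pos_freqs[0, nuc_idx[:, 0]]
          * pos_freqs[1, nuc_idx[:, 1]]
          * pos_freqs[2, nuc_idx[:, 2]])
    return CodonFrequencies(mode, pi / pi.sum(), position_freqs=pos_freqs)


@dataclass
class CodonRateMatrix:
    """A 61x61 codon generator with its frequencies and scaling metadata.

    Invariants (tested): zero row sums, nonnegative off-diagonal, unit mean
    rate ``-sum_i pi_i Q_ii = 1``, and detailed balance
    ``pi_i Q_ij = pi_j Q_ji`` (the kernel is symmetric and frequencies enter
    by right multiplication, so the chain is time reversible).
    """

    Q: np.ndarray
    freqs: CodonFrequencies
    omega: float
    alpha: int
    scale_factor: float
    code: GeneticCode = field(repr=False, default=None)

    @property
    def pi(self) -> np.ndarray:
        return self.freqs.pi


def kronecker_kernel(q1: NucleotideExchangeMatrix,
                     q2: NucleotideExchangeMatrix,
                     q3: NucleotideExchangeMatrix,
                     code: GeneticCode) -> np.ndarray:
    """Kronecker product of the three positional matrices on sense codons.

    Returns the symmetric 61x61 kernel: the entry for a codon pair is the
    product of the positional exchangeabilities at each position where the
    codons differ (unit diagonals contribute identity factors at unchanged
    positions).
    """
    k64 = np.kron(q1.to_matrix(), np.kron(q2.to_matrix(), q3.to_matrix()))
    s = code.sense_indices_64
    return k64[np.ix_(s, s)]


def _finalize(Q: np.ndarray, pi: np.ndarray):
    """Zero diagonal -> minus row sums -> unit mean rate; returns (Q, scale)."""
    np.fill_diagonal(Q, 0.0)
    rowsum = Q.sum(axis=1)
    mean_rate = float(pi @ rowsum)
    if mean_rate <= 0:
        raise DegenerateMatrixError("generator has no off-diagonal mass")
    Q /= mean_rate
    np.fill_diagonal(Q, -Q.sum(axis=1) + np.diag(Q))
    return Q, mean_rate


def build_kcm_Q(q1, q2, q3, freqs: CodonFrequencies, omega: float, alpha: int,
                code: GeneticCode) -> CodonRateMatrix:
    """Full KCM generator from positional matrices, frequencies, omega, alpha."""
    if omega <= 0:
        raise ParameterError(f"omega must be > 0, got {omega}")
    if alpha not in (0, 1):
        raise ParameterError(f"alpha must be 0 or 1, got {alpha}")
    K = kronecker_kernel(q1, q2, q3, code)
    Q = K * freqs.pi[None, :]
    syn = code.synonymous_matrix
    Q[~syn] *= omega
    if alpha == 0:
        Q[code.ndiff_matrix > 1] = 0.0
    Q, scale = _finalize(Q, freqs.pi)
    return CodonRateMatrix(Q=Q, freqs=freqs, omega=omega, alpha=alpha,
                           scale_factor=scale, code=code)


def build_m0_Q(kappa: float, omega: float, freqs: CodonFrequencies,
               code: GeneticCode) -> CodonRateMatrix:
    """Goldman-Yang M0 generator: single-hit, kappa for transitions.

    Identical to the KCM construction with ``alpha = 0`` and every
    positional matrix equal to the transition/transversion matrix.
    """
    if kappa <= 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    q = m0_exchange_matrix(kappa)
    qm = build_kcm_Q(q, q, q, freqs, omega, alpha=0, code=code)
    return CodonRateMatrix(Q=qm.Q, freqs=freqs, omega=omega, alpha=0,
                           scale_factor=qm.scale_factor, code=code)


def multi_hit_fraction(Q: CodonRateMatrix) -> float:
    """Expected fraction of substitution events changing >1 nucleotide.

    Flux-weighted: ``sum_{diff>1} pi_i Q_ij / sum_{i != j} pi_i Q_ij``;
    invariant under global rescaling of the generator.
    """
    code = Q.code
    flux = Q.pi[:, None] * Q.Q
    off = ~np.eye(61, dtype=bool)
    multi = code.ndiff_matrix > 1
    total = flux[off].sum()
    return float(flux[multi & off].sum() / total)


# ---------------------------------------------------------------------------
# text import/export of rate matrices

def write_matrix(path, M: np.ndarray, ordering: str = "sense61") -> None:
    """Whitespace-delimited matrix with a one-line ordering header.

    ``ordering`` is ``"sense61"`` (TCAG order, stops removed) or ``"full64"``.
    """
    expected = {"sense61": 61, "full64": 64}[ordering]
    if M.shape != (expected, expected):
        raise ParameterError(f"{ordering} matrix must be {expected}x{expected}")
    header = (f"# codon rate matrix, ordering={ordering} "
              "(lexicographic T,C,A,G; third position fastest)")
    np.savetxt(path, M, header=header.lstrip("# "), fmt="%.10g")


def read_matrix(path, code: GeneticCode) -> np.ndarray:
    """Read a 61x61 or 64x64 whitespace-delimited matrix; returns 61x61.

    A 64x64 input has its stop rows/columns deleted.
    """
    M = np.loadtxt(path)
    if M.shape == (64, 64):
        s = code.sense_indices_64
        M = M[np.ix_(s, s)]
    elif M.shape != (61, 61):
        raise ParameterError(
            f"matrix must be 61x61 or 64x64, got {M.shape} from {path}")
    return M
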