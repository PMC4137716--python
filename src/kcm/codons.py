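"""Codon state space: canonical ordering, translation, substitution classes.

The codon ordering used throughout the package is lexicographic over the
nucleotide order T, C, A, G with the third codon position varying fastest
(TTT, TTC, TTA, TTG, TCT, ... GGG).  This ordering makes the Kronecker
product of three 4x4 positional matrices land directly in codon order, so
the 61-state generator is obtained by simply deleting the three stop rows
and columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Nucleotide order used for all positional matrices and codon indexing.
NUCLEOTIDES = "TCAG"

NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: Standard (universal) genetic code, keyed by codon in TCAG order.
STANDARD_CODE_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class CodonError(ValueError):
    """Malformed codon or codon outside the sense-codon domain."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code over the canonical 64-codon ordering.

    Attributes
    ----------
    codon_order_64 : tuple of str
        All 64 trinucleotides in TCAG order, third position fastest.
    sense_order_61 : tuple of str
        The sense codons (order preserved from ``codon_order_64``).
    aa_of : dict
        Codon -> one-letter amino acid ('*' for stop).
    stop_set : frozenset
        The stop codons.
    """

    codon_order_64: tuple
    sense_order_61: tuple
    aa_of: dict
    stop_set: frozenset
    #: index of each sense codon within codon_order_64
    sense_indices_64: np.ndarray = field(repr=False, default=None)
    #: codon string -> index in sense_order_61
    sense_index: dict = field(repr=False, default=None)

    @property
    def n_sense(self) -> int:
        return len(self.sense_order_61)

    def translate(self, codon: str) -> str:
        try:
            return self.aa_of[codon]
        except KeyError:
            raise CodonError(f"not a codon: {codon!r}") from None

    # ---- vectorised classification tables -------------------------------
    @property
    def ndiff_matrix(self) -> np.ndarray:
        """61x61 integer matrix of pairwise nucleotide differences."""
        return _ndiff_matrix(self.sense_order_61)

    @property
    def synonymous_matrix(self) -> np.ndarray:
        """61x61 boolean matrix: True where the two codons encode the same aa."""
        aas = np.array([self.aa_of[c] for c in self.sense_order_61])
        return aas[:, None] == aas[None, :]


@lru_cache(maxsize=None)
def _ndiff_matrix(sense_order):
    arr = np.array([[NUC_INDEX[n] for n in c] for c in sense_order])
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def build_standard_code(table: dict | None = None) -> GeneticCode:
    """Build the standard genetic code (or one from a custom codon->aa table).

    Custom tables must cover all 64 codons; stops are the codons mapping
    to ``'*'``.
    """
    table = dict(STANDARD_CODE_TABLE if table is None else table)
    order64 = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    missing = set(order64) - set(table)
    if missing:
        raise CodonError(f"code table missing codons: {sorted(missing)}")
    stops = frozenset(c for c in order64 if table[c] == "*")
    sense = tuple(c for c in order64 if c not in stops)
    sense_idx64 = np.array([order64.index(c) for c in sense])
    return GeneticCode(
        codon_order_64=order64,
        sense_order_61=sense,
        aa_of=table,
        stop_set=stops,
        sense_indices_64=sense_idx64,
        sense_index={c: i for i, c in enumerate(sense)},
    )


def _check_codon(c: str) -> None:
    if len(c) != 3 or any(n not in NUC_INDEX for n in c):
        raise CodonError(f"malformed codon: {c!r}")


def num_differences(c1: str, c2: str) -> int:
    """Number of codon positions (0-3) at which two codons differ."""
    _check_codon(c1)
    _check_codon(c2)
    return sum(a != b for a, b in zip(c1, c2))


def is_synonymous(c1: str, c2: str, code: GeneticCode) -> bool:
    """True iff two *sense* codons encode the same amino acid."""
    for c in (c1, c2):
        _check_codon(c)
        if c in code.stop_set:
            raise CodonError(f"stop codon outside sense domain: {c}")
    return code.aa_of[c1] == code.aa_of[c2]


def is_transition(n1: str, n2: str) -> bool:
    """True for the purine-purine / pyrimidine-pyrimidine changes T<->C, A<->G."""
    return {n1, n2} in ({"T", "C"}, {"A", "G"})
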