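"""In-memory codon alignment with site-pattern compression."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codons import GeneticCode, build_standard_code

#: sentinel for a missing / ambiguous codon
MISSING = -1


class AlignmentError(ValueError):
    """Invalid alignment content (frame, stop codons, duplicate taxa...)."""


@dataclass
class CodonAlignment:
    """Codon-aligned sequences encoded as sense-codon indices.

    ``codes`` is an ``(n_taxa, n_sites)`` integer array holding indices into
    ``code.sense_order_61``; :data:`MISSING` marks gaps or ambiguous codons,
    which contribute a flat partial likelihood.
    """

    taxa: list
    codes: np.ndarray
    code: GeneticCode = field(default_factory=build_standard_code)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise AlignmentError("codes must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        self._patterns = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def patterns(self):
        """Unique site columns and their multiplicities.

        Returns ``(cols, weights)`` where ``cols`` is ``(n_taxa, n_patterns)``
        and ``weights`` sums to ``n_sites``.
        """
        if self._patterns is None:
            cols, counts = np.unique(self.codes, axis=1, return_counts=True)
            self._patterns = (cols, counts.astype(float))
        return self._patterns

    @classmethod
    def from_sequences(cls, taxa, seqs, code: GeneticCode | None = None,
                       source: str = "<memory>"):
        """Build from nucleotide strings (uppercased, U -> T).

        Raises :class:`AlignmentError` for length not divisible by 3, unequal
        lengths, duplicate taxa, or in-frame stop codons (reported with the
        taxon and 1-based codon site).  Codons containing characters outside
        T/C/A/G (gaps, N, ...) become :data:`MISSING`.
        """
        code = code or build_standard_code()
        seqs = [s.upper().replace("U", "T") for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"{source}: sequences have unequal lengths {sorted(lengths)}")
        (length,) = lengths or {0}
        if length % 3:
            raise AlignmentError(
                f"{source}: alignment length {length} is not divisible by 3")
        n_sites = length // 3
        codes = np.full((len(taxa), n_sites), MISSING, dtype=np.int64)
        for ti, (taxon, seq) in enumerate(zip(taxa, seqs)):
            for si in range(n_sites):
                codon = seq[3 * si: 3 * si + 3]
                if codon in code.stop_set:
                    raise AlignmentError(
                        f"{source}: in-frame stop codon {codon} in sequence "
                        f"{taxon!r} at codon site {si + 1}")
                idx = code.sense_index.get(codon)
                if idx is not None:
                    codes[ti, si] = idx
        return cls(taxa=list(taxa), codes=codes, code=code)

    def to_sequences(self) -> dict:
        """Codon index rows back to nucleotide strings (missing -> NNN)."""
        out = {}
        for taxon, row in zip(self.taxa, self.codes):
            out[taxon] = "".join(
                self.code.sense_order_61[c] if c >= 0 else "NNN" for c in row)
        return out
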