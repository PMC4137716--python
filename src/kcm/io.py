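"""Alignment/tree/results input-output.

FASTA and PHYLIP parsing is delegated to Biopython; trees go through
dendropy (see :mod:`kcm.trees`).  Fit results and study tables serialise to
JSON/TSV with enough provenance (seed, package version, configuration) to
re-run them exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from . import __version__
from .alignment import AlignmentError, CodonAlignment
from .codons import GeneticCode
from .inference import FitResult, ModelSpec, aicc
from .model import CodonFrequencies, FrequencyMode


def read_alignment(path, fmt: str | None = None,
                   code: GeneticCode | None = None) -> CodonAlignment:
    """Read a codon alignment from FASTA or PHYLIP.

    ``fmt`` is ``"fasta"``, ``"phylip"`` (interleaved), or
    ``"phylip-sequential"``; when omitted it is guessed from the first
    character of the file ('>' means FASTA) with both PHYLIP layouts tried
    otherwise.  Sequences are uppercased, U becomes T, and in-frame stop
    codons are rejected with sequence and 1-based codon-site coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"no such alignment file: {path}")
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fasta" if first == ">" else "phylip"
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"{path}: no FASTA records found")
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    else:
        records = None
        tried = (["phylip-relaxed", "phylip-sequential"] if fmt == "phylip"
                 else ["phylip-sequential"])
        errors = []
        for schema in tried:
            try:
                msa = AlignIO.read(str(path), schema)
                records = [(r.id, str(r.seq)) for r in msa]
                break
            except ValueError as exc:
                errors.append(f"{schema}: {exc}")
        if records is None:
            raise AlignmentError(f"{path}: could not parse PHYLIP ({errors})")
        taxa = [r[0] for r in records]
        seqs = [r[1] for r in records]
    return CodonAlignment.from_sequences(taxa, seqs, code=code,
                                         source=str(path))


def write_alignment(aln: CodonAlignment, path, fmt: str = "fasta") -> None:
    seqs = aln.to_sequences()
    with open(path, "w") as fh:
        if fmt == "fasta":
            for taxon in aln.taxa:
                fh.write(f">{taxon}\n{seqs[taxon]}\n")
        elif fmt in ("phylip", "phylip-sequential"):
            fh.write(f" {aln.n_taxa} {aln.n_sites * 3}\n")
            for taxon in aln.taxa:
                fh.write(f"{taxon[:10]:<10}  {seqs[taxon]}\n")
        else:
            raise AlignmentError(f"unknown alignment format {fmt!r}")


# ---------------------------------------------------------------------------
# fit-result JSON


def fit_result_to_dict(fit: FitResult, config: dict | None = None) -> dict:
    return {
        "package_version": __version__,
        "model": fit.spec.name,
        "freq_mode": fit.spec.freq_mode.value,
        "k_free": fit.spec.k_free,
        "lnL": fit.lnL,
        "aicc": fit.aicc,
        "n_sites": fit.n_sites,
        "params": fit.params,
        "branch_lengths": [float(x) for x in fit.branch_lengths],
        "frequencies": [float(x) for x in fit.freqs.pi],
        "converged": fit.converged,
        "n_evals": fit.n_evals,
        "seed": fit.seed,
        "data_hash": fit.data_hash,
        "warnings": list(fit.warnings),
        "config": config or {},
    }


def write_fit_result(fit: FitResult, path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(fit, config), fh, indent=2)
        fh.write("\n")


def read_fit_result(path) -> FitResult:
    """Reload a fit-result JSON; AICc is recomputed and checked."""
    with open(path) as fh:
        d = json.load(fh)
    spec = ModelSpec.from_name(d["model"], d["freq_mode"])
    freqs = CodonFrequencies(FrequencyMode(d["freq_mode"]),
                             np.asarray(d["frequencies"]))
    fit = FitResult(
        spec=spec, lnL=d["lnL"], params=d["params"],
        branch_lengths=np.asarray(d["branch_lengths"]),
        aicc=d["aicc"], n_sites=d["n_sites"], converged=d["converged"],
        n_evals=d["n_evals"], seed=d["seed"], freqs=freqs,
        data_hash=d["data_hash"], warnings=d.get("warnings", []))
    expected = aicc(fit.lnL, spec.k_free, fit.n_sites)
    if abs(expected - fit.aicc) > 1e-6:
        raise AlignmentError(
            f"{path}: stored AICc {fit.aicc} inconsistent with lnL/k/n "
            f"(recomputed {expected})")
    return fit
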