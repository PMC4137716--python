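"""Maximum-likelihood fitting of KCM variants and M0, AICc model comparison,
and the replicate simulation-study harness.

Model variants
--------------
======================  =====  ================  ======  ==============
name                    alpha  positional tying  omega   free params k
======================  =====  ================  ======  ==============
M0                      0      kappa only        free    2
KCM7x                   1      q1 = q2 = q3      free    7
KCM7xM0                 0      q1 = q2 = q3      free    7
KCM19x                  1      free              free    19
KCM19xM0                0      free              free    19
KCM19x_neutral          1      free              1       18
======================  =====  ================  ======  ==============

Codon frequency parameters are held out of ``k``: they are estimated the
same way for every model compared within a frequency mode, so they cancel
in AICc differences.
"""

from __future__ import annotations

import hashlib
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .codons import GeneticCode, build_standard_code
from .likelihood import LikelihoodError, PruningEngine
from .model import (PAIR_ORDER, CodonFrequencies, CodonRateMatrix,
                    FrequencyMode, NucleotideExchangeMatrix, ParameterError,
                    build_kcm_Q, build_m0_Q, estimate_frequencies,
                    m0_exchange_matrix)
from .trees import Phylogeny

#: optimisation bounds on the natural-parameter scale
RATE_BOUNDS = (1e-8, 1e3)
OMEGA_BOUNDS = (1e-6, 1e3)

_VARIANTS = {
    "M0": dict(alpha=0, tie_positions=True, omega_fixed=None, k_free=2),
    "KCM7x": dict(alpha=1, tie_positions=True, omega_fixed=None, k_free=7),
    "KCM7xM0": dict(alpha=0, tie_positions=True, omega_fixed=None, k_free=7),
    "KCM19x": dict(alpha=1, tie_positions=False, omega_fixed=None, k_free=19),
    "KCM19xM0": dict(alpha=0, tie_positions=False, omega_fixed=None, k_free=19),
    "KCM19x_neutral": dict(alpha=1, tie_positions=False, omega_fixed=1.0,
                           k_free=18),
}


@dataclass(frozen=True)
class ModelSpec:
    """Identity and parameter tying of one model variant."""

    name: str
    alpha: int
    tie_positions: bool
    omega_fixed: float | None
    k_free: int
    freq_mode: FrequencyMode = FrequencyMode.F3X4

    @classmethod
    def from_name(cls, name: str,
                  freq_mode: FrequencyMode | str = FrequencyMode.F3X4):
        if name not in _VARIANTS:
            raise ParameterError(
                f"unknown model {name!r}; choose from {sorted(_VARIANTS)}")
        return cls(name=name, freq_mode=FrequencyMode(freq_mode),
                   **_VARIANTS[name])

    @property
    def is_m0(self) -> bool:
        return self.name == "M0"


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    lnL: float
    params: dict
    branch_lengths: np.ndarray
    aicc: float
    n_sites: int
    converged: bool
    n_evals: int
    seed: int | None
    freqs: CodonFrequencies
    data_hash: str
    code: GeneticCode = field(repr=False, default_factory=build_standard_code)
    warnings: list = field(default_factory=list)

    @property
    def omega(self) -> float:
        return self.params["omega"]

    def exchange_matrices(self):
        """The three fitted positional matrices (tied variants repeat q1)."""
        if self.spec.is_m0:
            q = m0_exchange_matrix(self.params["kappa"])
            return q, q, q
        rates = self.params["rates"]
        qs = []
        for p in (1, 2, 3):
            key = f"q{p}" if f"q{p}" in rates else "q1"
            qs.append(NucleotideExchangeMatrix(
                tuple(rates[key][pair] for pair in PAIR_ORDER), position=p))
        return tuple(qs)

    def freqs_pi_code(self) -> GeneticCode:
        return self.code

    def rate_matrix(self) -> CodonRateMatrix:
        """Rebuild the fitted generator."""
        if self.spec.is_m0:
            return build_m0_Q(self.params["kappa"], self.omega, self.freqs,
                              self.code)
        q1, q2, q3 = self.exchange_matrices()
        return build_kcm_Q(q1, q2, q3, self.freqs, self.omega,
                           self.spec.alpha, self.code)


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ParameterError(f"AICc needs n > k+1 (n={n}, k={k})")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def delta_aicc(fit_ref: FitResult, fit_alt: FitResult) -> float:
    """AICc(ref) - AICc(alt); positive favours the alternative model."""
    if fit_ref.data_hash != fit_alt.data_hash:
        raise ParameterError("fits were made on different data sets")
    return fit_ref.aicc - fit_alt.aicc


def _alignment_hash(aln: CodonAlignment) -> str:
    h = hashlib.sha1()
    h.update("\x00".join(aln.taxa).encode())
    h.update(aln.codes.tobytes())
    return h.hexdigest()


class _Objective:
    """Maps the free log-parameter vector of a variant to -lnL."""

    def __init__(self, spec: ModelSpec, engine: PruningEngine,
                 freqs: CodonFrequencies, code: GeneticCode):
        self.spec, self.engine, self.freqs, self.code = spec, engine, freqs, code
        self.n_evals = 0
        if spec.is_m0:
            self.n_rates = 1  # kappa
        else:
            self.n_rates = 6 if spec.tie_positions else 18
        self.free_omega = spec.omega_fixed is None
        lo = [np.log(RATE_BOUNDS[0])] * self.n_rates
        hi = [np.log(RATE_BOUNDS[1])] * self.n_rates
        if self.free_omega:
            lo.append(np.log(OMEGA_BOUNDS[0]))
            hi.append(np.log(OMEGA_BOUNDS[1]))
        self.bounds = list(zip(lo, hi))

    @property
    def n_params(self) -> int:
        return self.n_rates + int(self.free_omega)

    def start(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Unit-rate start (kappa = 2, omega = 1), lognormal-perturbed if rng."""
        theta = np.zeros(self.n_params)
        if self.spec.is_m0:
            theta[0] = np.log(2.0)
        if rng is not None:
            theta = theta + rng.normal(0.0, 0.3, size=theta.shape)
        return theta

    def build_Q(self, theta: np.ndarray) -> CodonRateMatrix:
        omega = (np.exp(theta[-1]) if self.free_omega
                 else float(self.spec.omega_fixed))
        if self.spec.is_m0:
            return build_m0_Q(np.exp(theta[0]), omega, self.freqs, self.code)
        rates = np.exp(theta[:self.n_rates])
        if self.spec.tie_positions:
            q = NucleotideExchangeMatrix(tuple(rates))
            q1 = q2 = q3 = q
        else:
            q1, q2, q3 = (NucleotideExchangeMatrix(tuple(rates[6 * p:6 * p + 6]),
                                                   position=p + 1)
                          for p in range(3))
        return build_kcm_Q(q1, q2, q3, self.freqs, omega, self.spec.alpha,
                           self.code)

    def __call__(self, theta: np.ndarray, lengths: np.ndarray) -> float:
        self.n_evals += 1
        try:
            self.engine.set_model(self.build_Q(theta))
            return -self.engine.loglik(lengths)
        except (LikelihoodError, ParameterError, FloatingPointError):
            return 1e12

    def params_dict(self, theta: np.ndarray) -> dict:
        omega = (np.exp(theta[-1]) if self.free_omega
                 else float(self.spec.omega_fixed))
        out = {"omega": float(omega)}
        if self.spec.is_m0:
            out["kappa"] = float(np.exp(theta[0]))
        else:
            rates = np.exp(theta[:self.n_rates])
            if self.spec.tie_positions:
                out["rates"] = {"q1": dict(zip(PAIR_ORDER, map(float, rates)))}
            else:
                out["rates"] = {
                    f"q{p + 1}": dict(zip(PAIR_ORDER,
                                          map(float, rates[6 * p:6 * p + 6])))
                    for p in range(3)}
        return out


def fit(aln: CodonAlignment, tree: Phylogeny, spec: ModelSpec | str,
        optimize_branch_lengths: bool = True, seed: int | None = None,
        freqs: CodonFrequencies | None = None, n_starts: int = 3,
        max_rounds: int = 8, round_tol: float = 1e-4,
        max_iter: int = 500) -> FitResult:
    """Maximum-likelihood fit of one model variant on a fixed topology.

    Free rates and omega are optimised on the log scale with bounded
    L-BFGS-B, alternating with coordinate-wise branch-length sweeps until
    the likelihood gain per round drops below ``round_tol``.  ``n_starts``
    controls multi-start (first start is the unit-rate point, the rest are
    lognormal sigma=0.3 perturbations drawn from ``seed``); the best start
    is returned.  Non-convergence yields ``converged=False`` plus a warning
    rather than an exception.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    code = aln.code
    if freqs is None:
        freqs = estimate_frequencies(aln, spec.freq_mode, code)
    engine = PruningEngine(tree, aln)
    obj = _Objective(spec, engine, freqs, code)
    rng = np.random.default_rng(seed)
    notes: list = []

    best = None
    for s in range(max(1, n_starts)):
        theta = obj.start(rng if s > 0 else None)
        lengths = tree.lengths.copy()
        prev = -obj(theta, lengths)
        converged = False
        for _round in range(max_rounds):
            res = minimize(obj, theta, args=(lengths,), method="L-BFGS-B",
                           bounds=obj.bounds,
                           options={"maxiter": max_iter, "ftol": 1e-10,
                                    "gtol": 1e-7, "eps": 1e-6})
            theta = res.x
            cur = -res.fun
            if optimize_branch_lengths:
                engine.set_model(obj.build_Q(theta))
                lengths = engine.optimize_branch_lengths(lengths, n_sweeps=3)
                cur = -obj(theta, lengths)
            if cur - prev < round_tol:
                converged = True
                prev = max(cur, prev)
                break
            prev = cur
        if best is None or prev > best[0]:
            best = (prev, theta.copy(), lengths.copy(), converged)

    lnL, theta, lengths, converged = best
    if not converged:
        notes.append("optimizer did not converge within max_rounds")
        _warnings.warn(f"{spec.name} fit did not converge", RuntimeWarning)
    result = FitResult(
        spec=spec, lnL=float(lnL), params=obj.params_dict(theta),
        branch_lengths=lengths, aicc=aicc(lnL, spec.k_free, aln.n_sites),
        n_sites=aln.n_sites, converged=converged, n_evals=obj.n_evals,
        seed=seed, freqs=freqs, data_hash=_alignment_hash(aln), code=code,
        warnings=notes)
    return result


# ---------------------------------------------------------------------------
# replicate simulation study


def replicate_study(scheme, factor: float, n_reps: int, n_taxa: int,
                    n_codons: int, models, freq_mode=FrequencyMode.F3X4,
                    seed: int | None = None, n_starts: int = 1,
                    bl_mean: float = 0.41, bl_sd: float = 0.34,
                    bl_params: str = "arithmetic",
                    max_failure_fraction: float = 0.2) -> pd.DataFrame:
    """Simulate-and-refit replicates; the machine analogue of a results table.

    Each replicate draws a random tree, builds the scheme generator,
    simulates an alignment, and fits every requested model; per-replicate
    rows record lnL, AICc, fitted omega, corrected omega (for KCM variants)
    and, when M0 is among the models, AICc(M0) - AICc(model).  Replicate
    failures are recorded (column ``error``) rather than fatal unless they
    exceed ``max_failure_fraction``.  Fully reproducible from ``seed``.
    """
    from .omega import corrected_omega
    from .simulate import (SimulationScheme, build_scheme_matrix, random_tree,
                           simulate_alignment)
    if isinstance(scheme, str):
        scheme = SimulationScheme.from_name(scheme)
    model_specs = [ModelSpec.from_name(m, freq_mode) if isinstance(m, str)
                   else m for m in models]
    ss = np.random.SeedSequence(seed)
    rows, failures = [], 0
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        try:
            tree = random_tree(n_taxa, bl_mean=bl_mean, bl_sd=bl_sd,
                               bl_params=bl_params, rng=rng)
            Qsim = build_scheme_matrix(scheme, factor, rng=rng)
            aln = simulate_alignment(tree, Qsim, n_codons, rng=rng)
            fits = {}
            for mspec in model_specs:
                fits[mspec.name] = fit(
                    aln, tree, mspec, seed=int(rng.integers(2 ** 31)),
                    n_starts=n_starts)
            for name, fr in fits.items():
                row = dict(scheme=scheme.name, factor=factor, rep=rep,
                           model=name, lnL=fr.lnL, k=fr.spec.k_free,
                           n=fr.n_sites, aicc=fr.aicc, omega=fr.omega,
                           converged=fr.converged, error=None)
                if name != "M0" and not fr.spec.is_m0:
                    try:
                        row["omega_corrected"] = corrected_omega(fr).omega_kcm
                    except Exception:
                        row["omega_corrected"] = np.nan
                else:
                    row["omega_corrected"] = np.nan
                if "M0" in fits and name != "M0":
                    row["delta_aicc"] = delta_aicc(fits["M0"], fr)
                else:
                    row["delta_aicc"] = np.nan
                rows.append(row)
        except Exception as exc:  # per-replicate failure: record, keep going
            failures += 1
            rows.append(dict(scheme=scheme.name, factor=factor, rep=rep,
                             model=None, lnL=np.nan, k=0, n=n_codons,
                             aicc=np.nan, omega=np.nan,
                             omega_corrected=np.nan, delta_aicc=np.nan,
                             converged=False, error=str(exc)))
    if n_reps and failures / n_reps > max_failure_fraction:
        raise RuntimeError(
            f"{failures}/{n_reps} replicates failed; last errors: "
            f"{[r['error'] for r in rows if r['error']][-3:]}")
    return pd.DataFrame(rows)


def summarize_study(records: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean (SD) of fitted omega, corrected omega and delta AICc."""
    ok = records[records["model"].notna()]
    return (ok.groupby(["scheme", "factor", "model"])
              .agg(n_reps=("rep", "count"),
                   omega_mean=("omega", "mean"), omega_sd=("omega", "std"),
                   omega_corr_mean=("omega_corrected", "mean"),
                   omega_corr_sd=("omega_corrected", "std"),
                   delta_aicc_mean=("delta_aicc", "mean"),
                   delta_aicc_sd=("delta_aicc", "std"))
              .reset_index())
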