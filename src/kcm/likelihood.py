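"""Felsenstein pruning likelihood, generic over state space.

The same engine serves the 61-state codon models and 4-state positional GTR
fits.  All generators built by this package satisfy detailed balance
``pi_i Q_ij = pi_j Q_ji``, so ``S = diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is
symmetric and one eigendecomposition yields ``P(t) = A exp(wt) B`` for every
branch; a scaling-and-squaring fallback covers numerically asymmetric input.

Per-node rescaling of partial likelihoods (threshold 1e-80) keeps site
likelihoods finite on long trees; gaps and ambiguous codons contribute a
flat partial likelihood of one over all states.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm as _expm
from scipy.optimize import minimize_scalar

from .alignment import MISSING, CodonAlignment
from .model import CodonRateMatrix
from .trees import Phylogeny

_RESCALE_THRESHOLD = 1e-80
#: branch-length search interval (expected substitutions per codon)
BRANCH_BOUNDS = (1e-8, 50.0)


class LikelihoodError(ArithmeticError):
    """Non-finite likelihood or invalid engine input."""


def spectral_decomposition(Q: np.ndarray, pi: np.ndarray, atol: float = 1e-8):
    """Factor a reversible generator: returns (w, A, B) with P(t) = A e^{wt} B.

    Returns None when the similarity transform is not symmetric to ``atol``
    (caller should fall back to scaling-and-squaring).
    """
    sqrt_pi = np.sqrt(pi)
    S = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    if not np.allclose(S, S.T, atol=atol):
        return None
    w, U = np.linalg.eigh((S + S.T) / 2.0)
    A = U / sqrt_pi[:, None]
    B = U.T * sqrt_pi[None, :]
    return w, A, B


def transition_matrix(Q: CodonRateMatrix | np.ndarray, t: float,
                      pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, small negative round-off clamped to 0."""
    if t < 0:
        raise LikelihoodError(f"branch length must be >= 0, got {t}")
    if isinstance(Q, CodonRateMatrix):
        pi = Q.pi
        Q = Q.Q
    spec = spectral_decomposition(Q, pi) if pi is not None else None
    if spec is None:
        P = _expm(Q * t)
    else:
        w, A, B = spec
        P = (A * np.exp(w * t)[None, :]) @ B
    return np.clip(P, 0.0, None)


class PruningEngine:
    """Pruning likelihood for one (tree, alignment) pair over site patterns.

    The engine caches the pattern compression and tree layout; the model
    (``set_model``) and branch lengths can be swapped cheaply, which is what
    the optimiser exploits.
    """

    def __init__(self, tree: Phylogeny, aln: CodonAlignment | None = None,
                 tipcodes: np.ndarray | None = None,
                 weights: np.ndarray | None = None, n_states: int = 61):
        self.tree = tree
        self.n_states = n_states
        if aln is not None:
            cols, weights = aln.patterns()
            order = tree.leaf_order(aln.taxa)
            tipcodes = np.full((tree.n_taxa, cols.shape[1]), MISSING, dtype=np.int64)
            tipcodes[order] = cols
            if n_states == 61 and cols.max(initial=-1) > 60:
                raise LikelihoodError("codon index out of range")
        if tipcodes is None:
            raise LikelihoodError("need an alignment or tipcodes")
        self.tipcodes = tipcodes
        self.weights = np.asarray(weights, dtype=float)
        self.n_patterns = self.tipcodes.shape[1]
        self._spec = None
        self._pi = None
        self._Q = None

    # -- model ------------------------------------------------------------
    def set_model(self, Q: CodonRateMatrix | np.ndarray,
                  pi: np.ndarray | None = None) -> None:
        if isinstance(Q, CodonRateMatrix):
            pi, Q = Q.pi, Q.Q
        if Q.shape != (self.n_states, self.n_states):
            raise LikelihoodError(
                f"generator is {Q.shape}, engine expects {self.n_states} states")
        self._Q, self._pi = Q, np.asarray(pi, dtype=float)
        self._spec = spectral_decomposition(Q, self._pi)

    def _P(self, t: float) -> np.ndarray:
        if self._spec is None:
            return np.clip(_expm(self._Q * t), 0.0, None)
        w, A, B = self._spec
        return np.clip((A * np.exp(w * t)[None, :]) @ B, 0.0, None)

    def _tip_message(self, P: np.ndarray, codes: np.ndarray) -> np.ndarray:
        """P(t) columns for observed tip states; ones for missing."""
        msg = P[:, np.where(codes == MISSING, 0, codes)]
        msg = msg.copy()
        msg[:, codes == MISSING] = 1.0
        return msg

    def _upward(self, lengths: np.ndarray):
        """Post-order partials.

        Returns (up, msg, logscale): ``up[v]`` is the partial likelihood at
        node v (None for tips), ``msg[v]`` = P(t_v) @ up[v] is v's message to
        its parent, ``logscale`` the accumulated per-pattern log factors.
        """
        tree = self.tree
        up = [None] * tree.n_nodes
        msg = [None] * tree.n_nodes
        logscale = np.zeros(self.n_patterns)
        for v in range(tree.n_taxa):
            msg[v] = self._tip_message(self._P(lengths[v]), self.tipcodes[v])
        for v in tree.postorder_internal():
            L = msg[tree.children[v][0]].copy()
            for c in tree.children[v][1:]:
                L *= msg[c]
            mx = L.max(axis=0)
            bad = mx < _RESCALE_THRESHOLD
            mx = np.where(mx <= 0, 1.0, mx)
            if bad.any() or (mx < 1e-4).any():
                L = L / mx
                logscale += np.log(mx)
            up[v] = L
            if tree.parent[v] >= 0:
                msg[v] = self._P(lengths[v]) @ L
        return up, msg, logscale

    def loglik(self, lengths: np.ndarray | None = None) -> float:
        lengths = self.tree.lengths if lengths is None else lengths
        up, _msg, logscale = self._upward(lengths)
        site = self._pi @ up[self.tree.root]
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            raise LikelihoodError("non-positive site likelihood "
                                  f"(min={site.min():.3g})")
        lnl = float(self.weights @ (np.log(site) + logscale))
        if not np.isfinite(lnl):
            raise LikelihoodError("non-finite log-likelihood")
        return lnl

    # -- branch-length profile machinery -----------------------------------
    def edge_profiles(self, lengths: np.ndarray):
        """Per-edge 1-D likelihood profiles at the current model and lengths.

        For every non-root node v with parent u the site likelihood as a
        function of that branch length alone is
        ``L(t) = sum_k coef_k exp(w_k t)`` where the coefficients combine
        the partials below v with the likelihood of everything outside v's
        subtree.  Returns ``{v: (coef, logscale)}`` with ``coef`` of shape
        (n_patterns, n_states).  Requires the spectral decomposition.
        """
        if self._spec is None:
            return None
        w, A, B = self._spec
        tree = self.tree
        up, msg, logscale_up = self._upward(lengths)
        # downward pass: out[v] = likelihood of data outside subtree(v), as a
        # function of the state at parent(v), with the root prior folded in.
        out = [None] * tree.n_nodes
        out_scale = [None] * tree.n_nodes
        root = tree.root
        for u in reversed(list(tree.postorder_internal())):
            if u == root:
                base = np.repeat(self._pi[:, None], self.n_patterns, axis=1)
                base_scale = np.zeros(self.n_patterns)
            else:
                base = self._P(lengths[u]).T @ out[u]
                base_scale = out_scale[u]
            kids = tree.children[u]
            for v in kids:
                O = base.copy()
                for s in kids:
                    if s != v:
                        O *= msg[s]
                mx = O.max(axis=0)
                mx = np.where(mx <= 0, 1.0, mx)
                O /= mx
                out[v] = O
                out_scale[v] = base_scale + np.log(mx)
        profiles = {}
        for v in range(tree.n_nodes):
            if tree.parent[v] < 0:
                continue
            if v < tree.n_taxa:
                codes = self.tipcodes[v]
                obs = codes != MISSING
                # missing tip: up-partial is all-ones, so its transform is
                # the row sums of B
                upBt = np.tile(B.sum(axis=1), (self.n_patterns, 1))
                upBt[obs] = B[:, codes[obs]].T
                scale_v = np.zeros(self.n_patterns)
            else:
                upBt = (B @ up[v]).T
                scale_v = np.zeros(self.n_patterns)  # folded into logscale_up
            coef = (out[v].T @ A) * upBt
            profiles[v] = (coef, out_scale[v] + scale_v)
        # tip up-partials carry no scaling; internal up scalings are shared by
        # every edge through logscale_up, so report them separately.
        return w, profiles, logscale_up

    def optimize_branch_lengths(self, lengths: np.ndarray, n_sweeps: int = 2,
                                bounds=BRANCH_BOUNDS) -> np.ndarray:
        """Coordinate-wise branch-length maximisation; returns new lengths.

        Each sweep recomputes the up/down partials once, then optimises every
        branch on its cheap 1-D spectral profile.  Sweeps that fail to improve
        the exact likelihood are rolled back (the profiles of later edges in
        a sweep are computed at the sweep-start lengths).
        """
        lengths = lengths.copy()
        best = self.loglik(lengths)
        tree = self.tree
        for _ in range(n_sweeps):
            prof = self.edge_profiles(lengths)
            if prof is None:  # no spectral decomposition: slow exact path
                for v in range(tree.n_nodes):
                    if tree.parent[v] < 0:
                        continue
                    def neg(logt, v=v):
                        trial = lengths.copy()
                        trial[v] = np.exp(logt)
                        return -self.loglik(trial)
                    res = minimize_scalar(neg, bounds=np.log(bounds), method="bounded")
                    lengths[v] = np.exp(res.x)
                best = self.loglik(lengths)
                continue
            w, profiles, logscale_up = prof
            trial = lengths.copy()
            for v, (coef, _scale) in profiles.items():
                # per-pattern site likelihood ~ coef @ exp(w t); the scale
                # terms are constant in t and drop out of the argmax
                def neg(logt):
                    site = coef @ np.exp(w * np.exp(logt))
                    if np.any(site <= 0) or not np.all(np.isfinite(site)):
                        return 1e12
                    return -float(self.weights @ np.log(site))
                res = minimize_scalar(neg, bounds=np.log(bounds), method="bounded",
                                      options={"xatol": 1e-7})
                trial[v] = np.exp(res.x)
            new = self.loglik(trial)
            if new >= best - 1e-9:
                lengths, improved = trial, new - best
                best = new
                if improved < 1e-6:
                    break
            else:  # stale-profile sweep went backwards: keep previous lengths
                break
        # Gauss-Seidel polish: each edge against fresh profiles of the rest,
        # iterated until stable, so the result is a genuine coordinate-wise
        # optimum even when neighbouring edges interact.
        for _pass in range(4):
            pass_start = best
            for v in range(tree.n_nodes):
                if tree.parent[v] < 0:
                    continue
                prof = self.edge_profiles(lengths)
                if prof is None:
                    return lengths
                w, profiles, _ = prof
                coef, _scale = profiles[v]

                def neg(logt):
                    site = coef @ np.exp(w * np.exp(logt))
                    if np.any(site <= 0) or not np.all(np.isfinite(site)):
                        return 1e12
                    return -float(self.weights @ np.log(site))

                res = minimize_scalar(neg, bounds=np.log(bounds),
                                      method="bounded",
                                      options={"xatol": 1e-8})
                trial = lengths.copy()
                trial[v] = np.exp(res.x)
                new = self.loglik(trial)
                if new > best:
                    lengths, best = trial, new
            if best - pass_start < 1e-7:
                break
        return lengths


def log_likelihood(tree: Phylogeny, aln: CodonAlignment,
                   Q: CodonRateMatrix) -> float:
    """Log-likelihood of a codon alignment on a tree under one generator."""
    engine = PruningEngine(tree, aln)
    engine.set_model(Q)
    return engine.loglik()


# ---------------------------------------------------------------------------
# positional 4-state GTR fit (codon-position partitioned comparison)

from dataclasses import dataclass as _dataclass

from .codons import NUC_INDEX
from .model import PAIR_ORDER

#: reference pair whose rate is fixed to 1 in reported GTR rates
GTR_REFERENCE_PAIR = "TG"


@_dataclass
class GTRFit:
    """Result of a 4-state GTR fit on one codon position.

    ``rates`` maps the six nucleotide pairs to relative rates normalised so
    the G<->T rate is 1; ``branch_scale`` multiplies the input tree's branch
    lengths (codon units) to nucleotide-substitution units.
    """

    position: int
    rates: dict
    base_freqs: dict
    lnL: float
    branch_scale: float
    converged: bool
    warnings: list


def _gtr_Q(rates6: np.ndarray, pi: np.ndarray) -> np.ndarray:
    S = np.zeros((4, 4))
    for (a, b), r in zip(PAIR_ORDER, rates6):
        i, j = NUC_INDEX[a], NUC_INDEX[b]
        S[i, j] = S[j, i] = r
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    mean_rate = float(pi @ Q.sum(axis=1))
    Q /= mean_rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_positional_gtr(aln: CodonAlignment, tree: Phylogeny, position: int,
                       max_iter: int = 500) -> GTRFit:
    """ML fit of a nucleotide GTR to one codon position of the alignment.

    Extracts the nucleotide column at codon position 1, 2 or 3 of every
    codon site, estimates base frequencies empirically, and maximises the
    likelihood over five free relative rates (G<->T fixed at 1) plus a
    global branch-length scale, reusing the pruning engine with 4 states.
    The fitted rates are directly comparable with a KCM positional matrix.
    """
    from scipy.optimize import minimize

    if position not in (1, 2, 3):
        raise LikelihoodError(f"codon position must be 1, 2 or 3, got {position}")
    code = aln.code
    nuc_of = np.array([[NUC_INDEX[n] for n in c] for c in code.sense_order_61])
    codes = np.where(aln.codes == MISSING, MISSING,
                     nuc_of[np.clip(aln.codes, 0, 60), position - 1])
    obs = codes[codes != MISSING]
    warnings = []
    counts = np.bincount(obs, minlength=4).astype(float)
    if np.any(counts == 0):
        counts += 0.5
        warnings.append("zero-count base; pseudocount applied to frequencies")
    pi = counts / counts.sum()
    if not np.any(codes.max(axis=0) != codes.min(axis=0)):
        warnings.append("alignment position is invariant; rates unidentifiable")

    cols, wts = np.unique(codes, axis=1, return_counts=True)
    order = tree.leaf_order(aln.taxa)
    tipcodes = np.full((tree.n_taxa, cols.shape[1]), MISSING, dtype=np.int64)
    tipcodes[order] = cols
    engine = PruningEngine(tree, tipcodes=tipcodes, weights=wts.astype(float),
                           n_states=4)
    ref = PAIR_ORDER.index(GTR_REFERENCE_PAIR)
    free = [i for i in range(6) if i != ref]

    n_sites = float(wts.sum())

    def unpack(theta):
        rates = np.ones(6)
        rates[free] = np.exp(theta[:5])
        return rates, np.exp(theta[5])

    def neg(theta):
        # per-site scale keeps L-BFGS-B's unit-Hessian first step sane; the
        # graded penalty slopes back towards the feasible region
        rates, scale = unpack(theta)
        try:
            engine.set_model(_gtr_Q(rates, pi), pi)
            return -engine.loglik(tree.lengths * scale) / n_sites
        except LikelihoodError:
            return 1e4 + float(np.abs(theta).sum())

    theta0 = np.zeros(6)
    res = minimize(neg, theta0, method="L-BFGS-B",
                   bounds=[(np.log(1e-4), np.log(1e4))] * 6,
                   options={"maxiter": max_iter, "ftol": 1e-13, "eps": 1e-6})
    rates, scale = unpack(res.x)
    return GTRFit(position=position,
                  rates=dict(zip(PAIR_ORDER, map(float, rates))),
                  base_freqs=dict(zip("TCAG", map(float, pi))),
                  lnL=float(-res.fun * n_sites), branch_scale=float(scale),
                  converged=bool(res.success), warnings=warnings)
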