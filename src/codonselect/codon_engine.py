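"""Codon substitution matrices, pruning likelihoods, and ML fitting.

The shared numerical core for all site-model analyses. Rate matrices follow
the Goldman–Yang parameterization: a substitution between codons differing at
a single nucleotide has rate pi_j multiplied by kappa for transitions and by
omega for nonsynonymous changes; multi-nucleotide instantaneous changes are
forbidden. Matrices are scaled so one unit of branch length equals one
expected substitution per codon (for mixtures: averaged over site classes),
which keeps branch lengths comparable across models.

Likelihoods use Felsenstein pruning vectorized across alignment columns,
with per-site rescaling for numerical stability. Transition probabilities
come from the eigendecomposition of the reversible generator, so thousands
of branch-length/omega combinations are cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import linalg, optimize
from scipy.special import betainc, expit, logit

from .seqio import (MISSING, STANDARD_CODE, CodonAlignment, CodonFrequencies,
                    GeneticCode, Phylogeny, equal_frequencies)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@lru_cache(maxsize=4)
def _structure(code: GeneticCode):
    """Single-nucleotide neighbor structure over sense codons.

    Returns boolean (n,n) arrays: single-nt difference, transition, and
    synonymous change, plus the differing-position index (or -1).
    """
    n = code.n_sense
    single = np.zeros((n, n), dtype=bool)
    is_ts = np.zeros((n, n), dtype=bool)
    is_syn = np.zeros((n, n), dtype=bool)
    pos = np.full((n, n), -1, dtype=np.int8)
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            single[i, j] = True
            pos[i, j] = p
            is_ts[i, j] = (ci[p], cj[p]) in _TRANSITIONS
            is_syn[i, j] = code.codon_to_aa[ci] == code.codon_to_aa[cj]
    return single, is_ts, is_syn, pos


@dataclass
class RateMatrix:
    """A normalized codon generator with its parameters."""

    Q: np.ndarray
    kappa: float
    omega: float
    pi: np.ndarray
    scale: float  # divisor applied to the raw generator


def _raw_generator(kappa: float, omega: float, pi: np.ndarray,
                   code: GeneticCode = STANDARD_CODE):
    """Unscaled GY94 generator and its stationary substitution rate."""
    if not (np.isfinite(kappa) and np.isfinite(omega)):
        raise ValueError("kappa and omega must be finite")
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    single, is_ts, is_syn, _ = _structure(code)
    Q = np.zeros_like(single, dtype=float)
    Q[single] = pi[np.where(single)[1]]
    Q[single & is_ts] *= kappa
    Q[single & ~is_syn] *= omega
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = float(-(pi * np.diag(Q)).sum())
    return Q, rate


def build_codon_rate_matrix(kappa: float, omega: float,
                            pi: CodonFrequencies,
                            code: GeneticCode = STANDARD_CODE) -> RateMatrix:
    """GY94 rate matrix scaled to one expected substitution per unit time."""
    p = np.asarray(pi.pi, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pi must be strictly positive (use a pseudocount)")
    Q, rate = _raw_generator(kappa, omega, p, code)
    if rate <= 0:
        raise ValueError("degenerate generator (zero substitution rate)")
    return RateMatrix(Q / rate, kappa, omega, p, rate)


@dataclass
class MixtureSpec:
    """Site classes as (weight, omega) pairs; weights on the simplex."""

    classes: list

    def __post_init__(self):
        w = np.array([c[0] for c in self.classes], dtype=float)
        om = np.array([c[1] for c in self.classes], dtype=float)
        if np.any((w < -1e-12) | (w > 1 + 1e-12)):
            raise ValueError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-10:
            raise ValueError(f"weights sum to {w.sum()}, not 1")
        if np.any(om < 0):
            raise ValueError("omega must be non-negative")
        self.weights = w
        self.omegas = om


def discretize_beta(p: float, q: float, K: int = 10) -> MixtureSpec:
    """K equal-weight classes for a Beta(p, q); representatives are the
    conditional means within each equal-probability bin (closed form via the
    regularized incomplete beta function)."""
    if p <= 0 or q <= 0:
        raise ValueError("beta shapes must be positive")
    if K < 2:
        raise ValueError("need at least 2 classes")
    edges = np.linspace(0.0, 1.0, K + 1)
    from scipy.stats import beta as beta_dist
    x = beta_dist.ppf(edges, p, q)
    # E[X | a < X < b] = mean * (I_b(p+1,q) - I_a(p+1,q)) / (I_b(p,q) - I_a(p,q))
    upper = betainc(p + 1, q, x)
    mass = np.diff(betainc(p, q, x))
    mean = p / (p + q)
    reps = mean * np.diff(upper) / np.where(mass > 0, mass, 1.0)
    reps = np.clip(reps, 1e-9, 1 - 1e-9)
    return MixtureSpec([(1.0 / K, float(r)) for r in reps])


class TreeIndex:
    """Array view of a rooted traversal of a dendropy tree.

    Nodes are numbered in postorder with the root last; ``children`` maps an
    internal node to its child indices and ``lengths`` holds the edge length
    above each non-root node.
    """

    def __init__(self, phy: Phylogeny, taxa: list):
        nodes = list(phy.tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.children = [[self.node_of[id(ch)] for ch in nd.child_nodes()]
                         for nd in nodes]
        self.lengths = np.zeros(self.n_nodes)
        for i, nd in enumerate(nodes):
            if nd.edge.length is not None:
                self.lengths[i] = float(nd.edge.length)
        self.root = self.n_nodes - 1
        self.is_leaf = np.array([not c for c in self.children])
        self.leaf_row = np.full(self.n_nodes, -1, dtype=np.int64)
        taxon_row = {t: r for r, t in enumerate(taxa)}
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in taxon_row:
                    raise ValueError(f"tree leaf '{label}' not in alignment")
                self.leaf_row[i] = taxon_row[label]
        self.postorder = list(range(self.n_nodes))
        self.leaf_labels = {i: nodes[i].taxon.label
                            for i in range(self.n_nodes) if nodes[i].is_leaf()}

    def edge_indices(self):
        """Non-root node indices (each owns the edge above it)."""
        return [i for i in range(self.n_nodes) if i != self.root]


class _Eigen:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        lam, U = linalg.eigh((B + B.T) / 2.0)
        self.lam = lam
        self.L = U / d[:, None]
        self.R = U.T * d[None, :]

    def transition(self, t: float) -> np.ndarray:
        P = (self.L * np.exp(self.lam * t)) @ self.R
        np.maximum(P, 0.0, out=P)
        return P


class LikelihoodEngine:
    """Pruning likelihoods for one alignment/tree pair.

    Vectorizes across alignment columns; per-class transition matrices are
    rebuilt per parameter vector from a cached eigendecomposition keyed by
    (kappa, omega).
    """

    def __init__(self, aln: CodonAlignment, phy: Phylogeny,
                 pi: CodonFrequencies):
        phy.pair_with(aln)
        phy.validate_lengths()
        self.aln = aln
        self.code = aln.code
        self.n_states = self.code.n_sense
        self.pi = np.asarray(pi.pi, dtype=float)
        if np.any(self.pi <= 0):
            raise ValueError("pi must be strictly positive")
        self.tree = TreeIndex(phy, aln.taxa)
        self.lengths = self.tree.lengths.copy()
        self._eig_cache = {}

    # -- generator handling -------------------------------------------------

    def _eigen(self, kappa: float, omega: float):
        key = (round(float(kappa), 12), round(float(omega), 12))
        hit = self._eig_cache.get(key)
        if hit is None:
            Q, rate = _raw_generator(kappa, omega, self.pi, self.code)
            hit = (_Eigen(Q, self.pi), rate)
            if len(self._eig_cache) > 4096:
                self._eig_cache.clear()
            self._eig_cache[key] = hit
        return hit

    def class_rate(self, kappa: float, omega: float) -> float:
        return self._eigen(kappa, omega)[1]

    def mixture_scale(self, kappa, weights, omegas) -> float:
        """Mixture-averaged substitution rate of the raw generators."""
        return float(sum(w * self.class_rate(kappa, om)
                         for w, om in zip(weights, omegas)))

    # -- pruning ------------------------------------------------------------

    def site_loglik_class(self, kappa: float, omega: float,
                          scale: float | None = None,
                          lengths: np.ndarray | None = None) -> np.ndarray:
        """Per-site log-likelihood under a single omega class.

        ``scale`` divides the raw generator; by default the class's own rate,
        so branch lengths are expected substitutions per codon under that
        class. Mixture fits pass the mixture-averaged rate instead.
        """
        eig, rate = self._eigen(kappa, omega)
        s = rate if scale is None else float(scale)
        t = (self.lengths if lengths is None else lengths) / s
        return self._prune(eig, t)

    def _prune(self, eig: _Eigen, t: np.ndarray) -> np.ndarray:
        n_sites = self.aln.n_codons
        codes = self.aln.codons
        tree = self.tree
        partial = [None] * tree.n_nodes
        logscale = np.zeros(n_sites)
        for v in tree.postorder:
            if tree.is_leaf[v]:
                continue
            F = np.ones((n_sites, self.n_states))
            for ch in tree.children[v]:
                P = eig.transition(t[ch])
                if tree.is_leaf[ch]:
                    obs = codes[tree.leaf_row[ch]]
                    msg = np.ones((n_sites, self.n_states))
                    known = obs >= 0
                    msg[known] = P[:, obs[known]].T
                else:
                    msg = partial[ch] @ P.T
                    partial[ch] = None
                F *= msg
            m = F.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            F /= m[:, None]
            logscale += np.log(m)
            partial[v] = F
        root = partial[tree.root]
        if root is None:  # single-leaf degenerate tree
            raise ValueError("tree must have at least one internal node")
        lik = root @ self.pi
        return np.log(np.maximum(lik, 1e-320)) + logscale

    def mixture_site_logliks(self, kappa: float, mix: MixtureSpec,
                             lengths: np.ndarray | None = None,
                             scale: float | None = None):
        """Per-class and mixture per-site log-likelihoods.

        Returns (site_lnl, class_lnl) where class_lnl has shape
        (n_classes, n_sites); site_lnl is the log of the weighted mixture.
        """
        w, om = mix.weights, mix.omegas
        if scale is None:
            scale = self.mixture_scale(kappa, w, om)
        class_lnl = np.stack([
            self.site_loglik_class(kappa, o, scale=scale, lengths=lengths)
            for o in om])
        mx = class_lnl.max(axis=0)
        site_lnl = mx + np.log(
            np.tensordot(w, np.exp(class_lnl - mx), axes=1))
        return site_lnl, class_lnl

    def lnl(self, kappa: float, mix: MixtureSpec,
            lengths: np.ndarray | None = None) -> float:
        return float(self.mixture_site_logliks(kappa, mix, lengths)[0].sum())


@dataclass
class FitResult:
    """A maximized site-model fit."""

    model: str
    lnl: float
    kappa: float
    mixture: MixtureSpec
    params: dict
    freq_scheme: str
    pi: np.ndarray
    lengths: np.ndarray
    convergence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "lnL": self.lnl,
            "kappa": self.kappa,
            "classes": [{"weight": float(w), "omega": float(o)}
                        for w, o in zip(self.mixture.weights,
                                        self.mixture.omegas)],
            "params": {k: (float(v) if np.isscalar(v) else list(map(float, v)))
                       for k, v in self.params.items()},
            "freq_scheme": self.freq_scheme,
            "convergence": self.convergence,
        }


# ---------------------------------------------------------------------------
# Model parameterizations. Each spec maps an unconstrained vector x to a
# (kappa, MixtureSpec, params-dict); bounds are on the transformed scale.

_LOGK_B = (math.log(0.1), math.log(20.0))
_LOGW_B = (math.log(1e-4), math.log(50.0))
_LOGIT_B = (-15.0, 15.0)  # wide enough that boundary nulls are reachable
_LOGSHAPE_B = (math.log(0.05), math.log(32.0))
_LOGWS_B = (0.0, math.log(50.0))  # omega >= 1 classes

_BETA_K = 10


def _softmax3(z0, z1):
    e = np.array([math.exp(z0), math.exp(z1), 1.0])
    return e / e.sum()


class _ModelSpec:
    def __init__(self, name, n_params, unpack, inits):
        self.name = name
        self.n_params = n_params
        self.unpack = unpack
        self.inits = inits
        self.bounds = _MODEL_BOUNDS[name]


def _unpack_m0(x):
    kappa, omega = math.exp(x[0]), math.exp(x[1])
    return kappa, MixtureSpec([(1.0, omega)]), {"omega": omega}


def _unpack_m1a(x):
    kappa = math.exp(x[0])
    p0 = float(expit(x[1]))
    w0 = float(expit(x[2]))
    return kappa, MixtureSpec([(p0, w0), (1 - p0, 1.0)]), \
        {"p0": p0, "omega0": w0}


def _unpack_m2a(x):
    kappa = math.exp(x[0])
    p = _softmax3(x[1], x[2])
    w0 = float(expit(x[3]))
    w2 = math.exp(x[4])
    mix = MixtureSpec([(p[0], w0), (p[1], 1.0), (p[2], w2)])
    return kappa, mix, {"p0": p[0], "p1": p[1], "p2": p[2],
                        "omega0": w0, "omega2": w2}


def _unpack_m7(x):
    kappa = math.exp(x[0])
    p, q = math.exp(x[1]), math.exp(x[2])
    mix = discretize_beta(p, q, _BETA_K)
    return kappa, mix, {"p": p, "q": q}


def _unpack_m8(x):
    kappa = math.exp(x[0])
    p, q = math.exp(x[1]), math.exp(x[2])
    p0 = float(expit(x[3]))
    ws = math.exp(x[4])
    beta = discretize_beta(p, q, _BETA_K)
    classes = [(p0 * w, o) for w, o in beta.classes] + [(1 - p0, ws)]
    return kappa, MixtureSpec(classes), \
        {"p": p, "q": q, "p0": p0, "omega_s": ws}


_MODEL_BOUNDS = {
    "M0": [_LOGK_B, _LOGW_B],
    "M1a": [_LOGK_B, _LOGIT_B, _LOGIT_B],
    "M2a": [_LOGK_B, _LOGIT_B, _LOGIT_B, _LOGIT_B, _LOGWS_B],
    "M7": [_LOGK_B, _LOGSHAPE_B, _LOGSHAPE_B],
    "M8": [_LOGK_B, _LOGSHAPE_B, _LOGSHAPE_B, _LOGIT_B, _LOGWS_B],
}

_MODEL_SPECS = {
    "M0": _ModelSpec("M0", 2, _unpack_m0, [
        [math.log(2), math.log(0.3)],
        [math.log(1), math.log(1.0)],
        [math.log(4), math.log(0.05)],
        [math.log(2), math.log(2.0)],
        [math.log(8), math.log(0.5)],
    ]),
    "M1a": _ModelSpec("M1a", 3, _unpack_m1a, [
        [math.log(2), logit(0.7), logit(0.2)],
        [math.log(2), logit(0.5), logit(0.5)],
        [math.log(4), logit(0.9), logit(0.05)],
        [math.log(1), logit(0.3), logit(0.8)],
        [math.log(2), logit(0.95), logit(0.1)],
    ]),
    "M2a": _ModelSpec("M2a", 5, _unpack_m2a, [
        # first restart sits near the M1a boundary (p2 ~ 0) so the nested
        # null optimum is always reachable
        [math.log(2), 4.0, 4.0, logit(0.3), math.log(2.0)],
        [math.log(2), 1.0, 0.0, logit(0.2), math.log(3.0)],
        [math.log(2), 2.0, 1.0, logit(0.1), math.log(1.5)],
        [math.log(4), 0.5, -1.0, logit(0.5), math.log(8.0)],
        [math.log(1), 1.5, 0.5, logit(0.05), math.log(2.0)],
        [math.log(2), 2.5, -0.5, logit(0.3), math.log(5.0)],
    ]),
    "M7": _ModelSpec("M7", 3, _unpack_m7, [
        [math.log(2), math.log(0.5), math.log(1.5)],
        [math.log(2), math.log(1.0), math.log(1.0)],
        [math.log(4), math.log(0.2), math.log(2.0)],
        [math.log(1), math.log(2.0), math.log(5.0)],
        [math.log(2), math.log(0.3), math.log(0.5)],
    ]),
    "M8": _ModelSpec("M8", 5, _unpack_m8, [
        # first restart near the M7 boundary (p0 ~ 1, omega_s at 1)
        [math.log(2), math.log(0.5), math.log(1.5), 14.0, 0.0],
        [math.log(2), math.log(1.0), math.log(1.0), logit(0.8), math.log(4.0)],
        [math.log(4), math.log(0.2), math.log(2.0), logit(0.95), math.log(1.5)],
        [math.log(1), math.log(2.0), math.log(5.0), logit(0.7), math.log(8.0)],
        [math.log(2), math.log(0.3), math.log(0.5), logit(0.85), math.log(3.0)],
    ]),
}

SUPPORTED_MODELS = tuple(_MODEL_SPECS)


def maximize_likelihood(aln: CodonAlignment, phy: Phylogeny,
                        model: str = "M0", freq_scheme: str = "F3X4",
                        pi: CodonFrequencies | None = None,
                        optimize_branch_lengths: bool = False,
                        n_restarts: int = 5, tol: float = 1e-8,
                        maxiter: int = 500) -> FitResult:
    """Fit a codon site model by bounded quasi-Newton ML with multi-start.

    Branch lengths are taken from the tree; with
    ``optimize_branch_lengths=True`` (meaningful for M0) they are estimated
    jointly on the log scale and returned in the result, the usual first
    stage before fitting the site-class models with lengths held fixed.
    """
    if model not in _MODEL_SPECS:
        raise ValueError(f"unsupported model '{model}' "
                         f"(choose from {SUPPORTED_MODELS})")
    if pi is None:
        from .seqio import estimate_codon_frequencies
        pi = (equal_frequencies(aln.code) if freq_scheme == "equal"
              else estimate_codon_frequencies(aln, freq_scheme))
    spec = _MODEL_SPECS[model]
    eng = LikelihoodEngine(aln, phy, pi)
    edge_idx = [i for i in range(eng.tree.n_nodes) if i != eng.tree.root]
    base_lengths = eng.lengths.copy()

    n_bl = len(edge_idx) if optimize_branch_lengths else 0
    log_t0 = np.log(np.maximum(base_lengths[edge_idx], 1e-3)) if n_bl else None

    def objective(x):
        try:
            kappa, mix, _ = spec.unpack(x[:spec.n_params])
        except (OverflowError, ValueError):
            return 1e10
        lengths = base_lengths
        if n_bl:
            lengths = base_lengths.copy()
            lengths[edge_idx] = np.exp(x[spec.n_params:])
        val = eng.lnl(kappa, mix, lengths)
        return 1e10 if not np.isfinite(val) else -val

    bounds = list(spec.bounds)
    if n_bl:
        bounds += [(math.log(1e-6), math.log(50.0))] * n_bl

    best = None
    attempts = []
    for r in range(max(1, n_restarts)):
        x0 = np.array(spec.inits[r % len(spec.inits)], dtype=float)
        if n_bl:
            x0 = np.concatenate([x0, log_t0])
        # ftol is relative to |lnL| (~1e3-1e4 here); scale the requested
        # absolute lnL tolerance accordingly
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": max(tol * 1e-4, 1e-15),
                                         "gtol": 1e-7,
                                         "maxiter": maxiter})
        attempts.append((-res.fun, res.status))
        if best is None or -res.fun > -best.fun:
            best = res
    kappa, mix, params = spec.unpack(best.x[:spec.n_params])
    lengths = base_lengths.copy()
    if n_bl:
        lengths[edge_idx] = np.exp(best.x[spec.n_params:])
    conv = {"n_restarts": max(1, n_restarts),
            "status": int(best.status),
            "message": str(best.message),
            "restart_lnls": [float(a[0]) for a in attempts],
            "grad_norm": float(np.max(np.abs(best.jac)))
            if best.jac is not None else float("nan")}
    return FitResult(model=model, lnl=float(-best.fun), kappa=float(kappa),
                     mixture=mix, params=params, freq_scheme=pi.scheme,
                     pi=eng.pi, lengths=lengths, convergence=conv)


def engine_for_fit(aln: CodonAlignment, phy: Phylogeny,
                   fit: FitResult) -> LikelihoodEngine:
    """Engine with the fit's branch lengths installed (for posterior work)."""
    eng = LikelihoodEngine(aln, phy, CodonFrequencies(fit.freq_scheme, fit.pi))
    eng.lengths = fit.lengths.copy()
    return eng
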