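"""Site-model battery: LRTs, Bayesian site detection, consensus, episodic
selection, and evolutionary fingerprinting.

The M-series models (M0, M1a, M2a, M7, M8) are fitted by the shared engine;
M1a-vs-M2a and M7-vs-M8 likelihood-ratio tests use a chi-square reference
with 2 degrees of freedom. Site-level evidence of omega > 1 comes from three
routes — empirical-Bayes posteriors with parameter uncertainty integrated on
a grid (BEB), a fitted discrete (alpha, beta) distribution with Bayes
factors (REL), and a Dirichlet-weighted (alpha, beta) lattice sampled by
Gibbs (FUBAR-style) — and a site enters the consensus set when flagged by at
least ``min_methods`` of them. A gene-level episodic test constrains the
largest omega class to 1 (BUSTED-style), and fingerprinting selects the
number of (alpha, beta) rate classes by small-sample AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .codon_engine import (FitResult, LikelihoodEngine, MixtureSpec,
                           discretize_beta, engine_for_fit,
                           maximize_likelihood, _raw_generator)
from .seqio import CodonAlignment, CodonFrequencies, Phylogeny

BEB_CUTOFF = 0.90
FUBAR_CUTOFF = 0.90
REL_BF_CUTOFF = 50.0


# ---------------------------------------------------------------------------
# Fitting and LRTs

def fit_site_model(aln: CodonAlignment, phy: Phylogeny, model: str,
                   freq_scheme: str = "F3X4",
                   m0_fit: FitResult | None = None,
                   optimize_branch_lengths: bool = True,
                   n_restarts: int = 3, **kwargs) -> FitResult:
    """Fit one site model, with branch lengths taken from a single-ratio
    (M0) pre-fit and then held fixed — the usual two-stage convention.

    Pass ``m0_fit`` to reuse a previous M0 stage;
    ``optimize_branch_lengths=False`` keeps the input tree's lengths (useful
    when they are known, e.g. simulation truth).
    """
    if model == "M0":
        return maximize_likelihood(
            aln, phy, "M0", freq_scheme,
            optimize_branch_lengths=optimize_branch_lengths,
            n_restarts=n_restarts, **kwargs)
    phy_fit = phy
    if optimize_branch_lengths:
        if m0_fit is None:
            m0_fit = maximize_likelihood(aln, phy, "M0", freq_scheme,
                                         optimize_branch_lengths=True,
                                         n_restarts=n_restarts, **kwargs)
        phy_fit = _tree_with_lengths(phy, m0_fit)
    return maximize_likelihood(aln, phy_fit, model, freq_scheme,
                               optimize_branch_lengths=False,
                               n_restarts=n_restarts, **kwargs)


def _tree_with_lengths(phy: Phylogeny, fit: FitResult) -> Phylogeny:
    """Clone the tree and install the fit's branch lengths."""
    from .codon_engine import TreeIndex
    clone = phy.clone()
    nodes = list(clone.tree.postorder_node_iter())
    for i, nd in enumerate(nodes):
        if nd is not clone.tree.seed_node:
            nd.edge.length = float(fit.lengths[i])
    return clone


NESTED_PAIRS = {("M1a", "M2a"): 2, ("M7", "M8"): 2, ("M0", "M2a"): 3}


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    two_delta_lnl: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_null: FitResult,
                          fit_alt: FitResult) -> LRTResult:
    """2(lnL_alt - lnL_null), clamped at 0, against chi-square."""
    pair = (fit_null.model, fit_alt.model)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    df = NESTED_PAIRS[pair]
    stat = max(0.0, 2.0 * (fit_alt.lnl - fit_null.lnl))
    p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, df))
    return LRTResult(fit_null.model, fit_alt.model, stat, df, p)


# ---------------------------------------------------------------------------
# Site posterior tables

@dataclass
class SitePosteriorTable:
    """Per-codon evidence of positive selection from one method."""

    method: str
    codon: np.ndarray            # unmasked-gene 1-based coordinates
    posterior: np.ndarray        # P(site under positive selection)
    flag: np.ndarray             # detection at the method's cutoff
    cutoff: float
    bayes_factor: np.ndarray = None
    estimate: pd.DataFrame = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any((self.posterior < -1e-9) | (self.posterior > 1 + 1e-9)):
            raise ValueError("posteriors must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"codon": self.codon, "method": self.method,
                           "posterior": self.posterior, "flag": self.flag})
        if self.bayes_factor is not None:
            df["bayes_factor"] = self.bayes_factor
        return df


def _site_class_liks(eng: LikelihoodEngine, kappa: float, omegas,
                     scale: float) -> np.ndarray:
    """Linear-space site likelihoods for many omega values, jointly rescaled
    per site (constant per-site factors cancel in every posterior ratio)."""
    logf = np.stack([eng.site_loglik_class(kappa, float(w), scale=scale)
                     for w in omegas])
    mx = logf.max(axis=0)
    out = np.exp(logf - mx)
    return out, mx


def beb_posteriors(fit: FitResult, aln: CodonAlignment,
                   phy: Phylogeny, cutoff: float = BEB_CUTOFF
                   ) -> SitePosteriorTable:
    """Bayes empirical Bayes site posteriors under M2a or M8.

    Parameter uncertainty is integrated over 10-point uniform grids per free
    parameter (M2a: p0, p1, omega0, omega2; M8: p0, p, q, omega_s), with
    branch lengths, kappa, and the substitution-rate scaling held at their
    ML values. Sites are flagged at posterior >= 0.90.
    """
    if fit.model not in ("M2a", "M8"):
        raise ValueError("BEB requires an M2a or M8 fit")
    eng = engine_for_fit(aln, phy, fit)
    kappa = fit.kappa
    scale = eng.mixture_scale(kappa, fit.mixture.weights, fit.mixture.omegas)
    mids = np.linspace(0.05, 0.95, 10)
    if fit.model == "M2a":
        w0_grid = mids
        w2_grid = np.linspace(1.5, 10.5, 10)
        omegas = np.concatenate([w0_grid, [1.0], w2_grid])
        F, _ = _site_class_liks(eng, kappa, omegas, scale)
        A, B, C = F[:10], F[10], F[11:]
        combos = [(p0, p1) for p0 in mids for p1 in mids if p0 + p1 <= 1.0]
        P0 = np.array([c[0] for c in combos])
        P1 = np.array([c[1] for c in combos])
        P2 = 1.0 - P0 - P1
        idx0, idx2 = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        idx0, idx2 = idx0.ravel(), idx2.ravel()
        # grid axes: (p-combos, omega0 x omega2)
        f = (P0[:, None, None] * A[idx0][None, :, :]
             + P1[:, None, None] * B[None, None, :]
             + P2[:, None, None] * C[idx2][None, :, :])
        pos_part = P2[:, None, None] * C[idx2][None, :, :]
    else:  # M8
        p_grid = np.linspace(0.1, 1.9, 10)
        q_grid = np.linspace(0.1, 1.9, 10)
        ws_grid = np.linspace(1.5, 10.5, 10)
        p0_grid = mids
        beta_means = []
        omega_values = list(ws_grid)
        for p in p_grid:
            for q in q_grid:
                reps = [om for _, om in discretize_beta(p, q, 10).classes]
                beta_means.append(reps)
                omega_values.extend(reps)
        omega_values = np.array(omega_values)
        F, _ = _site_class_liks(eng, kappa, omega_values, scale)
        n_sites = F.shape[1]
        FW = F[:10]  # omega_s spike likelihoods
        Fbeta = F[10:].reshape(100, 10, n_sites).mean(axis=1)  # per (p,q)
        f = (p0_grid[:, None, None, None] * Fbeta[None, :, None, :]
             + (1 - p0_grid)[:, None, None, None] * FW[None, None, :, :])
        pos_part = np.broadcast_to(
            (1 - p0_grid)[:, None, None, None] * FW[None, None, :, :],
            f.shape)
        f = f.reshape(-1, n_sites)
        pos_part = pos_part.reshape(-1, n_sites)
    f = f.reshape(-1, F.shape[1])
    pos_part = pos_part.reshape(-1, F.shape[1])
    log_marg = np.log(np.maximum(f, 1e-300)).sum(axis=1)
    log_marg -= log_marg.max()
    gw = np.exp(log_marg)
    gw /= gw.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(f > 0, pos_part / np.maximum(f, 1e-300), 0.0)
    post = gw @ ratio
    post = np.clip(post, 0.0, 1.0)
    return SitePosteriorTable(method="BEB", codon=aln.site_index.copy(),
                              posterior=post, flag=post >= cutoff,
                              cutoff=cutoff,
                              notes={"model": fit.model})


# ---------------------------------------------------------------------------
# (alpha, beta) machinery shared by REL, FUBAR, and fingerprinting

def _rate_components(eng: LikelihoodEngine, kappa: float):
    """Stationary substitution rate is linear in omega: rate = A + omega*B."""
    r0 = eng.class_rate(kappa, 0.0)
    r1 = eng.class_rate(kappa, 1.0)
    return r0, r1 - r0


def _ab_site_logliks(eng: LikelihoodEngine, kappa: float, pairs,
                     scale: float) -> np.ndarray:
    """Per-site log-likelihoods for (alpha, beta) rate pairs.

    The generator alpha*Q_syn + beta*Q_nonsyn equals alpha times the
    single-omega generator with omega = beta/alpha, so each pair reuses the
    cached eigendecomposition with an adjusted branch-length scale.
    """
    out = []
    for a, b in pairs:
        a_eff = max(float(a), 1e-6)
        omega = float(b) / a_eff
        out.append(eng.site_loglik_class(kappa, omega, scale=scale / a_eff))
    return np.stack(out)


def _m0_kappa_scale(aln, phy, fit: FitResult | None, freq_scheme: str,
                    **fitkw):
    """M0 stage shared by the (alpha, beta) methods: returns the engine with
    fitted branch lengths, kappa, and the M0 rate scale."""
    if fit is None:
        fit = maximize_likelihood(aln, phy, "M0", freq_scheme,
                                  optimize_branch_lengths=True, **fitkw)
    eng = engine_for_fit(aln, phy, fit)
    omega0 = float(fit.mixture.omegas[0])
    scale = eng.class_rate(fit.kappa, omega0)
    return fit, eng, scale


def normalize_ab(weights, alphas, betas, rA, rB):
    """Rescale (alpha, beta) so the mixture-mean substitution rate is 1
    (reporting convention; per-class dN/dS = beta/alpha is unaffected)."""
    mean_rate = float((weights * (alphas * rA + betas * rB)).sum()
                      / (rA + rB))
    return alphas / mean_rate, betas / mean_rate


def _fit_ab_mixture(eng: LikelihoodEngine, kappa: float, scale: float,
                    k: int, n_restarts: int = 3):
    """ML fit of a k-class general discrete (alpha, beta) mixture.

    The overall rate scale stays free during optimization — branch lengths
    are held fixed, so the mixture must be able to rescale; normalize with
    :func:`normalize_ab` for reporting. Returns (lnl, weights, alphas,
    betas) on the fitted (raw) scale.
    """

    def unpack(x):
        a = np.exp(x[:k])
        b = np.exp(x[k:2 * k])
        e = np.concatenate([np.exp(x[2 * k:]), [1.0]])
        w = e / e.sum()
        return w, a, b

    def objective(x):
        try:
            w, a, b = unpack(x)
        except (OverflowError, FloatingPointError):
            return 1e10
        logf = _ab_site_logliks(eng, kappa, list(zip(a, b)), scale)
        mx = logf.max(axis=0)
        lik = np.tensordot(w, np.exp(logf - mx), axes=1)
        val = float((np.log(np.maximum(lik, 1e-300)) + mx).sum())
        return 1e10 if not np.isfinite(val) else -val

    bounds = ([(math.log(1e-3), math.log(20.0))] * (2 * k)
              + [(-8.0, 8.0)] * (k - 1))
    inits = []
    base_a = np.linspace(0.6, 1.4, k)
    base_b = np.geomspace(0.1, 3.0, k)
    inits.append(np.concatenate([np.log(base_a), np.log(base_b),
                                 np.zeros(k - 1)]))
    inits.append(np.concatenate([np.zeros(k), np.log(
        np.geomspace(0.05, 1.5, k)), np.zeros(k - 1)]))
    inits.append(np.concatenate([np.log(np.geomspace(0.5, 2.0, k)),
                                 np.log(np.geomspace(0.3, 5.0, k)),
                                 np.linspace(-1, 1, k - 1)]))
    best = None
    for r in range(max(1, n_restarts)):
        x0 = inits[r % len(inits)]
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-9, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    w, a, b = unpack(best.x)
    return float(-best.fun), w, a, b


def rel_posteriors(aln: CodonAlignment, phy: Phylogeny,
                   m0_fit: FitResult | None = None,
                   freq_scheme: str = "F3X4",
                   bf_cutoff: float = REL_BF_CUTOFF,
                   n_restarts: int = 3) -> SitePosteriorTable:
    """Random-effects site posteriors under a 3-class discrete (alpha, beta)
    distribution fitted by ML; evidence is an empirical-Bayes Bayes factor
    for beta > alpha, flagged at BF >= 50."""
    m0_fit, eng, scale = _m0_kappa_scale(aln, phy, m0_fit, freq_scheme,
                                         n_restarts=n_restarts)
    kappa = m0_fit.kappa
    lnl, w, a, b = _fit_ab_mixture(eng, kappa, scale, k=3,
                                   n_restarts=n_restarts)
    logf = _ab_site_logliks(eng, kappa, list(zip(a, b)), scale)
    mx = logf.max(axis=0)
    F = np.exp(logf - mx)
    joint = w[:, None] * F
    post = joint / joint.sum(axis=0, keepdims=True)
    pos_class = b > a
    prior_pos = float(w[pos_class].sum())
    p_pos = post[pos_class].sum(axis=0)
    eps = 1e-12
    prior_odds = max(prior_pos, eps) / max(1 - prior_pos, eps)
    post_odds = np.maximum(p_pos, eps) / np.maximum(1 - p_pos, eps)
    bf = post_odds / prior_odds
    degenerate = any(
        abs(a[i] - a[j]) + abs(b[i] - b[j]) < 1e-3
        for i in range(3) for j in range(i + 1, 3))
    rA, rB = _rate_components(eng, kappa)
    an, bn = normalize_ab(w, a, b, rA, rB)
    est = pd.DataFrame({"codon": aln.site_index,
                        "alpha": (post * an[:, None]).sum(axis=0),
                        "beta": (post * bn[:, None]).sum(axis=0)})
    return SitePosteriorTable(
        method="REL", codon=aln.site_index.copy(), posterior=p_pos,
        flag=bf >= bf_cutoff, cutoff=bf_cutoff, bayes_factor=bf,
        estimate=est,
        notes={"lnl": lnl, "weights": w.tolist(), "alpha": an.tolist(),
               "beta": bn.tolist(), "degenerate": bool(degenerate),
               "prior_pos": prior_pos})


def fubar_grid(grid_size: int = 20, max_rate: float = 8.0) -> np.ndarray:
    """Quadratically spaced rate grid on [0, max_rate] (dense near 0)."""
    i = np.arange(grid_size)
    return max_rate * (i / (grid_size - 1)) ** 2


def fubar_posteriors(aln: CodonAlignment, phy: Phylogeny,
                     m0_fit: FitResult | None = None,
                     freq_scheme: str = "F3X4", grid_size: int = 20,
                     n_samples: int = 2000, burn_in: int = 500,
                     thin: int = 5, chains: int = 2, seed: int = 0,
                     concentration: float = 0.5,
                     cutoff: float = FUBAR_CUTOFF,
                     n_restarts: int = 3) -> SitePosteriorTable:
    """Grid Bayesian site detection (FUBAR-style).

    Site likelihoods are precomputed on a grid_size x grid_size
    (alpha, beta) lattice; a Dirichlet(0.5) prior over lattice weights is
    sampled by Gibbs (site allocations / weight updates), and the per-site
    posterior of beta > alpha is Rao-Blackwellized over retained draws.
    Sites are flagged at posterior >= 0.90; a split-R̂ over chains on the
    total positive-selection weight is reported.
    """
    if burn_in >= n_samples:
        burn_in = n_samples // 4
    m0_fit, eng, scale = _m0_kappa_scale(aln, phy, m0_fit, freq_scheme,
                                         n_restarts=n_restarts)
    kappa = m0_fit.kappa
    rates = fubar_grid(grid_size)
    pairs = [(a, b) for a in rates for b in rates]
    logf = _ab_site_logliks(eng, kappa, pairs, scale)  # (G, n_sites)
    mx = logf.max(axis=0)
    L = np.exp(logf - mx).T  # (n_sites, G)
    L = np.maximum(L, 1e-300)
    G = L.shape[1]
    pos_sel = np.array([b > a for a, b in pairs])
    rng_master = np.random.default_rng(seed)
    n_sites = L.shape[0]
    post_sum = np.zeros(n_sites)
    n_kept = 0
    chain_means = []
    alpha_mean = np.zeros(n_sites)
    beta_mean = np.zeros(n_sites)
    pair_a = np.array([a for a, _ in pairs])
    pair_b = np.array([b for _, b in pairs])
    for _ in range(chains):
        rng = np.random.default_rng(rng_master.integers(2 ** 31 - 1))
        w = rng.dirichlet(np.full(G, concentration))
        kept_pos_w = []
        for it in range(n_samples):
            probs = L * w[None, :]
            probs /= np.maximum(probs.sum(axis=1, keepdims=True), 1e-300)
            u = rng.random(n_sites)
            z = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            np.clip(z, 0, G - 1, out=z)
            w = rng.dirichlet(concentration + np.bincount(z, minlength=G))
            if it >= burn_in and (it - burn_in) % thin == 0:
                num = L[:, pos_sel] @ w[pos_sel]
                den = np.maximum(L @ w, 1e-300)
                post_sum += num / den
                alpha_mean += (L * w) @ pair_a / den
                beta_mean += (L * w) @ pair_b / den
                kept_pos_w.append(float(w[pos_sel].sum()))
                n_kept += 1
        chain_means.append(kept_pos_w)
    post = post_sum / n_kept
    post = np.clip(post, 0.0, 1.0)
    from .gammamap_lite import _split_rhat
    m = min(len(c) for c in chain_means)
    rhat = _split_rhat(np.array([c[:m] for c in chain_means])) \
        if chains > 1 else float("nan")
    est = pd.DataFrame({"codon": aln.site_index,
                        "alpha": alpha_mean / n_kept,
                        "beta": beta_mean / n_kept})
    return SitePosteriorTable(
        method="FUBAR", codon=aln.site_index.copy(), posterior=post,
        flag=post >= cutoff, cutoff=cutoff, estimate=est,
        notes={"grid_size": grid_size, "rhat_pos_weight": rhat,
               "converged": (not np.isfinite(rhat)) or rhat <= 1.1,
               "kept_draws": n_kept})


# ---------------------------------------------------------------------------
# Consensus

@dataclass
class ConsensusReport:
    per_site: pd.DataFrame
    consensus: np.ndarray   # codon indices detected by >= min_methods
    strict: np.ndarray      # detected by every supplied method
    min_methods: int
    methods: list


def consensus_sites(tables, min_methods: int = 2) -> ConsensusReport:
    """Cross-method agreement: a codon is a consensus positive-selection
    target when flagged by at least ``min_methods`` methods."""
    if not tables:
        raise ValueError("need at least one site table")
    base = tables[0].codon
    for t in tables[1:]:
        if not np.array_equal(t.codon, base):
            raise ValueError("site tables use different codon coordinates")
    flags = pd.DataFrame({t.method: t.flag for t in tables})
    flags.insert(0, "codon", base)
    tally = flags[[t.method for t in tables]].sum(axis=1)
    flags["n_methods"] = tally
    consensus = base[(tally >= min_methods).to_numpy()] \
        if len(tables) >= min_methods else np.array([], dtype=base.dtype)
    strict = base[(tally == len(tables)).to_numpy()]
    return ConsensusReport(per_site=flags, consensus=consensus,
                           strict=strict, min_methods=min_methods,
                           methods=[t.method for t in tables])


# ---------------------------------------------------------------------------
# BUSTED-style episodic test

@dataclass
class BustedResult:
    lnl_unconstrained: float
    lnl_constrained: float
    omegas: np.ndarray
    weights: np.ndarray
    statistic: float
    p_value: float
    null_distribution: str = "chi2_mix"


def _busted_fit(eng: LikelihoodEngine, constrained: bool,
                n_restarts: int = 3):
    """3-class omega mixture with omega1 <= omega2 <= 1 <= omega3; the null
    pins omega3 at 1."""

    def unpack(x):
        kappa = math.exp(x[0])
        e = np.array([math.exp(x[1]), math.exp(x[2]), 1.0])
        w = e / e.sum()
        om2 = float(expit(x[3]))
        om1 = om2 * float(expit(x[4]))
        om3 = 1.0 if constrained else math.exp(x[5])
        return kappa, np.array([om1, om2, om3]), w

    def objective(x):
        try:
            kappa, oms, w = unpack(x)
        except OverflowError:
            return 1e10
        mix = MixtureSpec(list(zip(w, oms)))
        val = eng.lnl(kappa, mix)
        return 1e10 if not np.isfinite(val) else -val

    nper = 5 if constrained else 6
    bounds = [(math.log(0.1), math.log(20.0)), (-8, 8), (-8, 8),
              (-9, 9), (-9, 9)]
    if not constrained:
        bounds.append((0.0, math.log(50.0)))
    inits = [
        [math.log(2), 1.0, 0.5, logit(0.3), logit(0.3), math.log(3.0)],
        [math.log(2), 2.0, 0.0, logit(0.6), logit(0.1), math.log(1.5)],
        [math.log(4), 0.0, 0.0, logit(0.1), logit(0.5), math.log(8.0)],
    ]
    best = None
    for r in range(max(1, n_restarts)):
        x0 = np.array(inits[r % len(inits)][:nper])
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-9, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    kappa, oms, w = unpack(best.x)
    order = np.argsort(oms)
    return float(-best.fun), kappa, oms[order], w[order], best.x


def busted_test(aln: CodonAlignment, phy: Phylogeny,
                m0_fit: FitResult | None = None,
                freq_scheme: str = "F3X4", n_restarts: int = 3,
                null_distribution: str = "chi2_mix") -> BustedResult:
    """Gene-level test for episodic positive selection at a subset of sites
    (all branches treated as foreground).

    The unconstrained model allows a site class with omega3 >= 1; the null
    constrains omega3 = 1. Because omega3 sits on the boundary under the
    null, the default reference distribution is the equal-weight mixture of
    chi2(0), chi2(1) and chi2(2); ``null_distribution='chi2_2'`` gives the
    conservative plain chi-square alternative.
    """
    m0_fit, eng, _ = _m0_kappa_scale(aln, phy, m0_fit, freq_scheme,
                                     n_restarts=n_restarts)
    lnl_c, *_ = _busted_fit(eng, constrained=True, n_restarts=n_restarts)
    lnl_u, kappa, oms, w, _ = _busted_fit(eng, constrained=False,
                                          n_restarts=n_restarts)
    if lnl_u < lnl_c:  # the null is nested: never worse
        lnl_u = lnl_c
    stat = max(0.0, 2.0 * (lnl_u - lnl_c))
    if stat == 0.0:
        p = 1.0
    elif null_distribution == "chi2_2":
        p = float(stats.chi2.sf(stat, 2))
    else:
        p = float((stats.chi2.sf(stat, 1) + stats.chi2.sf(stat, 2)) / 3.0)
    return BustedResult(lnl_unconstrained=lnl_u, lnl_constrained=lnl_c,
                        omegas=oms, weights=w, statistic=stat, p_value=p,
                        null_distribution=null_distribution)


# ---------------------------------------------------------------------------
# Evolutionary fingerprinting

@dataclass
class FingerprintResult:
    k: int
    alphas: np.ndarray
    betas: np.ndarray
    weights: np.ndarray
    aicc_trace: dict
    lnl: float

    @property
    def dnds(self) -> np.ndarray:
        return self.betas / np.maximum(self.alphas, 1e-12)


def evolutionary_fingerprint(aln: CodonAlignment, phy: Phylogeny,
                             m0_fit: FitResult | None = None,
                             freq_scheme: str = "F3X4", k_max: int = 5,
                             n_restarts: int = 3) -> FingerprintResult:
    """Partition sites into (alpha, beta) selective classes.

    Fits general discrete bivariate rate mixtures for k = 1..k_max (weights
    free, mixture-mean rate normalized to 1) and selects k by small-sample
    AIC with n = number of codons; classes with vanishing weight are pruned.
    Per-class dN/dS is beta/alpha.
    """
    m0_fit, eng, scale = _m0_kappa_scale(aln, phy, m0_fit, freq_scheme,
                                         n_restarts=n_restarts)
    kappa = m0_fit.kappa
    n = aln.n_codons
    results = {}
    trace = {}
    for k in range(1, k_max + 1):
        lnl, w, a, b = _fit_ab_mixture(eng, kappa, scale, k,
                                       n_restarts=n_restarts)
        m = 3 * k - 1
        if n - m - 1 <= 0:
            break
        aicc = -2 * lnl + 2 * m + 2 * m * (m + 1) / (n - m - 1)
        trace[k] = float(aicc)
        results[k] = (lnl, w, a, b)
    k_best = min(trace, key=trace.get)
    lnl, w, a, b = results[k_best]
    rA, rB = _rate_components(eng, kappa)
    a, b = normalize_ab(w, a, b, rA, rB)
    keep = w > 1e-4
    w, a, b = w[keep], a[keep], b[keep]
    w = w / w.sum()
    order = np.argsort(b / np.maximum(a, 1e-12))
    return FingerprintResult(k=int(keep.sum()), alphas=a[order],
                             betas=b[order], weights=w[order],
                             aicc_trace=trace, lnl=lnl)


# ---------------------------------------------------------------------------
# Table-1-style summary

def lrt_table(fits: dict) -> pd.DataFrame:
    """Model-comparison table: one row per nested pair present in ``fits``
    (a dict model-name -> FitResult), mirroring the usual published layout
    (2ΔLnL, p, % sites with the average dN/dS of the selection class)."""
    rows = []
    for (null_m, alt_m), df in NESTED_PAIRS.items():
        if null_m not in fits or alt_m not in fits:
            continue
        lrt = likelihood_ratio_test(fits[null_m], fits[alt_m])
        alt = fits[alt_m]
        sel = alt.mixture.omegas > 1.0
        pct = float(alt.mixture.weights[sel].sum() * 100.0)
        avg = float((alt.mixture.weights[sel] * alt.mixture.omegas[sel]).sum()
                    / max(alt.mixture.weights[sel].sum(), 1e-12)) \
            if sel.any() else float("nan")
        rows.append({"comparison": f"{null_m} vs {alt_m}",
                     "freq_scheme": alt.freq_scheme,
                     "lnL_null": fits[null_m].lnl, "lnL_alt": alt.lnl,
                     "two_delta_lnl": lrt.two_delta_lnl, "df": lrt.df,
                     "p_value": lrt.p_value,
                     "pct_sites_selected": pct,
                     "avg_dnds_selected": avg})
    return pd.DataFrame(rows)
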