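"""Counting-based dN/dS (single-likelihood ancestor counting).

One joint maximum-likelihood ancestral reconstruction under the fitted
single-ratio model supplies internal-node codon states; synonymous and
nonsynonymous substitutions are then tallied along every branch, and each
codon's mutational opportunity is split into expected synonymous (ES) and
nonsynonymous (EN) site counts by single-nucleotide neighbor enumeration
with stop codons excluded (so ES + EN = 3 for every codon state).

The global ratio is dN/dS = (sum ON / sum EN) / (sum OS / sum ES) with a
nonparametric bootstrap over codon sites for the confidence interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .codon_engine import FitResult, LikelihoodEngine, TreeIndex, _structure
from .seqio import (MISSING, STANDARD_CODE, CodonAlignment, CodonFrequencies,
                    GeneticCode, Phylogeny)


@lru_cache(maxsize=32)
def codon_opportunities(code: GeneticCode, kappa: float = 1.0):
    """Per sense codon: (ES, EN) with ES + EN = 3.

    ES is 3 times the (optionally kappa-weighted) fraction of
    single-nucleotide *sense* neighbors that are synonymous; stop
    neighbors are excluded from the enumeration. With ``kappa`` != 1,
    transition neighbors carry weight kappa — the kappa-weighted variant
    of the opportunity split (unweighted counting is the default
    convention).
    """
    single, is_ts, is_syn, _ = _structure(code)
    wmat = np.where(is_ts, float(kappa), 1.0) * single
    n_syn = (wmat * is_syn).sum(axis=1)
    n_tot = wmat.sum(axis=1)
    es = 3.0 * n_syn / n_tot
    return es, 3.0 - es


@lru_cache(maxsize=4)
def substitution_path_counts(code: GeneticCode):
    """(syn, nonsyn) step counts between every codon pair, averaged over
    minimal mutational paths that avoid stop codons.

    A pair differing at d nucleotides has d! orderings of the single steps;
    orderings passing through a stop codon are excluded and the remainder
    averaged. If every ordering is invalid (rare), all orderings are used.
    """
    n = code.n_sense
    sense_index = {c: i for i, c in enumerate(code.sense_codons)}
    syn = np.zeros((n, n))
    nonsyn = np.zeros((n, n))

    def step_class(cu, cv):
        if cv in code.stop_codons:
            return None
        return 1 if code.codon_to_aa[cu] == code.codon_to_aa[cv] else 0

    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            paths = []
            for order in itertools.permutations(diffs):
                cur = ci
                s = ns = 0
                ok = True
                for p in order:
                    nxt = cur[:p] + cj[p] + cur[p + 1:]
                    cls = step_class(cur, nxt)
                    if cls is None:
                        ok = False
                        break
                    s += cls
                    ns += 1 - cls
                    cur = nxt
                if ok:
                    paths.append((s, ns))
            if not paths:  # all minimal paths cross a stop
                for order in itertools.permutations(diffs):
                    cur = ci
                    s = ns = 0
                    for p in order:
                        nxt = cur[:p] + cj[p] + cur[p + 1:]
                        aa_u = code.codon_to_aa.get(cur)
                        aa_v = code.codon_to_aa.get(nxt)
                        if aa_u is not None and aa_u == aa_v:
                            s += 1
                        else:
                            ns += 1
                        cur = nxt
                    paths.append((s, ns))
            arr = np.array(paths, dtype=float)
            syn[i, j], nonsyn[i, j] = arr.mean(axis=0)
    return syn, nonsyn


@dataclass
class AncestralAssignment:
    """Joint ML codon states for every tree node at every site."""

    states: np.ndarray  # (n_nodes, n_sites); MISSING where undetermined
    tree: TreeIndex
    method: str = "joint-ML"


def reconstruct_ancestors(aln: CodonAlignment, phy: Phylogeny,
                          m0_fit: FitResult) -> AncestralAssignment:
    """Joint ML ancestral codons by max-product dynamic programming.

    Uses the single-ratio generator and branch lengths from ``m0_fit``.
    Ties are broken deterministically toward the lowest codon index.
    Missing leaf states contribute no information and stay missing.
    """
    if m0_fit is None:
        raise ValueError("an M0 fit is required for reconstruction")
    eng = LikelihoodEngine(aln, phy, CodonFrequencies(m0_fit.freq_scheme,
                                                      m0_fit.pi))
    eng.lengths = m0_fit.lengths.copy()
    omega = m0_fit.mixture.omegas[int(np.argmax(m0_fit.mixture.weights))]
    eig, rate = eng._eigen(m0_fit.kappa, omega)
    t = eng.lengths / rate
    tree = eng.tree
    n_sites = aln.n_codons
    n_states = eng.n_states
    codes = aln.codons

    C = [None] * tree.n_nodes       # (n_sites, n_states) conditional scores
    choice = [None] * tree.n_nodes  # argmax child-state given parent state
    for v in tree.postorder:
        if v == tree.root:
            continue
        logP = np.log(np.maximum(eig.transition(t[v]), 1e-320))
        if tree.is_leaf[v]:
            obs = codes[tree.leaf_row[v]]
            Cv = np.zeros((n_sites, n_states))
            ch = np.full((n_sites, n_states), MISSING, dtype=np.int64)
            known = obs >= 0
            Cv[known] = logP[:, obs[known]].T
            ch[known] = obs[known, None]
            C[v], choice[v] = Cv, ch
        else:
            tot = np.zeros((n_sites, n_states))
            for u in tree.children[v]:
                tot += C[u]
            score = tot[:, None, :] + logP[None, :, :]
            choice[v] = np.argmax(score, axis=2)
            C[v] = np.max(score, axis=2)
    tot = np.zeros((n_sites, n_states))
    for u in tree.children[tree.root]:
        tot += C[u]
    tot += np.log(eng.pi)[None, :]
    states = np.full((tree.n_nodes, n_sites), MISSING, dtype=np.int64)
    states[tree.root] = np.argmax(tot, axis=1)
    parent_of = np.full(tree.n_nodes, -1)
    for p in range(tree.n_nodes):
        for c in tree.children[p]:
            parent_of[c] = p
    site_ix = np.arange(n_sites)
    for v in reversed(tree.postorder):
        if v == tree.root:
            continue
        ps = states[parent_of[v]]
        st = choice[v][site_ix, ps]
        states[v] = st
    return AncestralAssignment(states=states, tree=tree)


@dataclass
class SlacSiteCounts:
    """Per-codon expected (ES/EN) and observed (OS/ON) substitution counts."""

    codon: np.ndarray  # 1-based unmasked-gene coordinates
    ES: np.ndarray
    EN: np.ndarray
    OS: np.ndarray
    ON: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"codon": self.codon, "ES": self.ES,
                             "EN": self.EN, "OS": self.OS, "ON": self.ON})


def slac_counts(aln: CodonAlignment, phy: Phylogeny,
                anc: AncestralAssignment,
                kappa_weighted: bool = False,
                kappa: float = 1.0) -> SlacSiteCounts:
    """Tally per-site opportunities and substitutions on the reconstruction.

    ES/EN average the per-state neighbor split over all tree nodes with an
    assigned state (kappa-weighted when requested); OS/ON sum the
    path-averaged step counts over branches (branches into missing states
    are skipped).
    """
    code = aln.code
    es_tab, en_tab = codon_opportunities(
        code, float(kappa) if kappa_weighted else 1.0)
    syn_tab, nonsyn_tab = substitution_path_counts(code)
    tree = anc.tree
    states = anc.states
    n_sites = aln.n_codons
    es = np.zeros(n_sites)
    en = np.zeros(n_sites)
    n_assigned = np.zeros(n_sites)
    for v in range(tree.n_nodes):
        st = states[v]
        ok = st >= 0
        es[ok] += es_tab[st[ok]]
        en[ok] += en_tab[st[ok]]
        n_assigned[ok] += 1
    denom = np.maximum(n_assigned, 1)
    es /= denom
    en /= denom
    os_ = np.zeros(n_sites)
    on = np.zeros(n_sites)
    parent_of = np.full(tree.n_nodes, -1)
    for p in range(tree.n_nodes):
        for c in tree.children[p]:
            parent_of[c] = p
    for v in range(tree.n_nodes):
        p = parent_of[v]
        if p < 0:
            continue
        a, b = states[p], states[v]
        ok = (a >= 0) & (b >= 0)
        os_[ok] += syn_tab[a[ok], b[ok]]
        on[ok] += nonsyn_tab[a[ok], b[ok]]
    return SlacSiteCounts(codon=aln.site_index.copy(), ES=es, EN=en,
                          OS=os_, ON=on)


@dataclass
class SlacResult:
    """Aggregated counting-based dN/dS with bootstrap CI."""

    dn: float
    ds: float
    dnds: float
    ci_low: float
    ci_high: float
    bootstrap_reps: int
    seed: int
    site_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {"dN": self.dn, "dS": self.ds, "dN_dS": self.dnds,
                "ci_2.5": self.ci_low, "ci_97.5": self.ci_high,
                "bootstrap_reps": self.bootstrap_reps, "seed": self.seed}


def _ratio(ES, EN, OS, ON):
    ds = OS.sum() / ES.sum()
    dn = ON.sum() / EN.sum()
    return dn, ds


def slac_dnds(counts: SlacSiteCounts, bootstrap_reps: int = 1000,
              seed: int = 0) -> SlacResult:
    """Global dN/dS with a percentile bootstrap over codon sites and a
    per-site binomial test of the nonsynonymous fraction against the
    neutral expectation EN/(EN+ES)."""
    if counts.OS.sum() <= 0:
        raise ValueError("no synonymous substitutions; dN/dS undefined")
    dn, ds = _ratio(counts.ES, counts.EN, counts.OS, counts.ON)
    rng = np.random.default_rng(seed)
    n = counts.codon.size
    boots = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        bds = counts.OS[idx].sum() / counts.ES[idx].sum()
        bdn = counts.ON[idx].sum() / counts.EN[idx].sum()
        boots[b] = np.nan if bds == 0 else bdn / bds
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    pvals = np.ones(n)
    neutral_p = counts.EN / (counts.EN + counts.ES)
    for i in range(n):
        total = int(round(counts.ON[i] + counts.OS[i]))
        if total > 0:
            k = int(round(counts.ON[i]))
            k = min(k, total)
            pvals[i] = stats.binomtest(k, total, neutral_p[i]).pvalue
    table = counts.to_frame()
    # ES can be 0 at sites whose codons have no synonymous neighbors (Met/Trp)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = (counts.ON / counts.EN) - (counts.OS / counts.ES)
    table["dn_minus_ds"] = np.where(np.isfinite(diff), diff, np.nan)
    table["p_value"] = pvals
    return SlacResult(dn=float(dn), ds=float(ds), dnds=float(dn / ds),
                      ci_low=float(lo), ci_high=float(hi),
                      bootstrap_reps=bootstrap_reps, seed=seed,
                      site_table=table)


def slac_pipeline(aln: CodonAlignment, phy: Phylogeny, m0_fit: FitResult,
                  bootstrap_reps: int = 1000, seed: int = 0,
                  kappa_weighted: bool = False) -> SlacResult:
    """Reconstruction, counting, and aggregation in one call."""
    anc = reconstruct_ancestors(aln, phy, m0_fit)
    counts = slac_counts(aln, phy, anc, kappa_weighted=kappa_weighted,
                         kappa=m0_fit.kappa)
    return slac_dnds(counts, bootstrap_reps=bootstrap_reps, seed=seed)
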