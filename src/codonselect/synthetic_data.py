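"""Seeded generators for every input the pipeline consumes.

Each generator emulates one of the three data modalities the analysis
assumes — codon alignments evolved under site-class omega mixtures on a
tree, per-codon polymorphism/divergence counts under a Poisson random field
with known selection coefficients, and age–expression trajectories with a
specified trend and noise — and emits a machine-readable truth table so
recovery tests can join estimates against ground truth.

Sequence evolution samples each branch from the exact transition matrix
exp(Q t) rather than simulating individual mutation events; at these scales
that is both exact and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .codon_engine import LikelihoodEngine, MixtureSpec, _Eigen, _raw_generator
from .seqio import (STANDARD_CODE, CodonAlignment, CodonFrequencies,
                    GeneticCode, Phylogeny, equal_frequencies)


def fixture_tree(n_taxa: int, total_depth: float = 0.5,
                 shape: str = "balanced") -> Phylogeny:
    """Deterministic test phylogeny with equal root-to-tip path lengths.

    ``balanced`` builds the most balanced binary topology on ``n_taxa``
    leaves (a perfect tree when n is a power of two); ``ladder`` builds a
    caterpillar. Leaf labels are t1..tN.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    if shape == "balanced":
        def sub(names, depth):
            # subtree whose root sits `depth` above every tip
            levels = int(np.ceil(np.log2(len(names))))
            step = depth / max(levels, 1)
            half = (len(names) + 1) // 2
            parts = []
            for grp in (names[:half], names[half:]):
                if len(grp) == 1:
                    parts.append(f"{grp[0]}:{depth:.8f}")
                else:
                    parts.append(f"{sub(grp, depth - step)}:{step:.8f}")
            return "(" + ",".join(parts) + ")"
        newick = sub(labels, total_depth) + ";" if n_taxa > 1 else None
    elif shape == "ladder":
        step = total_depth / max(n_taxa - 1, 1)
        s = f"({labels[0]}:{step:.8f},{labels[1]}:{step:.8f})"
        depth = step
        for lab in labels[2:]:
            s = f"({s}:{step:.8f},{lab}:{depth + step:.8f})"
            depth += step
        newick = s + ";"
    else:
        raise ValueError(f"unknown tree shape '{shape}'")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return Phylogeny(tree)


@dataclass
class SimulationConfig:
    """Shared configuration block for the generators; ``seed`` is mandatory."""

    seed: int
    n_codons: int = 300
    kappa: float = 2.0
    mixture: MixtureSpec = None
    pi: CodonFrequencies = None
    tree: Phylogeny = None
    n_taxa: int = 8
    tree_depth: float = 1.0
    # PRF block
    gamma_profile: np.ndarray = None
    theta: float = 0.01
    T: float = 2.0
    n_chromosomes: int = 50
    # expression block
    trend: str = "flat"
    amplitude: float = 0.0
    noise_sd: float = 0.3
    n_individuals: dict = field(default_factory=lambda: {"human": 25})
    max_age: float = 80.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.mixture is None:
            self.mixture = MixtureSpec([(1.0, 0.4)])
        if self.pi is None:
            self.pi = equal_frequencies()
        if self.tree is None:
            self.tree = fixture_tree(self.n_taxa, self.tree_depth)


def simulate_codon_alignment(cfg: SimulationConfig,
                             code: GeneticCode = STANDARD_CODE):
    """Evolve a codon alignment under a site-class omega mixture.

    Root codons are drawn from pi; each site draws a class from the mixture
    and evolves along the tree with the class's transition matrices (the
    mixture-averaged rate is normalized to 1 so branch lengths are expected
    substitutions per codon). Returns the alignment and a truth DataFrame
    with per-site class label and omega.
    """
    rng = np.random.default_rng(cfg.seed)
    mix = cfg.mixture
    pi = np.asarray(cfg.pi.pi)
    n_sites = cfg.n_codons
    scale = sum(w * _raw_generator(cfg.kappa, om, pi, code)[1]
                for w, om in zip(mix.weights, mix.omegas))
    eigs = [_Eigen(_raw_generator(cfg.kappa, om, pi, code)[0], pi)
            for om in mix.omegas]

    site_class = rng.choice(len(mix.weights), size=n_sites, p=mix.weights)
    nodes = list(cfg.tree.tree.preorder_node_iter())
    states = {}
    root = nodes[0]
    states[id(root)] = rng.choice(len(pi), size=n_sites, p=pi)
    n_states = len(pi)
    for nd in nodes[1:]:
        t = (nd.edge.length or 0.0) / scale
        parent_states = states[id(nd.parent_node)]
        child = np.empty(n_sites, dtype=np.int64)
        for c in range(len(mix.weights)):
            sel = site_class == c
            if not sel.any():
                continue
            P = eigs[c].transition(t)
            P = P / P.sum(axis=1, keepdims=True)
            ps = parent_states[sel]
            u = rng.random(ps.shape[0])
            cdf = np.cumsum(P[ps], axis=1)
            child[sel] = np.minimum((u[:, None] > cdf).sum(axis=1),
                                    n_states - 1)
        states[id(nd)] = child
    taxa, rows = [], []
    for lf in cfg.tree.tree.leaf_node_iter():
        taxa.append(lf.taxon.label)
        rows.append(states[id(lf)])
    aln = CodonAlignment(taxa, np.vstack(rows), code)
    truth = pd.DataFrame({
        "codon": np.arange(1, n_sites + 1),
        "class": site_class,
        "omega": mix.omegas[site_class],
    })
    return aln, truth


def simulate_prf_site_counts(cfg: SimulationConfig):
    """Draw per-codon polymorphism/divergence counts from the PRF model.

    Means follow the same Poisson structure the selection-coefficient mapper
    evaluates: lambda_Ds = (theta/2) T, lambda_Dn = (theta/2) T Z_n h(gamma),
    lambda_Ps = (theta/2) a_n, lambda_Pn = (theta/2) a_n Z_n G_rel(gamma, n),
    with a_n the harmonic number of n-1. ``gamma_profile`` gives the true
    selection coefficient per codon (values on the 12-class grid).
    """
    from .gammamap_lite import (GAMMA_GRID, SiteCounts, fixation_factor,
                                polymorphism_factor_rel)
    rng = np.random.default_rng(cfg.seed)
    if cfg.gamma_profile is None:
        raise ValueError("gamma_profile required")
    gamma = np.asarray(cfg.gamma_profile, dtype=float)
    off = ~np.isin(gamma, GAMMA_GRID)
    if off.any():
        raise ValueError(
            f"gamma values off the 12-class grid: {np.unique(gamma[off])}")
    n = cfg.n_chromosomes
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    a_n = np.sum(1.0 / np.arange(1, n))
    half_theta = cfg.theta / 2.0
    from .slac import codon_opportunities
    es, en = codon_opportunities(STANDARD_CODE)
    z_n = np.full(gamma.size, float(en.mean() / es.mean()))
    h = np.array([fixation_factor(g) for g in gamma])
    g_rel = np.array([polymorphism_factor_rel(g, n) for g in gamma])
    lam_ds = np.full(gamma.size, half_theta * cfg.T)
    lam_dn = half_theta * cfg.T * z_n * h
    lam_ps = np.full(gamma.size, half_theta * a_n)
    lam_pn = half_theta * a_n * z_n * g_rel
    counts = SiteCounts(
        codon=np.arange(1, gamma.size + 1),
        D_n=rng.poisson(lam_dn), D_s=rng.poisson(lam_ds),
        P_n=rng.poisson(lam_pn), P_s=rng.poisson(lam_ps),
        Z_n=z_n, n=n)
    truth = pd.DataFrame({"codon": counts.codon, "gamma": gamma})
    return counts, truth


def persistent_gamma_profile(n_codons: int, blocks: list) -> np.ndarray:
    """Build a gamma profile from (start, end, gamma) 1-based closed blocks
    on a neutral (gamma=0) background."""
    prof = np.zeros(n_codons)
    for a, b, g in blocks:
        prof[a - 1:b] = g
    return prof


def simulate_snp_table(aln, taxon: str, n_chromosomes: int = 50,
                       snp_rate: float = 0.02, seed: int = 0) -> pd.DataFrame:
    """Segregating sites consistent with one taxon's sequence.

    Each codon carries a SNP with probability ``snp_rate``; the reference
    allele is the taxon's base at a uniformly chosen codon position, the
    alternate a different base, and the derived count is drawn uniformly on
    [1, n-1]. Returns the minimal SNP table (pos, ref, alt, derived_count)
    in 1-based CDS nucleotide coordinates.
    """
    rng = np.random.default_rng(seed)
    code = aln.code
    row = aln.row(taxon)
    rows = []
    for col in range(aln.n_codons):
        if row[col] < 0 or rng.random() >= snp_rate:
            continue
        codon = code.sense_codons[row[col]]
        p = int(rng.integers(0, 3))
        ref = codon[p]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        gene_codon = int(aln.site_index[col])
        rows.append({"pos": (gene_codon - 1) * 3 + p + 1, "ref": ref,
                     "alt": alt,
                     "derived_count": int(rng.integers(1, n_chromosomes))})
    return pd.DataFrame(rows, columns=["pos", "ref", "alt", "derived_count"])


def _range_anchor(x, frac):
    return x.min() + frac * max(np.ptp(x), 1e-9)


# trend(x) reaches +/- amplitude at the extreme of the transformed age axis
_TRENDS = {
    "flat": lambda x, amp: np.zeros_like(x),
    "linear": lambda x, amp: amp * (x - x.mean()) / max(np.ptp(x), 1e-9),
    "late_rise": lambda x, amp: amp * np.clip(
        (x - _range_anchor(x, 0.6)) / (0.4 * max(np.ptp(x), 1e-9)), 0, 1),
    "early_decline": lambda x, amp: -amp * np.clip(
        (_range_anchor(x, 0.4) - x) / (0.4 * max(np.ptp(x), 1e-9)), 0, 1),
}


def simulate_expression(cfg: SimulationConfig):
    """Age–expression points per species: trend(log2 age) + Gaussian noise.

    Ages are drawn uniformly on [0, max_age] per individual; the trend is
    evaluated on the log2-transformed age axis used throughout the
    expression analysis. Returns a tidy table (individual, species, region,
    age_years, expression) plus a truth copy with the noiseless trend value
    per record; split per-species series with
    :func:`codonselect.expression_resampling.split_series`.
    """
    from .expression_resampling import AGE_OFFSET
    if cfg.noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    if cfg.trend not in _TRENDS:
        raise ValueError(f"unknown trend '{cfg.trend}'")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    truths = []
    for species, n_ind in cfg.n_individuals.items():
        ages = np.sort(rng.uniform(0.0, cfg.max_age, size=n_ind))
        x = np.log2(ages + AGE_OFFSET)
        trend = _TRENDS[cfg.trend](x, cfg.amplitude)
        expr = trend + rng.normal(0.0, cfg.noise_sd, size=n_ind)
        for i in range(n_ind):
            rows.append({"individual": f"{species}_{i + 1}",
                         "species": species, "region": "PFC",
                         "age_years": float(ages[i]),
                         "expression": float(expr[i])})
            truths.append(float(trend[i]))
    df = pd.DataFrame(rows)
    truth = df.assign(trend_value=truths)
    return df, truth
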