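import math

import numpy as np
import pytest
from scipy import integrate, stats

from codonselect import seqio
from codonselect.codon_engine import (LikelihoodEngine, MixtureSpec,
                                      _Eigen, _raw_generator,
                                      build_codon_rate_matrix,
                                      discretize_beta, maximize_likelihood)
from codonselect.seqio import CodonAlignment, equal_frequencies, read_newick


@pytest.fixture(scope="module")
def pi_eq():
    return equal_frequencies()


class TestRateMatrix:
    def test_symmetric_rates_under_neutrality(self, pi_eq):
        rm = build_codon_rate_matrix(1.0, 1.0, pi_eq)
        off = rm.Q[~np.eye(61, dtype=bool)]
        permitted = off[off > 0]
        assert np.allclose(permitted, permitted[0])

    def test_kappa_omega_rate_ratio(self, code, pi_eq):
        kappa, omega = 3.0, 0.4
        Q, _ = _raw_generator(kappa, omega, pi_eq.pi)
        i = code.index("TTT")
        j_syn_ts = code.index("TTC")    # synonymous transition
        j_non_tv = code.index("TTA")    # nonsynonymous transversion
        assert Q[i, j_syn_ts] / Q[i, j_non_tv] == pytest.approx(kappa / omega)

    def test_normalized_flow_is_one(self, pi_eq):
        rm = build_codon_rate_matrix(2.5, 0.3, pi_eq)
        assert -(pi_eq.pi * np.diag(rm.Q)).sum() == pytest.approx(1.0)

    def test_rows_sum_to_zero_and_detailed_balance(self, pi_eq):
        rng = np.random.default_rng(1)
        w = rng.random(61) + 0.1
        pi = seqio.CodonFrequencies("F61", w / w.sum())
        rm = build_codon_rate_matrix(2.0, 0.5, pi)
        assert np.allclose(rm.Q.sum(axis=1), 0, atol=1e-12)
        flux = pi.pi[:, None] * rm.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_multi_nucleotide_changes_forbidden(self, code, pi_eq):
        rm = build_codon_rate_matrix(2.0, 0.5, pi_eq)
        i, j = code.index("TTT"), code.index("AAT")  # 2 positions differ
        assert rm.Q[i, j] == 0.0

    def test_invalid_inputs_rejected(self, pi_eq):
        with pytest.raises(ValueError):
            build_codon_rate_matrix(-1.0, 0.5, pi_eq)
        with pytest.raises(ValueError):
            build_codon_rate_matrix(2.0, float("nan"), pi_eq)


class TestDiscretizeBeta:
    def test_uniform_beta_gives_bin_midpoints(self):
        mix = discretize_beta(1.0, 1.0, 10)
        assert np.allclose(mix.omegas, np.arange(0.05, 1.0, 0.1), atol=1e-9)
        assert np.allclose(mix.weights, 0.1)

    def test_class_means_match_quadrature_oracle(self):
        p, q = 2.0, 5.0
        mix = discretize_beta(p, q, 10)
        edges = stats.beta.ppf(np.linspace(0, 1, 11), p, q)
        for k in range(10):
            num, _ = integrate.quad(
                lambda x: x * stats.beta.pdf(x, p, q), edges[k], edges[k + 1])
            assert mix.omegas[k] == pytest.approx(num / 0.1, abs=1e-6)
        assert float(mix.weights @ mix.omegas) == pytest.approx(2 / 7,
                                                                abs=1e-9)

    def test_invalid_shapes(self):
        with pytest.raises(ValueError):
            discretize_beta(0.0, 1.0)
        with pytest.raises(ValueError):
            discretize_beta(1.0, 1.0, K=1)


class TestPruning:
    def test_matches_exhaustive_enumeration(self, tiny_triplet, pi_eq):
        aln, phy = tiny_triplet
        eng = LikelihoodEngine(aln, phy, pi_eq)
        mix = MixtureSpec([(0.6, 0.2), (0.4, 3.0)])
        site_lnl, _ = eng.mixture_site_logliks(2.0, mix)
        scale = eng.mixture_scale(2.0, mix.weights, mix.omegas)
        brute = np.zeros(aln.n_codons)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in phy.tree.leaf_node_iter()}
        for w, om in zip(mix.weights, mix.omegas):
            Q, _ = _raw_generator(2.0, om, pi_eq.pi)
            eig = _Eigen(Q, pi_eq.pi)
            P = {t: eig.transition(lengths[t] / scale) for t in aln.taxa}
            for s in range(aln.n_codons):
                obs = aln.codons[:, s]
                lik = sum(pi_eq.pi[r]
                          * P["A"][r, obs[0]] * P["B"][r, obs[1]]
                          * P["C"][r, obs[2]] for r in range(61))
                brute[s] += w * lik
        assert np.max(np.abs(np.exp(site_lnl) - brute) / brute) < 1e-12

    def test_zero_branch_lengths_give_pi(self, pi_eq):
        phy = read_newick("(A:0.0,B:0.0,C:0.0);")
        aln = CodonAlignment(["A", "B", "C"], np.full((3, 1), 17))
        eng = LikelihoodEngine(aln, phy, pi_eq)
        lnl, _ = eng.mixture_site_logliks(2.0, MixtureSpec([(1.0, 0.5)]))
        assert np.exp(lnl[0]) == pytest.approx(pi_eq.pi[17], rel=1e-10)

    def test_duplicate_classes_equal_single_class(self, tiny_triplet, pi_eq):
        aln, phy = tiny_triplet
        eng = LikelihoodEngine(aln, phy, pi_eq)
        single, _ = eng.mixture_site_logliks(2.0, MixtureSpec([(1.0, 0.7)]))
        double, _ = eng.mixture_site_logliks(
            2.0, MixtureSpec([(0.5, 0.7), (0.5, 0.7)]))
        assert np.allclose(single, double, atol=1e-12)

    def test_transition_matrix_identity_and_rows(self, pi_eq):
        Q, rate = _raw_generator(2.0, 0.5, pi_eq.pi)
        eig = _Eigen(Q, pi_eq.pi)
        assert np.allclose(eig.transition(0.0), np.eye(61), atol=1e-10)
        rng = np.random.default_rng(2)
        for t in rng.uniform(0, 5, size=4):
            P = eig.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= 0)

    def test_likelihood_invariant_to_taxon_order_and_rerooting(self, pi_eq):
        from codonselect import synthetic_data as synth
        import dendropy
        cfg = synth.SimulationConfig(seed=5, n_codons=20, n_taxa=5,
                                     tree_depth=0.8)
        aln, _ = synth.simulate_codon_alignment(cfg)
        mix = MixtureSpec([(0.5, 0.3), (0.5, 1.2)])
        eng = LikelihoodEngine(aln, cfg.tree, pi_eq)
        base = eng.lnl(2.0, mix)
        # taxon order
        perm = [3, 0, 4, 1, 2]
        aln2 = CodonAlignment([aln.taxa[i] for i in perm],
                              aln.codons[perm], aln.code)
        assert LikelihoodEngine(aln2, cfg.tree, pi_eq).lnl(2.0, mix) == \
            pytest.approx(base, abs=1e-8)
        # rerooting (pulley principle for a reversible model)
        tree2 = dendropy.Tree(cfg.tree.tree)
        edge = tree2.leaf_nodes()[2].edge
        tree2.reroot_at_edge(edge, length1=edge.length / 2,
                             length2=edge.length / 2)
        phy2 = seqio.Phylogeny(tree2)
        assert LikelihoodEngine(aln, phy2, pi_eq).lnl(2.0, mix) == \
            pytest.approx(base, abs=1e-6)


class TestMaximizeLikelihood:
    def test_m0_recovers_simulation_truth(self, m0_sim):
        aln, tree, _ = m0_sim
        fit = maximize_likelihood(aln, tree, "M0", "F3X4", n_restarts=2)
        assert 0.3 <= fit.params["omega"] <= 0.5
        assert 1.2 <= fit.kappa <= 3.2  # truth kappa = 2

    def test_refit_from_optimum_is_stable(self, m0_sim):
        aln, tree, _ = m0_sim
        fit = maximize_likelihood(aln, tree, "M0", "F3X4", n_restarts=1)
        eng = LikelihoodEngine(
            aln, tree, seqio.CodonFrequencies(fit.freq_scheme, fit.pi))
        direct = eng.lnl(fit.kappa, fit.mixture)
        assert direct == pytest.approx(fit.lnl, abs=1e-6)

    def test_nesting_inequalities(self, m0_sim):
        aln, tree, _ = m0_sim
        fits = {m: maximize_likelihood(aln, tree, m, "F3X4", n_restarts=2)
                for m in ("M1a", "M2a", "M7", "M8")}
        # equality holds at the shared boundary optimum up to optimizer
        # termination tolerance
        assert fits["M2a"].lnl >= fits["M1a"].lnl - 1e-3
        assert fits["M8"].lnl >= fits["M7"].lnl - 1e-3

    def test_unknown_model_rejected(self, m0_sim):
        aln, tree, _ = m0_sim
        with pytest.raises(ValueError, match="unsupported model"):
            maximize_likelihood(aln, tree, "M99")
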