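import numpy as np
import pytest

from codonselect import codon_engine as ce, seqio, synthetic_data as synth
from codonselect import site_models as sm
from codonselect.codon_engine import FitResult, MixtureSpec


class TestLRT:
    def _fit(self, model, lnl):
        return FitResult(model=model, lnl=lnl, kappa=2.0,
                         mixture=MixtureSpec([(1.0, 0.5)]), params={},
                         freq_scheme="equal", pi=np.full(61, 1 / 61),
                         lengths=np.zeros(3))

    def test_statistic_and_p(self):
        res = sm.likelihood_ratio_test(self._fit("M1a", -1007.15),
                                       self._fit("M2a", -1000.0))
        assert res.two_delta_lnl == pytest.approx(14.30)
        assert res.df == 2
        assert res.p_value == pytest.approx(7.85e-4, rel=0.01)

    def test_clamped_at_zero(self):
        res = sm.likelihood_ratio_test(self._fit("M7", -999.9),
                                       self._fit("M8", -1000.0))
        assert res.two_delta_lnl == 0.0 and res.p_value == 1.0

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            sm.likelihood_ratio_test(self._fit("M1a", -1.0),
                                     self._fit("M8", -1.0))


class TestBEB:
    def test_requires_selection_model(self, planted_m0_fit,
                                      planted_selection_sim):
        aln, tree, _ = planted_selection_sim
        with pytest.raises(ValueError, match="M2a or M8"):
            sm.beb_posteriors(planted_m0_fit, aln, tree)

    def test_purifying_data_yields_no_flags(self):
        cfg = synth.SimulationConfig(seed=21, n_codons=150, n_taxa=8,
                                     tree_depth=1.0,
                                     mixture=MixtureSpec([(1.0, 0.2)]))
        aln, _ = synth.simulate_codon_alignment(cfg)
        fit = sm.fit_site_model(aln, cfg.tree, "M2a", "F3X4",
                                optimize_branch_lengths=False, n_restarts=2)
        table = sm.beb_posteriors(fit, aln, cfg.tree)
        assert table.flag.mean() <= 0.01
        assert np.all((table.posterior >= 0) & (table.posterior <= 1))


class TestREL:
    def test_monomorphic_alignment_gives_no_evidence(self):
        phy = seqio.read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = seqio.CodonAlignment(["A", "B", "C", "D"],
                                   np.tile(np.arange(20) % 40, (4, 1)))
        table = sm.rel_posteriors(aln, phy, n_restarts=1)
        assert not table.flag.any()
        # posterior odds match prior odds when data carry no rate contrast
        assert np.all(table.bayes_factor < 50)


class TestFUBAR:
    def test_matches_prior_importance_sampling_oracle(self):
        """Gibbs grid posterior vs direct Monte-Carlo integration over the
        Dirichlet weight prior on a 5-codon toy with a coarse lattice."""
        cfg = synth.SimulationConfig(seed=33, n_codons=5, n_taxa=6,
                                     tree_depth=0.8,
                                     mixture=MixtureSpec([(1.0, 1.0)]))
        aln, _ = synth.simulate_codon_alignment(cfg)
        m0 = ce.maximize_likelihood(aln, cfg.tree, "M0", "equal",
                                    n_restarts=1)
        table = sm.fubar_posteriors(aln, cfg.tree, m0_fit=m0,
                                    freq_scheme="equal", grid_size=4,
                                    n_samples=4000, burn_in=1000, thin=2,
                                    chains=2, seed=0)
        # oracle: importance sampling from the Dirichlet prior
        fit, eng, scale = sm._m0_kappa_scale(aln, cfg.tree, m0, "equal")
        rates = sm.fubar_grid(4)
        pairs = [(a, b) for a in rates for b in rates]
        logf = sm._ab_site_logliks(eng, fit.kappa, pairs, scale)
        L = np.maximum(np.exp(logf - logf.max(axis=0)).T, 1e-300)
        pos = np.array([b > a for a, b in pairs])
        rng = np.random.default_rng(1)
        W = rng.dirichlet(np.full(len(pairs), 0.5), size=40_000)
        loglik = np.log(W @ L.T).sum(axis=1)
        iw = np.exp(loglik - loglik.max())
        iw /= iw.sum()
        r = (W[:, pos] @ L[:, pos].T) / (W @ L.T)
        oracle = iw @ r
        mc_se = np.sqrt((iw ** 2).sum()) * 0.5  # conservative per-site scale
        assert np.max(np.abs(table.posterior - oracle)) < max(3 * mc_se,
                                                              0.05)

    def test_posteriors_in_unit_interval(self, planted_selection_sim,
                                         planted_m0_fit):
        aln, tree, _ = planted_selection_sim
        table = sm.fubar_posteriors(aln, tree, m0_fit=planted_m0_fit,
                                    n_samples=600, burn_in=200, seed=2)
        assert np.all((table.posterior >= 0) & (table.posterior <= 1))
        assert table.notes["rhat_pos_weight"] == pytest.approx(1.0, abs=0.2)


class TestConsensus:
    def _table(self, method, flags):
        flags = np.asarray(flags, dtype=bool)
        return sm.SitePosteriorTable(method=method,
                                     codon=np.arange(1, flags.size + 1),
                                     posterior=flags.astype(float),
                                     flag=flags, cutoff=0.9)

    def test_threshold_logic(self):
        rep = sm.consensus_sites([self._table("BEB", [1, 1, 0]),
                                  self._table("REL", [0, 1, 0]),
                                  self._table("FUBAR", [0, 1, 1])],
                                 min_methods=2)
        assert list(rep.consensus) == [2]
        assert list(rep.strict) == [2]

    def test_single_method_site_excluded(self):
        rep = sm.consensus_sites([self._table("BEB", [1, 0]),
                                  self._table("FUBAR", [0, 0])], 2)
        assert rep.consensus.size == 0

    def test_strict_subset_of_consensus(self):
        rng = np.random.default_rng(0)
        tables = [self._table(m, rng.random(30) < 0.3)
                  for m in ("BEB", "REL", "FUBAR")]
        rep = sm.consensus_sites(tables, 2)
        assert set(rep.strict) <= set(rep.consensus)

    def test_coordinate_mismatch_rejected(self):
        t1 = self._table("BEB", [1, 0])
        t2 = sm.SitePosteriorTable(method="REL", codon=np.array([5, 6]),
                                   posterior=np.zeros(2),
                                   flag=np.zeros(2, bool), cutoff=50)
        with pytest.raises(ValueError, match="coordinates"):
            sm.consensus_sites([t1, t2])


class TestBusted:
    def test_nesting_on_purifying_and_selected_data(self, planted_m0_fit,
                                                    planted_selection_sim):
        aln, tree, _ = planted_selection_sim
        res = sm.busted_test(aln, tree, m0_fit=planted_m0_fit, n_restarts=1)
        assert res.lnl_constrained <= res.lnl_unconstrained + 1e-9
        assert res.omegas[0] <= res.omegas[1] <= 1.0 + 1e-9
        assert res.omegas[2] >= 1.0 - 1e-9
        # strong planted selection on every branch must be detected
        assert res.p_value < 0.01

    def test_null_data_not_rejected(self):
        cfg = synth.SimulationConfig(seed=8, n_codons=150, n_taxa=6,
                                     tree_depth=0.8,
                                     mixture=MixtureSpec([(0.8, 0.2),
                                                          (0.2, 1.0)]))
        aln, _ = synth.simulate_codon_alignment(cfg)
        res = sm.busted_test(aln, cfg.tree, n_restarts=1)
        assert res.p_value > 0.05

    def test_conservative_chi2_option(self, planted_m0_fit,
                                      planted_selection_sim):
        aln, tree, _ = planted_selection_sim
        a = sm.busted_test(aln, tree, m0_fit=planted_m0_fit, n_restarts=1)
        b = sm.busted_test(aln, tree, m0_fit=planted_m0_fit, n_restarts=1,
                           null_distribution="chi2_2")
        assert b.p_value >= a.p_value  # plain chi2(2) is conservative


class TestFingerprint:
    def test_recovers_two_class_structure(self):
        hits = 0
        n_rep = 8
        for r in range(n_rep):
            cfg = synth.SimulationConfig(
                seed=300 + r, n_codons=200, n_taxa=8, tree_depth=1.5,
                mixture=MixtureSpec([(0.6, 0.1), (0.4, 1.5)]))
            aln, _ = synth.simulate_codon_alignment(cfg)
            fp = sm.evolutionary_fingerprint(aln, cfg.tree, k_max=3,
                                             n_restarts=1)
            hits += fp.k == 2
        assert hits >= int(0.6 * n_rep)

    def test_class_definitions(self, planted_selection_sim, planted_m0_fit):
        aln, tree, _ = planted_selection_sim
        fp = sm.evolutionary_fingerprint(aln, tree, m0_fit=planted_m0_fit,
                                         k_max=3, n_restarts=1)
        assert fp.weights.sum() == pytest.approx(1.0)
        assert np.allclose(fp.dnds, fp.betas / fp.alphas)
        assert fp.k == len(fp.weights)
        # planted data: a purifying class and a positive class must appear
        assert fp.dnds.min() < 0.5 and fp.dnds.max() > 1.5
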