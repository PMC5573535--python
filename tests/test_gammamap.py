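import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from codonselect import seqio, synthetic_data as synth
from codonselect.gammamap_lite import (GAMMA_GRID, PopulationSample,
                                       PriorSpec, SiteCounts,
                                       classify_and_summarize,
                                       derive_site_counts,
                                       enumerate_single_codon_posterior,
                                       fixation_factor, gamma_loglik_matrix,
                                       gamma_site_loglik, parsimony_ancestor,
                                       polymorphism_factor_rel, prf_factors,
                                       run_gammamap_mcmc)


class TestPrfKernels:
    def test_neutral_normalization(self):
        h, g = prf_factors(0.0, 20)
        assert h == pytest.approx(1.0, abs=1e-12)
        assert g == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("gamma", [0.25, 1.0, 5.0, 10.0, 50.0])
    def test_fixation_reflection_identity(self, gamma):
        ratio = fixation_factor(gamma) / fixation_factor(-gamma)
        assert ratio == pytest.approx(math.exp(gamma), rel=1e-12)

    def test_kernels_monotone_on_grid(self):
        # grid is ordered beneficial -> deleterious
        h = [fixation_factor(g) for g in GAMMA_GRID]
        grel = [polymorphism_factor_rel(g, 50) for g in GAMMA_GRID]
        assert np.all(np.diff(h) < 0)
        assert np.all(np.diff(grel) < 0)

    def test_g_matches_independent_quadrature(self):
        # fixed-order Gauss-Legendre as an independent integration route
        from codonselect.gammamap_lite import _spectrum_integrand
        x, w = np.polynomial.legendre.leggauss(400)
        q = 0.5 * (x + 1.0)
        for gamma in (5.0, -10.0):
            gl = 0.5 * sum(wi * _spectrum_integrand(qi, gamma, 30)
                           for qi, wi in zip(q, w))
            rel = polymorphism_factor_rel(gamma, 30)
            gl_rel = gl / (0.5 * sum(
                wi * _spectrum_integrand(qi, 0.0, 30)
                for qi, wi in zip(q, w)))
            assert rel == pytest.approx(gl_rel, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fixation_factor(float("inf"))
        with pytest.raises(ValueError):
            prf_factors(1.0, 1)


class TestParsimonyAncestor:
    def _aln(self, code, rows):
        taxa = ["human", "chimpanzee", "orangutan", "macaque"]
        idx = [[code.index(c) for c in row] for row in rows]
        return seqio.CodonAlignment(taxa, np.array(idx))

    def test_all_identical(self, code):
        aln = self._aln(code, [["ATG"]] * 4)
        anc = parsimony_ancestor(aln)
        assert anc[0] == code.index("ATG")

    def test_human_specific_change(self, code):
        aln = self._aln(code, [["GTG"], ["ATG"], ["ATG"], ["ATG"]])
        anc = parsimony_ancestor(aln)
        assert anc[0] == code.index("ATG")

    def test_two_vs_two_split_is_ambiguous(self, code):
        aln = self._aln(code, [["ATG"], ["ATG"], ["GTG"], ["GTG"]])
        anc = parsimony_ancestor(aln)
        assert anc[0] == seqio.MISSING

    def test_missing_taxon_raises(self, code):
        aln = seqio.CodonAlignment(["human", "chimpanzee", "orangutan"],
                                   np.zeros((3, 1), dtype=int))
        with pytest.raises(ValueError, match="macaque"):
            parsimony_ancestor(aln)


class TestDeriveSiteCounts:
    def _setup(self, code, human_codon, anc_codon, snp_rows):
        taxa = ["human", "chimpanzee", "orangutan", "macaque"]
        idx = [code.index(human_codon)] + [code.index(anc_codon)] * 3
        aln = seqio.CodonAlignment(taxa, np.array(idx)[:, None])
        anc = np.array([code.index(anc_codon)])
        sample = PopulationSample(
            "human", 10, pd.DataFrame(
                snp_rows, columns=["codon", "codon_pos", "ref", "alt",
                                   "derived_count"]))
        return derive_site_counts(aln, sample, anc, "human")

    def test_nonsynonymous_fixed_difference(self, code):
        counts = self._setup(code, "GTG", "ATG", [])
        assert counts.D_n[0] == 1 and counts.D_s[0] == 0
        assert counts.P_n[0] == 0 and counts.P_s[0] == 0

    def test_synonymous_snp(self, code):
        counts = self._setup(code, "TTT", "TTT",
                             [[1, 3, "T", "C", 3]])  # TTT<->TTC
        assert counts.P_s[0] == 1 and counts.P_n[0] == 0
        assert counts.D_n[0] == 0 and counts.D_s[0] == 0

    def test_identical_everything_gives_zero_counts(self, code):
        counts = self._setup(code, "ATG", "ATG", [])
        assert (counts.D_n[0] == counts.D_s[0] == counts.P_n[0]
                == counts.P_s[0] == 0)

    def test_inconsistent_snp_allele_raises(self, code):
        with pytest.raises(ValueError, match="inconsistent"):
            self._setup(code, "TTT", "TTT", [[1, 3, "G", "A", 2]])


def _counts(n_codons=1, **kw):
    base = dict(codon=np.arange(1, n_codons + 1),
                D_n=np.zeros(n_codons), D_s=np.zeros(n_codons),
                P_n=np.zeros(n_codons), P_s=np.zeros(n_codons),
                Z_n=np.full(n_codons, 3.0), n=20)
    base.update(kw)
    return SiteCounts(**base)


class TestLikelihood:
    def test_no_data_limit_is_flat_in_gamma(self):
        c = _counts(3)
        ll = gamma_loglik_matrix(c, theta=1e-12, T=1.0)
        assert np.allclose(ll - ll[:, [0]], 0.0, atol=1e-9)

    def test_simulated_selection_favored(self):
        prof = np.full(50, 10.0)
        cfg = synth.SimulationConfig(seed=3, n_codons=50, gamma_profile=prof,
                                     theta=0.05, T=2.0, n_chromosomes=20)
        counts, _ = synth.simulate_prf_site_counts(cfg)
        ll_pos = gamma_site_loglik(counts, 10.0, 0.05, 2.0).sum()
        ll_neg = gamma_site_loglik(counts, -10.0, 0.05, 2.0).sum()
        assert ll_pos > ll_neg

    def test_total_loglik_invariant_to_codon_order(self):
        rng = np.random.default_rng(0)
        c = _counts(20, D_n=rng.poisson(1.0, 20).astype(float),
                    D_s=rng.poisson(0.5, 20).astype(float))
        ll = gamma_loglik_matrix(c, 0.01, 2.0)
        perm = rng.permutation(20)
        c2 = _counts(20, D_n=c.D_n[perm], D_s=c.D_s[perm])
        ll2 = gamma_loglik_matrix(c2, 0.01, 2.0)
        assert ll.sum() == pytest.approx(ll2.sum(), rel=1e-12)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            gamma_loglik_matrix(_counts(), theta=0.0, T=1.0)


class TestMcmc:
    def test_identical_seed_identical_output(self):
        c = _counts(5, D_n=np.array([2., 0, 1, 0, 0]))
        a = run_gammamap_mcmc(c, iterations=500, thin=5, chains=1, seed=7)
        b = run_gammamap_mcmc(c, iterations=500, thin=5, chains=1, seed=7)
        assert np.array_equal(a.posterior, b.posterior)
        assert np.allclose(a.posterior.sum(axis=1), 1.0)

    def test_single_codon_matches_enumeration(self):
        c = _counts(1, D_n=np.array([3.0]), D_s=np.array([1.0]),
                    P_n=np.array([1.0]), P_s=np.array([2.0]))
        prof = run_gammamap_mcmc(c, iterations=20_000, thin=10, chains=2,
                                 seed=5)
        exact = enumerate_single_codon_posterior(c)
        # kept draws ~3600; allow generous Monte-Carlo slack
        assert np.max(np.abs(prof.posterior[0] - exact)) < 0.05

    def test_persistence_smooths_neighboring_sites(self):
        prof_truth = synth.persistent_gamma_profile(60, [(21, 30, 10.0)])
        cfg = synth.SimulationConfig(seed=9, n_codons=60,
                                     gamma_profile=prof_truth, theta=0.02,
                                     T=2.0, n_chromosomes=20)
        counts, _ = synth.simulate_prf_site_counts(cfg)
        cors = []
        for p in (0.0, 0.5, 0.9):
            prof = run_gammamap_mcmc(counts, iterations=4000, thin=5,
                                     chains=1, seed=11, fix_p=p)
            cum = prof.cumulative_p(1.0)
            cors.append(np.corrcoef(cum[:-1], cum[1:])[0, 1])
        assert cors[0] < cors[2]  # stronger coupling at high persistence

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            run_gammamap_mcmc(_counts(0), iterations=100)


class TestClassification:
    def _profile(self, post):
        from codonselect.gammamap_lite import SelectionProfile
        return SelectionProfile(codon=np.arange(1, post.shape[0] + 1),
                                posterior=post, grid=GAMMA_GRID,
                                diagnostics={}, settings={})

    def test_all_neutral_mass_gives_empty_selection(self):
        post = np.zeros((5, 12))
        post[:, list(GAMMA_GRID).index(0.0)] = 1.0
        out = classify_and_summarize(self._profile(post))
        assert out["selected"].empty

    def test_impossible_threshold_gives_empty_set(self):
        post = np.zeros((5, 12))
        post[:, 0] = 1.0  # all mass at gamma=100
        out = classify_and_summarize(self._profile(post), threshold=1.01)
        assert out["selected"].empty

    def test_selected_table_schema(self, code):
        post = np.zeros((2, 12))
        post[0, 0] = 1.0                        # gamma=100
        post[1, list(GAMMA_GRID).index(0.0)] = 1.0
        anc = np.array([code.index("ATG"), code.index("TTT")])
        der = np.array([code.index("GTG"), code.index("TTT")])
        out = classify_and_summarize(self._profile(post), ancestor=anc,
                                     derived=der, lineage="human")
        assert list(out["selected"].columns) == [
            "lineage", "codon", "ancestral_aa", "derived_aa", "Pr"]
        row = out["selected"].iloc[0]
        assert (row["ancestral_aa"], row["derived_aa"]) == ("Met", "Val")
        assert row["Pr"] == pytest.approx(1.0)


class TestGenerators:
    def test_theta_zero_gives_all_zero_counts(self):
        cfg = synth.SimulationConfig(seed=1, n_codons=30,
                                     gamma_profile=np.zeros(30), theta=0.0)
        counts, _ = synth.simulate_prf_site_counts(cfg)
        assert counts.D_n.sum() == 0 and counts.P_s.sum() == 0

    def test_off_grid_gamma_rejected(self):
        cfg = synth.SimulationConfig(seed=1, n_codons=3,
                                     gamma_profile=np.array([0.0, 2.5, 0.0]))
        with pytest.raises(ValueError, match="off the 12-class grid"):
            synth.simulate_prf_site_counts(cfg)

    def test_divergence_mean_matches_theta_T(self):
        cfg = synth.SimulationConfig(seed=2, n_codons=10_000,
                                     gamma_profile=np.zeros(10_000),
                                     theta=0.02, T=3.0)
        counts, _ = synth.simulate_prf_site_counts(cfg)
        mean, expect = counts.D_s.mean(), 0.02 * 3.0 / 2.0
        se = math.sqrt(expect / 10_000)
        assert abs(mean - expect) < 3 * se

    def test_selected_block_shows_prf_dn_enrichment(self):
        n = 20_000
        prof = np.concatenate([np.full(n // 2, 50.0), np.zeros(n // 2)])
        cfg = synth.SimulationConfig(seed=3, n_codons=n, gamma_profile=prof,
                                     theta=0.02, T=3.0)
        counts, _ = synth.simulate_prf_site_counts(cfg)
        ratio = (counts.D_n[:n // 2].mean() / counts.D_n[n // 2:].mean())
        h50 = fixation_factor(50.0)
        assert ratio == pytest.approx(h50, rel=0.1)
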