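import numpy as np
import pytest

from codonselect import codon_engine as ce
from codonselect import seqio, synthetic_data as synth


@pytest.fixture(scope="session")
def code():
    return seqio.STANDARD_CODE


@pytest.fixture()
def tiny_triplet():
    """3-taxon star tree with a 2-codon alignment (enumeration-oracle size)."""
    phy = seqio.read_newick("(A:0.3,B:0.2,C:0.4);")
    aln = seqio.CodonAlignment(["A", "B", "C"],
                               np.array([[0, 5], [7, 5], [30, 2]]))
    return aln, phy


@pytest.fixture(scope="session")
def m0_sim():
    """Single-ratio simulation (omega*=0.4) reused by recovery tests."""
    cfg = synth.SimulationConfig(seed=11, n_codons=500, n_taxa=12,
                                 tree_depth=1.0,
                                 mixture=ce.MixtureSpec([(1.0, 0.4)]))
    aln, truth = synth.simulate_codon_alignment(cfg)
    return aln, cfg.tree, truth


@pytest.fixture(scope="session")
def planted_selection_sim():
    """Mixture simulation with 10% of codons at omega=5 on a 21-taxon tree
    (the species count of the emulated study), primate-scale divergence."""
    cfg = synth.SimulationConfig(
        seed=42, n_codons=300, n_taxa=21, tree_depth=1.0,
        mixture=ce.MixtureSpec([(0.55, 0.15), (0.35, 1.0), (0.10, 5.0)]))
    aln, truth = synth.simulate_codon_alignment(cfg)
    planted = truth["omega"].to_numpy() == 5.0
    return aln, cfg.tree, planted


@pytest.fixture(scope="session")
def planted_m0_fit(planted_selection_sim):
    aln, tree, _ = planted_selection_sim
    return ce.maximize_likelihood(aln, tree, "M0", "F3X4", n_restarts=2)
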