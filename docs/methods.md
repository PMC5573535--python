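# Methods

`codonselect` reimplements, as one tested pipeline, the standard battery of
molecular-evolution analyses applied to a single protein-coding gene across
a clade: site-model positive-selection inference with cross-method site
detection, counting-based dN/dS, a gene-level episodic-selection test,
evolutionary fingerprinting, a population-genetics–phylogenetics scan for
lineage-specific selection coefficients, and a permutation test for
age-dependent expression divergence. This note records the models, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions a maintainer would want
written down.

## Codon substitution core

Rate matrices follow the Goldman–Yang (GY94) parameterization over the 61
sense codons of the standard genetic code: a change between codons one
nucleotide apart has rate π_j, multiplied by κ for transitions and ω for
nonsynonymous changes; instantaneous multi-nucleotide changes are
forbidden. Stop codons are excluded throughout; equilibrium frequencies
come from one of three schemes — `equal` (1/61), `F3X4` (products of
position-specific nucleotide frequencies renormalized over sense codons),
or `F61` (empirical codon counts). Both empirical schemes carry a 0.5
pseudocount (per codon for F61, per positional nucleotide for F3X4):
zero-frequency states break the reversibility scaling and are never
observed merely because an alignment is short.

Each generator is scaled so one unit of branch length is one expected
substitution per codon; for site-class mixtures the scaling uses the
mixture-averaged rate, so branch lengths remain comparable across models.
Likelihoods use Felsenstein pruning vectorized over alignment columns with
per-site rescaling; transition matrices come from the symmetric-form
eigendecomposition of the reversible generator, making the thousands of
(ω, branch-length) combinations needed by the grid methods cheap. Columns
containing a gap or ambiguous codon are treated as missing data for that
taxon (summing over all 61 states), not dropped, so site counts and
coordinates are preserved. All user-facing codon coordinates are 1-based
positions in the unmasked gene, before any mask (such as a tandem-repeat
region excluded from analysis) is applied.

ML fitting is bounded L-BFGS-B on transformed parameters (log κ with
κ ∈ [0.1, 20], log ω with ω ∈ [1e-4, 50], proportions through
logistic/softmax maps, beta shapes in [0.05, 32]) with dispersed
deterministic restarts (default 5; the first restart of each selection
model sits near its null boundary so the nested optimum is always
reachable). The logistic bounds are ±15 — wide enough that boundary nulls
(p0 → 1, p2 → 0) are attainable to well below the reported lnL precision.
The default convergence target is 1e-8 on lnL (mapped to the optimizer's
relative tolerance using the |lnL| scale); bulk simulation studies use a
looser 1e-5 target, which only matters through the clamped LRT statistic.
Branch lengths are estimated once under the single-ratio model (M0) and
held fixed for the site models — the common two-stage convention — with a
switch for joint optimization; simulation studies that know the true
lengths may skip the re-estimation.

The beta distribution of M7/M8 is discretized into K = 10 equal-weight
classes represented by their conditional bin means (closed form via the
regularized incomplete beta function). Bin means rather than medians give
lower discretization bias; the choice is a documented switch in the code.

## Site models, LRTs, and site detection

The model battery is M0, M1a (nearly neutral), M2a (M1a plus a class with
ω ≥ 1), M7 (beta), and M8 (beta plus a spike at ω_s ≥ 1). Both
likelihood-ratio tests (M1a vs M2a, M7 vs M8) use χ² with 2 degrees of
freedom and clamp the statistic at zero. Because the alternative's extra
parameters sit partly on the boundary under the null, the χ²(2) reference
is conservative; the calibration experiment below confirms type-I error at
or below nominal.

Three site-detection routes are implemented:

- **BEB** (Bayes empirical Bayes) under M2a or M8: posterior probability
  that a codon belongs to the positive-selection class, integrating
  parameter uncertainty over 10-point uniform grids per free parameter
  (M2a: p0, p1 over the probability triangle, ω0 ∈ (0,1), ω2 ∈ (1,11);
  M8: p0, p and q over (0,2), ω_s ∈ (1,11)), with branch lengths, κ, and
  the rate scaling held at their ML values. Detection cutoff 0.90.
- **REL**-style empirical Bayes: a 3-class general discrete bivariate
  (α, β) distribution (synonymous and nonsynonymous rate per site) fitted
  by ML, per-site Bayes factor for β > α, cutoff BF ≥ 50. Known
  limitation: when the gene truly contains a neutral site class, one
  fitted class often lands with β marginally above α and absorbs neutral
  sites, inflating REL's flag rate — this is intrinsic to the method and
  is the reason the pipeline's consensus rule demands agreement of at
  least two methods before calling a site.
- **FUBAR-style grid posterior**: site likelihoods precomputed on a
  20×20 (α, β) lattice (values quadratically spaced on [0, 8], dense near
  zero), symmetric Dirichlet(0.5) prior over lattice weights, Gibbs
  sampling alternating site allocations and weight updates (2 chains,
  2000 sweeps, 500 burn-in, thin 5), Rao-Blackwellized per-site posterior
  of β > α, cutoff 0.90. Split-R̂ on the total positive-selection weight
  is reported; R̂ > 1.1 marks the table as unconverged.

The consensus report flags a codon as a positive-selection target when at
least `min_methods` (default 2) of the supplied tables flag it, and keeps
the strict all-methods set separately.

The episodic-selection test fits an unconstrained 3-class mixture
ω1 ≤ ω2 ≤ 1 ≤ ω3 (all branches treated as foreground) against a null with
ω3 = 1. Because ω3 sits on the boundary under the null, the default
reference distribution is the equal-weight mixture of χ²(0), χ²(1), χ²(2);
a plain χ²(2) option is available as a conservative alternative.

Evolutionary fingerprinting fits general discrete bivariate (α_c, β_c)
mixtures for k = 1..5 and selects k by small-sample AIC (AICc, n = number
of codons). During fitting the overall rate scale stays free — branch
lengths are held fixed, so constraining the mixture-mean rate to 1 would
force systematic misfit that spuriously favors extra classes; the
normalization to mean rate 1 is applied only when reporting class values
(per-class dN/dS = β/α is unaffected). Classes with vanishing weight
(< 1e-4) are pruned.

## Counting-based dN/dS (SLAC)

A single joint ML ancestral reconstruction (max-product dynamic
programming under the fitted M0 generator, ties broken toward the lowest
codon index) supplies internal-node states. Per codon state, the
mutational opportunity splits into expected synonymous/nonsynonymous site
counts by single-nucleotide neighbor enumeration with stops excluded, so
ES + EN = 3 exactly (ES = 0 is possible — Met and Trp have no synonymous
neighbors). Observed substitutions are tallied per branch; branch changes
spanning several nucleotides are averaged over the minimal mutational
paths that avoid stop codons (all orderings are used in the rare case
every path crosses a stop). Opportunities are averaged over all assigned
node states; κ-weighted opportunity counting is available as a switch-off
default (unweighted counting is the baseline because implementations
differ). The global ratio is (ΣON/ΣEN)/(ΣOS/ΣES) with a nonparametric
percentile bootstrap over codons (default 1000 replicates) for the 95%
interval, and a per-site two-sided binomial test of the nonsynonymous
fraction against the neutral expectation EN/(EN+ES) (fractional counts
from path averaging are rounded for the test only). Like all counting
estimators, the ratio is modestly biased toward 1 — in the recovery
experiments roughly +15% relative at ω = 0.2 and −9% at ω = 1 — because
reconstruction error and uniform path averaging misattribute a small
fraction of substitution classes; the ML estimate from the same data does
not share this bias.

## Selection-coefficient mapping (gammaMap-style)

The lineage scan combines within-species polymorphism and
ancestor-polarized divergence per codon: D_n, D_s (fixed differences vs
the parsimony ancestor), P_n, P_s (segregating sites), and the
opportunity ratio Z_n of the ancestral codon. The ancestral state is the
sense codon minimizing total nucleotide changes to the two ingroup and
two outgroup reference sequences; ties (e.g. 2-vs-2 splits, which cannot
be polarized) are flagged ambiguous and excluded.

Counts are modeled as independent Poissons with the classic
Poisson-random-field means: λ_Ds = (θ/2)T, λ_Dn = (θ/2)T·Z_n·h(γ),
λ_Ps = (θ/2)a_n, λ_Pn = (θ/2)a_n·Z_n·G_rel(γ, n), where
h(γ) = γ/(1−e^(−γ)) is the relative fixation probability (h(0) = 1 by
continuity; computed in log space so the identity h(γ)/h(−γ) = e^γ holds
to machine precision even for the inviable class), G_rel is the relative
expected number of detectable segregating sites from adaptive quadrature
of the PRF frequency spectrum, and a_n is the harmonic number of n−1.
γ is the population-scaled coefficient entering h directly (no extra
factor-of-two convention), and lives on the fixed 12-value grid
{100, 50, 10, 5, 1, 0, −1, −5, −10, −50, −100, −500}. This deliberately
replaces the original tool's full codon-path mutation likelihood (with κ)
by the PRF skeleton while keeping its grid, priors, persistence structure
and MCMC design; output diagnostics carry a note to that effect.

Priors: θ and T lognormal (defaults LogNormal(log 10⁻³, 1) and
LogNormal(0, 1) — weakly informative around typical per-site diversity
and divergence), persistence p uniform, class weights uniform Dirichlet,
neutral codon frequencies 1/61. The sampler is Metropolis-within-Gibbs:
per-codon γ classes follow a first-order persistence chain (adjacent
codons share γ with probability p, else draw from the Dirichlet weights)
and are block-updated exactly by forward filtering / backward sampling —
single-site sweeps mix far too slowly through long runs of uninformative
codons under high persistence; copy/fresh indicator augmentation makes
the weight and p updates conjugate; θ and T use log-scale random-walk
Metropolis (step 0.3). The path-sampling kernel is JIT-compiled when
numba is available, with an identical pure-Python fallback. Defaults are two chains of
100,000 iterations, thinning 10, 10% burn-in (the burn-in fraction is the
package's choice); chains are compared by split-R̂ on θ, T, p and merged,
with R̂ > 1.1 downgrading the run to a warning rather than an error. A
codon is called a positive-selection target when the cumulative posterior
P(γ ≥ 1) exceeds 0.80; the γ > 0 variant of the call is a config option
(on this grid the two coincide, since no grid value lies in (0, 1)).

A single-codon oracle (Gauss–Hermite quadrature over θ and T under their
lognormal priors, exact summation over the grid) verifies the sampler.

## Expression-trajectory envelope

For each species × brain-region series, expression is lowess-smoothed
against x = log2(age + 0.75) (the offset approximates a human gestation so
age 0 maps to a finite coordinate; species-specific offsets are
configurable). Defaults: span 0.5, 3 robustness iterations, 100-point
evaluation grid over the observed age range — the span and grid are
package choices exposed in config. The null of constant expression over
the lifespan is simulated by permuting expression values across
individuals within the series (B = 1000), refitting the lowess per
permutation on the same grid, and taking pointwise 2.5%/97.5%
percentiles. Envelopes are built per series separately; grid points where
the observed curve leaves the band are flagged with direction and
converted to age intervals in the comparative report. Series with fewer
than 8 individuals are rejected as too small for stable tail percentiles,
as are B < 100 replicates.

## Synthetic-data generators and what passing tests show

All generators are seed-deterministic and emit truth tables aligned to the
analysis coordinate conventions.

- **Codon alignments** evolve root codons drawn from π along a fixture
  tree by exact transition-matrix sampling per branch (not event-level
  simulation), with per-site classes drawn from the configured ω mixture.
  They emulate a single-gene, recombination-free, indel-free history with
  site-independent evolution and a constant synonymous rate — matching
  the assumptions of the fitted models. They do not emulate alignment
  error, indels, recombination, CpG or context effects, or synonymous
  rate variation, so passing recovery tests demonstrates correctness of
  the inference machinery, not robustness to those real-data violations.
- **PRF counts** are Poisson draws from exactly the means the scan
  evaluates, with block-structured γ profiles for persistence studies; a
  generator/likelihood self-consistency that is intended (the scan is
  verified against its own model class, not against a Wright–Fisher
  simulator).
- **Expression series** draw ages uniformly over the lifespan and add
  Gaussian noise around a configurable trend (flat, linear, late-life
  rise, early decline) evaluated on the log2 age axis.

Study designs used by the verification experiments (tests and the
reproduction script):

- LRT calibration: 200 simulations under a nearly-neutral null
  (70% ω = 0.3, 30% ω = 1), 8 taxa, 200 codons, depth 1.
- Recovery: single-ratio simulations at ω ∈ {0.2, 0.4, 1.0}, 12 taxa,
  500 codons; ML ω̂ and the counting estimate both within 20% of truth.
- Site detection: 300 codons with 10% planted at ω = 5 on a balanced
  21-taxon tree (the species count of the kind of primate ortholog panel
  the pipeline targets) with root-to-tip depth 1 expected
  substitutions/codon — deep enough for per-site information, shallow
  enough that ω = 5 sites (which evolve ~4× the gene average) are not
  saturated.
- Selection-coefficient recovery: 200 codons with 10 isolated γ = 50
  codons spaced along a neutral background (isolated, so per-codon
  detection is measured without genuine posterior spillover between
  neighboring selected sites being scored as false positives; persistence
  smoothing has its own property test), θ = 0.01, T = 2, n = 50
  chromosomes, with sampler runs reduced to 20,000 iterations (2 chains,
  thin 10).
- Envelope coverage: 100 null series of 25 individuals, B = 1000.

## Degenerate inputs and tie-breaks

Frame errors, internal stops, duplicate taxa, tree/alignment leaf
mismatches, negative branch lengths, out-of-bounds or total masks, SNPs
off the coding region or inconsistent with the sequence, and empty count
tables all raise immediately with the offending taxon/codon named. A
terminal stop column is dropped silently (ordinary CDS convention).
Reconstruction ties go to the lowest codon index; a zero synonymous total
makes the global dN/dS an explicit error, not infinity; chain
non-convergence is reported as a warning with the R̂ values rather than
discarded.

## Known limitations

- The episodic test treats all branches as foreground (no per-branch
  foreground selection, no branch-site per-site episodic variant).
- REL's neutral-class absorption (above) makes its solo flag rate
  anti-conservative on genes with truly neutral classes.
- The selection-coefficient likelihood is the PRF skeleton, not the full
  codon-path mutation model; absolute posteriors on real data will differ
  from the original tool even at identical priors and MCMC settings.
- No demographic corrections: population size changes distort the PRF
  frequency spectrum and are not modeled.
- The expression test is pointwise, not a family-wise band; exceedance
  fractions are descriptive and their null behavior is quantified by the
  coverage experiment.
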