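# Methods

## The inference problem

The European crow complex contrasts two histories that produce the same
genomic landscape of differentiation.  Western European carrion crows
(EURw) are all-black like the Iberian population (SPA) but genomically
near-identical to grey-coated hooded crows (EURns), except for a ~2 Mb
plumage locus on chromosome 18.  Either (i) EURw descends from the Iberian
refugium and its genome was subsequently *swamped* by asymmetric gene flow
from expanding hooded crows, with the colour locus held back by divergent
selection (**genome-wide swamping, GWS**, population tree
`((SPA,EURw),(EURns,IRQ))`), or (ii) EURw shares recent ancestry with
hooded crows and only the colour locus *introgressed* from Iberia
(**locus-specific introgression, LSI**, tree `((IRQ,(EURw,EURns)),SPA)`).
The package implements the full chain that discriminates the two:
coalescent simulation under both four-population isolation-with-migration
models, folded joint-SFS composite-likelihood fitting with AIC model
choice and parametric bootstrap, topology weighting of block gene trees
with ternary comparison, and the windowed diversity/introgression
statistics — all exercisable end to end on synthetic data.

## Demographic model

A `DemographicModel` is a rooted population tree (splits as
backward-in-time merges of a derived into an ancestral lineage, each
internal branch with its own diploid size), per-population exponential
growth, and epochs of migration.  Conventions:

- **Time** is stored in years before present and converted to continuous
  generations (`t / g`, generation time `g = 5.79` years) only at
  simulation time; event times are never rounded, so arbitrarily close
  events cannot collide on a coarse grid.
- **Mutation rate** `mu = 3.18e-9` per site per generation.
- **Migration** rates are forward-time donor-to-recipient fractions per
  generation; the engine converts them to backward lineage-movement rates
  by swapping indices.  Epochs must lie within the coexistence window of
  their populations; the scenario builders optionally *clamp* the
  secondary-contact epoch to that window (`clamp_epochs`) because
  optimisers explore parameter boxes whose corners are infeasible.
- **Growth**: the size backward at time `t` is
  `Ne_present * exp(-GR * t/g)` for `t` younger than the growth onset
  (TEGR) and constant earlier — the backward image of fastsimcoal-style
  forward exponential growth.

Point estimates used throughout synthetic work (times in kya; rates per
generation): splits 504 / 131 / 34.5, secondary contact 20.0;
m(SPA→EURw) = 3.16e-4, m(EURw→SPA) = 1.69e-4, m(IRQ→EURns) = 5.68e-6,
m(EURns→IRQ) = 4.52e-5, m(EURns→EURw) = 6.94e-4, m(EURw→EURns) = 1.29e-4;
growth GR = 2.35e-4 / 2.54e-4 since 3.10 / 34.5 kya for EURw / EURns.  An
alternative parameterisation (428 / 107 / 31.2 / 30.6 kya with its own
rates) ships as the `*_jaatha` presets.  Present-day effective sizes are
**package defaults for synthetic work, not empirical estimates**:
SPA 5e4, IRQ 2e4, EURw 2e5, EURns 4e5, internal branches 1e5.  The sample
panel is 15/15/15/5 diploids for SPA/EURw/EURns/IRQ.

## Coalescent engine

Genealogies of independent non-recombining loci are drawn by an exact
event-driven structured coalescent (a numba-compiled kernel).  The
demography is compiled to piecewise-constant intervals; within an interval
the next event is an exponential race between per-population coalescence
and migration, with the time-inhomogeneous coalescence hazard under
exponential size change inverted in closed form
(`s = ln(1 + g E / lambda_0)/g`).  Candidates beyond an interval boundary
are discarded and redrawn, which is exact because the competing processes
are conditionally memoryless.  Haploid lineages are simulated; diploids
are consecutive haplotype pairs, so phase is known in synthetic data.
One master seed yields counter-based per-locus seeds, making locus *i*
reproducible independently of how many loci are simulated.

Mutations: an infinite-sites model (Poisson on branches, every mutation a
fresh site, 0/1 haplotypes) and a finite-sites HKY-style model with equal
base frequencies where each mutation is a transition with probability 0.5
— each of the two transversion types then carries probability 0.25, i.e. a
per-type rate ratio kappa = 2, reconciling a transition *fraction* of one
half with a transition/transversion *ratio* of two.  Recurrent hits and
back-mutation are possible by construction.

The engine is cross-validated in the test suite against msprime — an
independent simulator configured identically — by two-sample
Kolmogorov-Smirnov tests on TMRCA and segregating-site distributions
(p > 0.01 at 2,000 replicates, three seeds), and against the analytic
moments E[T2] = 2N and E[pi] = 4 N mu.

## Folded joint SFS and composite likelihood

For each of the six population pairs the folded joint spectrum counts
sites by minor-allele configuration: raw cell `(i, j)` is folded with its
complement `(nA-i, nB-j)`, the smaller total count keeping the site (exact
ties to the lexicographically smaller index); the two monomorphic corners
are masked.  A 14-bin reduction (per-axis categories absent / singleton /
interior / fixed, minus the two fully-monomorphic corner combinations)
is provided for the coarse-grained likelihood variant.

The expected spectrum under a model is estimated by simulation.  Rather
than dropping Poisson mutations and counting, each branch contributes its
*length* to the folded cell determined by its descendant counts — the
Rao-Blackwellised (conditional-expectation) estimator, which removes all
mutational noise from the Monte-Carlo estimate at no extra cost.
Synthetic *observed* spectra do draw Poisson counts per branch, one draw
shared across the six pairs so they describe the same underlying sites.
Zero cells of an expected spectrum are floored at 1e-8 and renormalised
before logs (finite simulation cannot populate all cells of a 31x31
spectrum).

The score is the multinomial composite log-likelihood
`sum_c O_c log10 p_c`, summed over the six pairs (pairwise-composite),
treating sites as independent — valid for point estimation and relative
model comparison, not for naive standard errors.  AIC is
`2k - 2 ln(10) log10(L)`.

**Fitting** (`CompositeLikelihoodModel.fit`) is cyclic conditional
maximisation: each cycle line-searches every free parameter in turn by
golden section over its box (rates and sizes on a log scale, times
linear), with *common random numbers* — all evaluations within one start
share the simulation seed — so the simulated likelihood surface is smooth
enough for a line search.  Multi-start is supported; the first start
initialises at the fixed-parameter values when present (so bootstrap
refits start at the point estimate).  Structurally infeasible parameter
combinations (split-order violations inside the search box) score `-inf`.
A final re-scoring with more simulated loci reduces comparison noise
between competing models; the re-score seed is shared across models.

**Parametric bootstrap**: replicate spectra simulated at the point
estimate (defaults follow the neutral-genome tiling: 636,281 loci of
1,000 bp — `ceil((11,146,221 + 625,134,484)/1000)`; desk-scale runs use
far fewer), refit initialised at the point estimate, Efron-Tibshirani
bias correction `2*theta - mean(theta*)` and quantiles.  The neutral
genome length itself follows
`used/total * (total + invariant) = 329,623,861 bp` for the recorded
counts.

## Topology weighting

Block gene trees are built from 50-SNP windows (never spanning contigs;
the trailing short block is kept but flagged): neighbour joining
(scikit-bio) on substitution-corrected distances, rooted on the outgroup.
For nucleotide data the distance cascade is log-det (the GTR-consistent
paralinear distance) → Kimura two-parameter → Jukes-Cantor → raw
p-distance, falling back per pair when a correction is undefined on a
50-SNP alignment; 0/1 synthetic data uses the p-distance directly.
Polytomies and the arbitrary NJ root are resolved deterministically
(left-first) before classification, which uses topology only.

Weights follow the iterative-subtree-sampling scheme: the weight of a
rooted ingroup topology is the fraction of one-leaf-per-taxon subtrees
matching it.  Three-taxon weights are computed *exactly* in closed form by
subtree counting — for each internal node, the number of cross-child
(x, y) leaf pairs whose MRCA is that node, times the number of z-leaves
outside its subtree — in O(nodes) per tree, with no combination cap.
Four-taxon weights enumerate combinations exactly below a 50,000-
combination cap and fall back to Monte-Carlo sampling (default 10,000
draws) above it.  Canonical three-taxon labels for (SPA, EURw, EURns):
topo2 = EURw with EURns (the introgression/ILS signal), topo3 = SPA with
EURw (the carrion species tree).

Weight vectors are binned on the k-fold triangular subdivision of the
simplex (k = 20 → 400 congruent cells; floors of the scaled coordinates
sum to k-1 for upward and k-2 for downward cells, lattice-boundary points
pushed deterministically to the adjacent cell).  Observed and simulated
grids are compared by per-bin differences after rescaling the simulated
grid to the observed total; the summary statistic is the L1 distance.

## Windowed and introgression statistics

Fixed-bp windows (default 50 kb, left-anchored, final short window kept):
pi and d_XY as mean pairwise differences per accessible site (all
positions accessible by default, correct for synthetic data where
monomorphic sites are observed), Hudson's F_ST as a per-window ratio of
sums, and the net divergence d_a = d_XY − (pi_x + pi_y)/2 reported as-is
(negative values allowed).  d_a converts to time as T = d_a/(2 mu)
generations, assuming all net divergence accumulated post-split.
Patterson's D uses the frequency form with a delete-one block jackknife
(5-Mb blocks by default; SE withheld below 20 blocks); the f4-ratio
estimates ancestry proportions with the same jackknife.  f_dM is computed
in non-overlapping 50-SNP windows with the dynamic-donor denominator,
signed so complete P2–P3 introgression gives +1 and complete P1–P3 gives
−1.  The four-gamete statistic is the fraction of polymorphic site pairs
in a window displaying all four gametes (exactly 0 on one non-recombining
genealogy under infinite sites).  Hardy-Weinberg filtering uses the exact
conditional test per site per population, removing a site that fails in
*any* population at alpha = 1e-4 (the threshold is a package default; the
upstream pipeline's is unrecorded), with sites on the designated barrier
contig exempt.  Tajima's D uses the standard normalising constants at the
modal sample size.

## Synthetic datasets

`generate_dataset` tiles independent loci over synthetic contigs (default
20 contigs x 50 loci x 2,000 bp) and writes a phased GT-only VCF 4.2,
a sample→population map, a sidecar outgroup/ancestral-allele table (the
ancestral allele per site, which is how the ABBA-BABA statistics consume
an outgroup), and a truth record from which the dataset regenerates
byte-identically.  Loci inside the declared barrier span (default: 40
central loci of contig18, a chr18-like region) are simulated under the
same model with the EURw↔EURns and SPA↔EURw migration edges removed —
divergent selection is emulated through its effect on *effective*
migration, not by fitness, because the downstream analyses only see the
effective-migration consequence.  `spike_missingness` drops diploid calls
independently at a given rate for stress-testing the complete-case SFS
path.

What the generator does **not** emulate: intra-locus recombination (loci
are non-recombining blocks; linkage between loci is absent rather than
attenuated), sequencing error, DNA damage, unphased-genotype ambiguity,
reference bias, and real chromosome-scale recombination-rate variation.
Passing tests therefore demonstrate correctness of the inference chain
under the model's own assumptions, not robustness to those artefacts.

## Scales used in the checks, and their rationale

The published analysis used ~11.1 M neutral SNPs, 1,000,000 coalescent
simulations per likelihood evaluation, and 285,323 gene-tree blocks; the
package's experiments run at desk scale:

- **Profile recovery**: observed data of 5,000 loci x 2,000 bp (~0.5 M
  sites) per replicate; 21-point grids; the expected spectrum per grid
  point uses 40,000 simulated loci under common random numbers, shared
  across replicates.  With the branch-length estimator this effort keeps
  the shared grid noise below the profile curvature for the identifiable
  parameters.
- **Model selection**: both scenarios fitted with 3 free times + 2 free
  migration rates, 3 starts, 2 cycles, 300 simulated loci per evaluation
  and a 4,000-locus final re-score under a shared seed.
- **Topology weighting**: 1,500 trees per grid, 4 diploids per taxon plus
  one outgroup diploid, exact three-taxon weights.
- **Direction properties**: 20 datasets of 6 contigs x 25 loci.

A known limitation surfaced by these experiments: the EURw split time is
only weakly identified at desk scale.  Backward in time an EURw lineage
leaves EURw at ~1e-3 per generation (the sum of the two incoming
migration rates), so essentially no lineage remains by the split —
the profile is nearly flat above ~0.7x the generating value, and the
per-replicate maximiser scatters beyond ±20% more often than the other
parameters (its median across replicates remains on target).  This is an
information limit of the data size, not an estimator defect; at the
published data scale the likelihood differences grow proportionally and
the parameter becomes identifiable.

## Numerical choices

- Expected-SFS floor 1e-8 (renormalised); likelihood raises instead when
  flooring is disabled and a populated cell has zero expectation.
- Golden-section line searches use a fixed evaluation budget per
  parameter rather than a tolerance (the surface is simulated; extra
  evaluations buy more than tighter brackets).
- Fold ties (`i+j` equal to its complement) go to the lexicographically
  smaller cell; ternary lattice-boundary points go to the lowest-index
  adjacent cell; NJ polytomies resolve left-first — all deterministic.
- Seeds: every public entry point takes a seed; per-locus, per-replicate
  and per-start seeds derive from it via `SeedSequence` counters and stay
  below 2^31.
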