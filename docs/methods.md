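# Methods

This note documents the models, estimators and design choices behind
`parvapop`, and what the synthetic-data tests do and do not establish about
real data.

## Data model

The unit of data is one aligned mtDNA fragment (cytochrome *b*, nominally
700 bp) per individual, plus a population map (population code,
native/invasive group, decimal-degree coordinates). Missing data are handled
by *complete deletion*: any column containing a gap or IUPAC ambiguity code
in any sequence is removed dataset-wide before haplotype collapsing, so all
pairwise statistics share one site set. Haplotypes are numbered H1, H2, … by
first appearance, which makes tables reproducible across runs; the partition
of individuals into haplotypes is order-invariant.

Simulated datasets store representatives over segregating sites only and
carry the true locus length in `site_span`, so per-site statistics stay on
the full-locus scale; the K2P comparable-site denominator likewise counts
the omitted invariant columns.

## Divergence screen

A haplotype is flagged as a putative introgressed mitochondrion when its
minimum K2P distance to every other haplotype exceeds `fold_threshold`
(default 5) times the median of all per-haplotype minimum distances. The
screen is scale-free: it keys on the sample's own divergence scale, which is
what makes a single ~5%-diverged congener haplotype stand out against
within-species variation of well under 1%. Flagged haplotypes are excluded
from π-based group comparisons and from the network (a single foreign
haplotype otherwise dominates both).

## Diversity estimators

- Haplotype diversity: H = n/(n−1)(1 − Σp̂²).
- Standardised diversity H_k: the expected *uncorrected* diversity of a
  with-replacement subsample of size k (default 6, the smallest sample).
  E[Σp̂²] under multinomial resampling gives the closed form
  E[H_k] = (1 − 1/k)(1 − Σp̂²) = (1 − 1/k)·H·(n−1)/n, which the Monte-Carlo
  path (default B = 1000, seed mandatory) matches within Monte-Carlo error.
  The small-sample correction is deliberately *not* applied inside
  replicates: the standardised column of a diversity table is the expected
  heterozygosity at size k, and this convention reproduces published
  standardised columns from their H columns.
- Nucleotide diversity π: mean pairwise p-distance per site (Nei). The K2P
  correction is attached to the distance matrices (D_XY, F_ST), not to π;
  at within-species divergences the difference is far below reporting
  precision, and a switch is not exposed.
- θ estimators: Watterson θ_W = S/(a_{n−1}L) and θ_π = π, converted to
  effective female population size as N_e = θ/(c·μ) with c = 2 (maternally
  inherited haploid locus, θ = 2N_f μ) and c configurable. The conventional
  teleost mtDNA clock of 1% divergence per million years corresponds to
  μ = 0.5×10⁻⁸ per site per year per lineage.

## Differentiation

F_ST = 1 − H_w/H_b (Hudson), with H_w the mean of the two within-population
mean pairwise K2P distances and H_b = D_XY the mean between-population K2P
distance. Raw negative estimates are floored at zero for reporting and kept
in `fst_raw`. Saturated pairs (K2P log argument ≤ 0) are masked with a
warning rather than clamped, so a saturation problem is visible instead of
silently biased. Group medians (native–native, invasive–invasive,
native–invasive) are the quantities the spread models make predictions
about.

## Equilibrium envelope and the admixture classifier

The null model is a constant-size Kingman coalescent with infinite-sites
mutation at rate θ/2 per branch-length unit, simulated on a grid of 21
log-spaced θ values from 0.01 to 30 per locus (plus an exact θ = 0 anchor),
default 15 samples and 1000 replicates per θ. Each replicate records
corrected H and per-site π; the envelope table reports per-θ means and the
empirical 5–95% π band.

Classification of an observed population compares its π against the
*conditional* 5–95% band of π given realised H — the quantiles of the 300
replicate draws nearest in H, pooled across the θ grid. The per-θ marginal
curves interpolated on mean H (kept as a fallback when only the table is
available) systematically under-cover, because a single sample's realised H
fluctuates around the mean-H axis; the conditional band restores nominal
coverage (~91–97% within, measured at θ = 1–3) while remaining a pure
function of the same simulated null. Points outside the simulated H range
get verdict `NA` (extrapolation refused).

What the calibration shows — and its limit: a 50:50 pool of two
nearly-monomorphic demes from the two peripheral lineages (≥13 substitutions
apart through the central lineage) is classified *above* the band in ≥95% of
replicates. A mix of demes only 6 substitutions apart is **not** reliably
separable from equilibrium at moderate-to-high H: the Kingman null itself
produces deep bimodal genealogies with the same H–π signature at a rate
above 5%. Real single-population verdicts at that divergence should be read
as suggestive, which is why the analysis leans on the *population-wide*
pattern (most invasive populations sitting high relative to the band)
rather than any single call.

## Spatial structure

Geographic distances default to Euclidean distance on decimal degrees (to
mirror conventional IBD analyses over a continental extent); haversine
great-circle distance is available. The Mantel statistic is the Pearson
correlation of upper-triangle entries, with significance from simultaneous
row/column permutation, one-sided p = (#{r* ≥ r} + 1)/(nperm + 1) and the
classical cross-product Z reported alongside. F_ST is log₁₀-transformed with
a 10⁻⁴ floor (the transform is conventional; the floor handles exact zeros,
which the convention leaves unspecified). Distance-from-source regressions
are ordinary least squares of F_ST(source, i), H_i and π_i on distance from
the putative introduction site, with a population exclusion list for known
recently-bottlenecked satellites. Ordination is classical (Torgerson) MDS —
double-centred squared distances, top positive eigenpairs; negative
eigenvalues are truncated with a warning.

## Invasion scenarios and ABC

Three demographic scenarios are encoded backward in time over demes pop1
(lineage-1 natives), pop2 (admixed northern natives), pop3 (the invasive
pool), pop4 (lineage-2 natives) and ghosts GH1/GH2 absorbing unsampled
lineage-2 ancestry. All share a founder event: pop3 has size NF for the DB
generations following the introduction t1 generations ago. Scenario 1
sources pop3 from pop2; scenario 2 makes pop3 a fresh pop1 × GH2 admixture
at t1; scenario 3 sources pop3 from an unsampled pool whose pop1 × GH2
admixture predates pop2's own admixture (enforced ordering
t2 < t_a < min(t3, t4)).

Default priors (all overridable; uniform unless noted): deme sizes
U(10, 5×10⁴); t1 ~ U(20, 100) generations (one-year generations; the
introduction is decades old); t2 ~ U(10², 5×10³); t_a ~ logU(10⁴, 10⁵) —
scenario 3's deep admixture is placed at the natural secondary-contact
timescale (end-Pleistocene, ~10⁴ years) rather than the anthropogenic one;
ghost split times t3, t4 ~ logU(10⁴, 10⁶); root ~ logU(10⁶, 5×10⁶)
(early-Pleistocene lineage separation at the 1%/MY clock); admixture
proportions U(0.1, 0.9); NF ~ U(2, 100); DB ~ U(1, 10);
μ ~ logU(5×10⁻⁹, 5×10⁻⁸) per site per generation. Mutations follow K2P with
transition:transversion rate ratio κ = 2 on 700 sites (infinite-sites
placement; saturation capped at L, vanishingly rare under these priors).

Summary statistics: the base vector is, per population, (Nh, H, π, S) and,
per pair, (F_ST, D_XY) — length 4P + 2·C(P,2). The ABC machinery defaults to
an extended vector adding per-population private-haplotype counts and
per-pair shared-haplotype mass and count: which populations the invaders
*share haplotypes with* is precisely what separates a pop2-sourced invasion
from an independently admixed one, and without it the scenarios are close to
exchangeable. Statistics are MAD-normalised, exact-duplicate columns are
dropped (so duplicating a statistic cannot double its weight), and
degenerate zero-spread statistics are removed with a warning.

Model choice reports both the direct approach (scenario frequencies among
the k closest simulations over a nested k grid, Clopper–Pearson intervals)
and a multinomial logistic regression fit on the closest 1% and evaluated at
the observed statistics (bootstrap CIs). Parameter posteriors use Beaumont's
local-linear adjustment with Epanechnikov weights, two stabilisers suited to
desk-scale reference tables (10³–2×10⁴ simulations per scenario instead of
the 10⁶ a production run would use): parameters with known prior bounds are
logit-transformed so adjusted draws respect the support, and the slope
estimate is ridge-penalised (λ = 0.5 × mean design diagonal). Without them,
an OLS adjustment on ~40 statistics and a few hundred accepted draws
injects more noise than it removes (measured t1 coverage dropped from ~90%
to ~70%); with them the deterministic-signal limit still collapses the
posterior (posterior SD < prior SD/5 on a linear-response fixture).

Calibration at desk scale (2×10⁴ simulations per scenario, mid-prior
pseudo-observations): the generating scenario is recovered as highest
logistic posterior in ≥80% of repetitions, and the 95% credible interval for
t1 covers the truth in ≥85% of prior-drawn repetitions.

## Haplotype networks and trees

The median-joining network uses weighted distances — default site weight 50,
listed homoplastic positions down-weighted to 1 (1-based positions on the
trimmed alignment, supplied via config), transversions ×3 — and ε = 0:
minimum spanning network keeping all tie edges, augmented to closure with
per-site-majority quasi-medians of triplets centred on a shared
spanning-network neighbour whenever the star through the median is strictly
cheaper, then pruning of unsampled vectors of degree ≤ 2. Full Steiner
optimality is not attempted (nor is it by the standard algorithm). With no
homoplasy the result contains a minimum spanning tree; node order cannot
affect the edge set because nodes are processed in canonical sequence order.

Neighbour joining is the standard Saitou–Nei agglomeration with the Q
criterion, deterministic lowest-index tie-breaking and negative branch
lengths clamped to zero; on additive matrices it reproduces the generating
tree exactly (property-tested on random 6-taxon trees). Bootstrap supports
resample alignment columns, rebuild K2P+NJ and count original bipartitions.

## Synthetic data: what it emulates, what it does not

The generator builds a native range of three lineages (peripheral cores 6
and 7 substitutions from the central core at disjoint diagnostic sites),
single-lineage demes as equilibrium coalescent samples (default θ = 1 per
locus, matching π ≈ 0.0014 over 700 bp; the study's river populations span
θ ≈ 0–1.6), one contact-zone deme pooling two lineages, and invasions under
three spread models: independent single-lineage foundings
(multiple-source-sink), a serial-founder chain from an admixed pool with
linear coordinates (stepping-stone; default 4 founders per step — 3 or fewer
lets drift destroy the monotone gradient), and independent foundings from
one admixed pool at random coordinates (long-distance; default 10 founders).
Optional satellites refound the last population from 1–2 fish (the
recently-introduced, fixed-haplotype pattern), and an optional introgressed
haplotype replaces one individual with a consensus-derived sequence at a
target K2P divergence. Defaults are 700 bp, 15 individuals per site, 4
native + 6 invasive populations (a reduced-scale image of the original 8 +
14 sampling); the IBD calibration uses 12 invasive demes because Mantel
power at 6–8 demes is structurally too low to certify the stepping-stone
signature, and the original design itself had 14 European sites.

Not emulated: river-network geography (coordinates are planar), selection,
recombination (correctly absent for mtDNA), heteroplasmy, sequencing error,
and within-population geographic substructure. Passing calibrations
therefore certify the *statistical machinery* under the stated demographic
conditions, not robustness to those real-data complications.

## Numerical and reproducibility choices

Every stochastic routine takes a seed or Generator; the pipeline fans a
single global seed into fixed per-stage offsets so stages rerun in
isolation byte-identically. Mantel p-values use the +1/+1 permutation
convention; F_ST flooring, the 10⁻⁴ log floor, the K2P saturation error and
the degenerate-statistic warnings are all deliberate visible-failure choices
over silent clamping. Problem sizes in tests (10⁴ coalescent replicates,
500–1000 envelope replicates per θ, 2×10⁴ ABC simulations per scenario) are
the package's desk-scale defaults; all scale up linearly via arguments.
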