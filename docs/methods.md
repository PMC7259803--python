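# Methods notes

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-engineer
from the code.

## Synthetic data (`ploidpop.simdata`)

**Genotypes.** Per-site population alternate-allele frequencies follow a
symmetric Beta(α, α) prior with α = 0.2 by default, giving the
concentration of mass near 0 and 1 (excess of rare variants) characteristic
of a neutral site-frequency spectrum. Diploids and tetrasomic tetraploids
draw dosage ~ Binomial(ploidy, q) from one panmictic pool. A disomic
tetraploid draws Binomial(2, q₁) + Binomial(2, q₂) from two subgenomes;
with probability *d* (`fixed_diff_prob`) a site is a fixed inter-subgenome
difference (q₁ = 0, q₂ = 1), forcing dosage exactly 2 — the AABB mechanism
that creates the intermediate-frequency excess diagnostic of allopolyploidy.

**Read counts.** Depth is Poisson(λ) truncated to ≥1 (zero-depth sites carry
no information and would only complicate bookkeeping); alternate reads are
Binomial(depth, f) with f = (k/p)(1 − ε) + (1 − k/p)ε under a symmetric
biallelic miscall model with ε < 0.5. There is no third-allele channel, no
mapping bias, and no base-quality structure: the generator produces the
*input* of the frequency analyses, not raw reads.

**Two-species cohorts.** For inheritance-mode experiments both species share
ancestral frequencies except at fixed differences (probability *d*). An
observed tetraploid is modelled as the pooled sequencing of its two
chromosome-pair sets — two diploid-like draws at λ each (total expected
depth 2λ). This matches, by construction, the read-count law of an in-silico
combination of two diploids, which is what makes the observed-versus-model
Wilcoxon comparisons exchangeable under the null. A real tetraploid
sequenced at depth 2λ has reads sampling all four chromosomes jointly rather
than two pairs separately; the difference is a second-order narrowing of the
frequency peaks and does not affect the band counts materially, but it is a
modelling choice to be aware of.

**Coalescent loci.** Hudson's algorithm in coalescent units: waiting times
Exponential with rate C(j,2) (rescaled through e^{βt} under exponential
growth β), infinite-sites mutations Poisson(θ·T_total/2) placed uniformly on
branches and mapped to distinct columns. Closed forms E[S] = θ·a₁ and
E[π] = θ hold exactly and are used as test oracles, alongside an independent
cross-check against `msprime`. A finite-sites Jukes–Cantor simulator along a
fixed tree provides fixtures for distance-based tree building. If the
realized number of segregating sites exceeds the locus length the generator
raises rather than silently resampling, so simulated θ is never biased.

**Gene trees.** Each tree is a base topology chosen by weight, perturbed by
one random nearest-neighbour interchange with probability `nni_prob`. Note
this produces *exact topological duplicates* at rate 1 − `nni_prob`, unlike
empirical maximum-likelihood gene trees which are almost all distinct; see
the gap-statistic discussion below.

**Rasters.** Suitable cells get probability in (0.8, 1], the rest in
[0, 0.8), so an inclusive 0.8 threshold recovers planted counts exactly.
Raster I/O is plain-text ESRI ASCII grid only.

## Ploidy assignment (`ploidpop.sitefreq`)

Site filters: depth ≥ 10, both alleles ≥ 3 reads, third-allele fraction
≤ 0.05 — conservative defaults, all exposed as parameters. Frequencies are
kept unfolded and mirrored (each site contributes f and 1 − f), so the
multiset is symmetric about 0.5 and histograms span the full 0–1 axis; all
band statistics downstream are defined on this representation.

Denoising fits, by EM, Uniform(0,1) + three free-mean Gaussians with a
shared variance; an entry's signal posterior is averaged over its mirrored
pair (preserving symmetry exactly) and entries below 0.5 are dropped. On
pure uniform input the ML fit still leaves the narrow Gaussians ~13% of the
mass — the uniform/Gaussian split is only weakly identifiable there — but
essentially every entry is flagged as noise, which is the operationally
relevant outcome.

The ploidy fit maximizes fixed-mean mixtures ({1/2}, {1/3, 2/3},
{1/4, 1/2, 3/4}; weights and shared variance free) and a free 3-component
mixture. EM details: duplicate frequency values are collapsed to weighted
unique values first (likelihood-identical, large speedup at high depth);
k-means++-style restarts plus warm starts from each fixed optimum, which
guarantees logL_free ≥ logL_fixed up to tolerance; convergence |Δll| < 10⁻⁶
or 500 iterations; variance floor 10⁻⁴; the log-likelihood is checked to be
non-decreasing every iteration.

**Decision rule.** Because the diploid fixed model is nested in the
tetraploid one (weights are free), Δ(4) ≤ Δ(2) holds identically at the
optimum and a naive "smallest Δ" rule misassigns diploids. Near-ties are
therefore resolved by a BIC penalty, argmin_p 2Δ(p) + (p − 1)·ln n, which
reduces to smallest-Δ away from ties and implements "prefer the lower
ploidy" in a noise-robust way. With λ = 50, ε = 0.005 and 5000
heterozygous sites, assignment accuracy in the recovery experiments is
effectively 100%.

Sample QC applies, in order, the missing-data filter (informative non-gap
fraction ≥ 0.2, inclusive) and the ploidy-concordance filter. The triploid
model is retained even where a study design excludes triploids, so
interploidy hybrids are detectable rather than silently mis-binned.

## Inheritance mode (`ploidpop.inheritance`)

"Combining" two diploids means summing their per-site allele counts over
shared coordinates after allele-identity matching (conflicting allele pairs
are dropped and tallied); this is informationally equivalent to merging
read alignments for every frequency-histogram purpose and keeps the module
free of alignment-file dependencies.

Band conventions on the unfolded representation: intermediate is the closed
interval [0.40, 0.60] (a balanced site contributes both mirrored entries),
rare is the open interval (0, 0.30) — the low side only. This makes the
per-individual ratio a monotone transform of the folded version, harmless
to rank tests. Ratios are computed per individual and compared between
groups with two-sided Wilcoxon rank-sum tests: exact enumeration when both
groups are ≤ 10 without ties, otherwise the normal approximation with tie
and continuity corrections. The BH family is declared per run as
{observed-vs-auto, observed-vs-allo, auto-vs-allo}. A per-pooled-group
ratio would also be defensible; per-individual ratios were chosen because
they give the rank tests a real sampling unit.

Classification at α = 0.05: *tetrasomic* requires a significant deficit
relative to the allo model and no significant difference from the auto
model; *disomic* the mirror; anything else (both or neither) is *mixed* —
deliberately conservative, since both gene flow into an autotetraploid and
a young allotetraploid produce intermediate patterns.

## Summary statistics (`ploidpop.popgen`)

Complete deletion is the default gap policy (any gap/N drops the column)
for determinism; pairwise deletion is a switch. Locus retention demands
strictly more than 100 kept sites. Estimators are haplotype-based (a
tetraploid contributes four rows), π via per-column allele counts
(n² − Σcᵢ²)/2, Tajima's D with the standard a₁…e₂ constants, Hudson's
F_ST = 1 − H_w/H_b with H_w the unweighted mean of the two within-species
diversities. Hudson's form was chosen as the primary estimator for its
simplicity and direct haplotype interpretation. F_ST is undefined (and
excluded from medians) when H_b = 0. Note the finite-sample Hudson
estimator is *not* zero for two samples drawn identically — it is zero in
expectation under panmixia (a property test) and exactly zero only when
within- and between-sample diversity balance. Across-locus aggregation uses
the median for F_ST (robust to the long right tail of per-locus values) and
the mean for diversity/d_xy matrices; clustering is scipy average-linkage
(UPGMA) with its deterministic lowest-index tie-break.

## Tree space (`ploidpop.treespace`)

Trees are handled unrooted; splits are canonical frozensets of leaf labels
(the side not containing the lexicographically smallest leaf), so trees
from different sources compare by label. RF is the unnormalized symmetric
difference of non-trivial splits, verified in tests against both a
graph-connectivity brute force and dendropy.

MDS is classical (Torgerson): double-center −D²/2, top eigenpairs, axes
with non-positive eigenvalues dropped, each axis sign-fixed so its first
nonzero coordinate is positive. PAM is the standard build + greedy-swap on
the embedding's Euclidean distances, with the swap deltas evaluated in
vectorized form; the objective is non-increasing by construction. The gap
statistic uses B = 50 uniform reference draws over the coordinate bounding
box and selects the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}.

**Known limitation.** On gene-tree sets containing many exact topological
duplicates — which the single-NNI generator produces by design — the PAM
cost collapses at every k up to the number of distinct topologies, Gap(k)
increases monotonically, and the rule selects k_max regardless of the true
number of mixture components. This is not an implementation artefact: R's
`cluster::clusGap` with `pam` returns the same answer on identical
coordinates, and alternative references (uniform random topologies) or
topology deduplication do not rescue it. The gap statistic is appropriate
for diffuse clouds of mostly-distinct topologies (the empirical situation
for ML gene trees); for point-mass mixtures, cluster counts should be read
from the distance matrix structure directly. The corresponding recovery
test is left failing rather than papered over.

NJ tree building uses Jukes–Cantor distances with pairwise-deletion
overlap (saturated pairs, p ≥ 0.75, are capped at 5.0 substitutions/site
with a warning) and scikit-bio's neighbor-joining; internal edges of
numerically zero length are collapsed, so identical sequences yield a star
tree. The within-locus consistency test draws `n_replicates` (default 6)
one-individual-per-species subsamples per locus, scores the mean pairwise
RF among replicate trees, summarizes each locus by a strict-majority
(>50%, ties excluded) consensus, and contrasts the median within-locus
score (threshold 0: exact topological identity) against the between-locus
mean. gCF counts, per internal species-tree branch, the decisive gene trees
(≥1 leaf in each of the branch's four neighbour groups) containing the
branch's bipartition after restriction to the gene tree's leaves.

## Niche statistics (`ploidpop.niche`)

Variable pruning recomputes the full |Pearson| matrix and repeatedly drops,
from the worst offending pair above r = 0.85, the member with the higher
mean absolute correlation to the remaining variables (ties keep the earlier
column); constant columns are dropped first. Suitable area is a cell count
at an inclusive 0.8 threshold by default — cell counts, not geodesic areas,
keep current/past comparable when the two rasters share a grid; an optional
cos-latitude weighting (≈111.32 km/degree) is provided for geographic
grids. The relative change (current − past)/current is positive under
shrinkage, negative under expansion, and undefined at zero current area.
The correlation p-value is the two-sided t with n − 2 df; its calibration
at n = 6 is verified by label permutation in the tests.

## Problem sizes

The replicated experiments run at: 100 replicates for inheritance-mode
recovery (8 diploids/species, 8 observed tetraploids per mode, 5000 sites,
d = 0.05, λ = 50, ε = 0.005); 400 replicates for the Wilcoxon type-I rate
(a tighter estimate than the recovery runs because the acceptance band is
only two points wide); 300 individuals for ploidy accuracy; 1000 neutral
loci (n = 20, θ = 5) for Tajima's D and 2000 replicates (n = 10, θ = 2)
for the Watterson check; 100 runs of the tree-space recovery (200 trees,
8 leaves); 50 loci for the consistency contrast; 1000 permutation tests for
correlation calibration. `scripts/acceptance.py` runs the same experiments
at roughly half these sizes, chosen so the full reproduction completes in a
few minutes on one core while keeping Monte-Carlo standard errors small
relative to the quantities reported.

## What passing tests do and do not show

The generators realize exactly the distributional assumptions of the
analyses (binomial read sampling, symmetric errors, neutral coalescent,
uniform NNI perturbations, planted raster truth). Passing recovery tests
therefore demonstrate correctness and internal calibration of the
implementations, not robustness to the things real data add: mapping and
reference bias, allele-specific error, linked selection, alignment error,
missing data structure, or model misfit in the distribution models.
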