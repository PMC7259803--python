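# ploidpop

Analyses for mixed-ploidy species complexes — ploidy estimation from
sequencing read counts, inheritance-mode (tetrasomic vs. disomic) inference
for tetraploids, locus-wise population-genetic summary statistics,
gene-tree-space conflict analysis, and habitat-suitability range-change
statistics — built as one tested pipeline that runs end-to-end on synthetic
data with known truth.

## Who this is for

Population geneticists working on groups that mix diploid and polyploid
lineages (common in amphibians and plants) face a chain of bespoke analysis
steps between variant-level read counts and evolutionary conclusions:
Is this individual 2n, 3n or 4n? Is a tetraploid an autopolyploid
(tetrasomic inheritance) or an allopolyploid (disomic inheritance)? Do gene
trees conflict because of rapid speciation or because of incomplete lineage
sorting and gene flow? Has each species' climatically suitable range grown
or shrunk, and does that track its demographic trajectory? `ploidpop`
implements each of these steps as library functions with a thin CLI, plus
generators that simulate inputs with exactly the statistical structure each
step assumes — so every step is testable without any sequencing data.

## The statistics at the core

**Ploidy from base frequencies.** At a biallelic site, the read-level
alternate-allele frequency of a ploidy-*p* individual concentrates near the
dosage fractions *k/p*. After filtering and denoising (an EM fit of a
Uniform(0,1) noise component plus three Gaussians), ploidy is assigned by
comparing fixed-mean Gaussian mixtures — means clamped at {1/2}, {1/3, 2/3},
or {1/4, 1/2, 3/4}, weights and a shared variance free — against a free
3-component mixture: Δ(p) = logL_free − logL_fixed(p), with near-ties
resolved toward the more parsimonious model by a BIC penalty.

**Inheritance mode.** An allotetraploid with disomic inheritance carries two
non-recombining subgenomes; fixed inter-subgenome differences surface as
balanced AABB sites, i.e. an excess of intermediate (40–60%) over rare
(<30%) allele frequencies. Expectations are built from observed diploids by
summing per-site allele counts pairwise: within-species pairs model
autotetraploids, between-species pairs model allotetraploids. Each observed
tetraploid's intermediate/rare ratio is compared with the two model groups
by two-sided Wilcoxon rank-sum tests (Benjamini–Hochberg adjusted);
*tetrasomic* = indistinguishable from the auto model but significantly
below the allo model, *disomic* = the mirror, *mixed* otherwise.

**Summary statistics.** Per locus, on phased haplotype alignments filtered
to invariant + biallelic sites (loci kept only with >100 such sites):
nucleotide diversity π, Watterson's θ_W = S/(a₁L), Tajima's
D = (π_total − S/a₁)/√(e₁S + e₂S(S−1)), between-species d_xy, and Hudson's
F_ST = 1 − H_w/H_b (median across loci), with UPGMA clustering of the
resulting species matrices.

**Tree space.** Robinson–Foulds distances between gene trees, classical
(Torgerson) MDS embedding, PAM clustering with the gap statistic (k = 1–10,
uniform reference over the coordinate bounding box), per-branch gene
concordance factors (gCF, the percentage of decisive gene trees containing
a species-tree bipartition), and a within-locus consistency test that
rebuilds each locus tree from random one-individual-per-species subsamples
to separate rapid speciation from ILS/gene flow.

**Niche change.** Suitable area from presence-probability rasters at an
inclusive 0.8 threshold, relative change (current − past)/current, greedy
pruning of bioclimatic variables with |r| > 0.85, and the Pearson
correlation of range change against per-species median Tajima's D.

## Worked example

Simulate a two-species diploid cohort plus observed tetraploids of both
inheritance modes, estimate a ploidy, and classify the tetraploids:

```python
from ploidpop import (SimConfig, simulate_inheritance_cohort,
                      build_expectation_sets, classify_inheritance,
                      extract_biallelic_frequencies, fit_ploidy)
from ploidpop.inheritance import ratios_for_counts

cfg = SimConfig(seed=7, n_sites=5000, mean_depth=50, error_rate=0.005,
                ploidy=4, inheritance_mode="disomic", fixed_diff_prob=0.05)
cohort = simulate_inheritance_cohort(cfg, n_diploids_per_species=8,
                                     n_tetrasomic=8, n_disomic=8)

fit = fit_ploidy(extract_biallelic_frequencies(cohort.tetrasomic[0]))
print(fit.best_ploidy, fit.delta)

auto, allo = build_expectation_sets(cohort.diploids)
r_auto = ratios_for_counts(auto, "model_auto")
r_allo = ratios_for_counts(allo, "model_allo")
for name, group in [("tetrasomic", cohort.tetrasomic),
                    ("disomic", cohort.disomic)]:
    call = classify_inheritance(ratios_for_counts(group), r_auto, r_allo,
                                species=name)
    print(name, call.label, call.p_vs_auto, call.p_vs_allo)
```

Output:

```
estimated ploidy: 4  delta = {2: 517.1, 3: 333.3, 4: 15.1}
tetrasomic truth -> label='tetrasomic'  p_vs_auto=0.216  p_vs_allo=2.51e-10
disomic truth    -> label='disomic'     p_vs_auto=0.000  p_vs_allo=7.45e-01
```

The free-vs-fixed likelihood gap is smallest for the tetraploid model
(Δ = 15.1 vs. 517.1 for diploid), so the individual is called 4n. The
tetrasomic group is indistinguishable from the autotetraploid expectation
(p = 0.22) but far below the allotetraploid one (p ≈ 10⁻¹⁰) — and the
disomic group shows the mirror image, as its AABB excess predicts.

The same steps are available from the shell, e.g.
`ploidpop simulate reads --out data/`, `ploidpop ploidy --counts
data/counts.tsv`, `ploidpop inherit ...`, `ploidpop popgen ...`,
`ploidpop treespace ...`, `ploidpop niche ...`.

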