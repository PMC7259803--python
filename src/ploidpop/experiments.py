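"""Replicated recovery and calibration experiments for the whole pipeline.

These drivers exercise the package end-to-end under the study-style synthetic
conditions: inheritance-mode recovery and Wilcoxon null calibration, ploidy
assignment accuracy, neutral-coalescent validity of the summary statistics,
tree-space cluster-count recovery, the within-locus consistency contrast, and
the niche-change statistics. Both the test suite and the reproduction script
run them; problem sizes are arguments so the script can scale them.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import inheritance as inh
from .containers import LocusAlignment, TreeSet
from .niche import correlate_demography, relative_area_change, suitable_area
from .popgen import diversity_stats
from .simdata import (
    SimConfig,
    random_topology,
    simulate_biallelic_individual,
    simulate_coalescent_alignment,
    simulate_gene_trees,
    simulate_inheritance_cohort,
    simulate_jc_alignment,
    simulate_raster_pair,
)
from .sitefreq import denoise_frequencies, extract_biallelic_frequencies, fit_ploidy
from .treespace import pam_gap, rf_matrix, within_locus_consistency


# --------------------------------------------------------------------------- #
# inheritance-mode recovery and null calibration
# --------------------------------------------------------------------------- #


@dataclass
class InheritanceRecovery:
    n_replicates: int
    tetrasomic_correct: int
    disomic_correct: int
    null_rejections: int

    @property
    def tetrasomic_pct(self) -> float:
        return 100.0 * self.tetrasomic_correct / self.n_replicates

    @property
    def disomic_pct(self) -> float:
        return 100.0 * self.disomic_correct / self.n_replicates

    @property
    def null_rejection_pct(self) -> float:
        return 100.0 * self.null_rejections / self.n_replicates


def inheritance_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    n_sites: int = 5000,
    fixed_diff_prob: float = 0.05,
    mean_depth: float = 50.0,
    error_rate: float = 0.005,
    n_diploids: int = 8,
    n_observed: int = 8,
    alpha: float = 0.05,
) -> InheritanceRecovery:
    """Label recovery for tetrasomic and disomic truth, plus a null contrast.

    Each replicate simulates a two-species diploid cohort with observed
    tetraploids of both inheritance modes, builds the auto/allo expectation
    sets, classifies both observed groups, and additionally compares two
    independent tetrasomic groups with a Wilcoxon test (the type-I control).
    """
    rng = np.random.default_rng(seed)
    ok_t = ok_d = rej = 0
    for rep in range(n_replicates):
        cfg = SimConfig(
            seed=seed + rep,
            n_sites=n_sites,
            mean_depth=mean_depth,
            error_rate=error_rate,
            ploidy=4,
            inheritance_mode="disomic",
            fixed_diff_prob=fixed_diff_prob,
        )
        cohort = simulate_inheritance_cohort(
            cfg, n_diploids, 2 * n_observed, n_observed, rng=rng
        )
        observed_t = cohort.tetrasomic[:n_observed]
        null_extra = cohort.tetrasomic[n_observed:]
        auto, allo = inh.build_expectation_sets(cohort.diploids)
        r_auto = inh.ratios_for_counts(auto, "model_auto")
        r_allo = inh.ratios_for_counts(allo, "model_allo")
        r_tet = inh.ratios_for_counts(observed_t, "observed_4n")
        r_dis = inh.ratios_for_counts(cohort.disomic, "observed_4n")
        r_null = inh.ratios_for_counts(null_extra, "observed_4n")
        call_t = inh.classify_inheritance(r_tet, r_auto, r_allo, alpha=alpha)
        call_d = inh.classify_inheritance(r_dis, r_auto, r_allo, alpha=alpha)
        ok_t += call_t.label == "tetrasomic"
        ok_d += call_d.label == "disomic"
        rej += inh.compare_groups(r_tet, r_null).p_raw < alpha
    return InheritanceRecovery(n_replicates, ok_t, ok_d, rej)


def wilcoxon_null_calibration(
    n_replicates: int = 400,
    seed: int = 0,
    n_sites: int = 5000,
    n_per_group: int = 8,
    alpha: float = 0.05,
) -> dict:
    """Type-I rate of the group comparison on exchangeable tetrasomic groups.

    More replicates than the recovery experiment because the rejection-rate
    estimate needs a standard error well below the nominal 5% level.
    """
    rng = np.random.default_rng(seed)
    rej = 0
    for rep in range(n_replicates):
        cfg = SimConfig(
            seed=seed + rep, n_sites=n_sites, mean_depth=50.0,
            error_rate=0.005, ploidy=4, inheritance_mode="disomic",
            fixed_diff_prob=0.05,
        )
        cohort = simulate_inheritance_cohort(cfg, 0, 2 * n_per_group, 0, rng=rng)
        r_a = inh.ratios_for_counts(cohort.tetrasomic[:n_per_group])
        r_b = inh.ratios_for_counts(cohort.tetrasomic[n_per_group:])
        rej += inh.compare_groups(r_a, r_b).p_raw < alpha
    return {
        "n_replicates": n_replicates,
        "rejection_rate_pct": 100.0 * rej / n_replicates,
    }


# --------------------------------------------------------------------------- #
# ploidy assignment accuracy
# --------------------------------------------------------------------------- #


def ploidy_recovery(
    n_per_ploidy: int = 100,
    seed: int = 0,
    n_sites: int = 5000,
    mean_depth: float = 50.0,
    error_rate: float = 0.005,
    denoise: bool = True,
) -> dict:
    """Fraction of simulated individuals assigned their true ploidy."""
    rng = np.random.default_rng(seed)
    correct = {2: 0, 3: 0, 4: 0}
    for ploidy in (2, 3, 4):
        for _ in range(n_per_ploidy):
            counts = simulate_biallelic_individual(
                ploidy, n_sites, rng,
                mean_depth=mean_depth, error_rate=error_rate,
            )
            freqs = extract_biallelic_frequencies(counts)
            if denoise:
                freqs = denoise_frequencies(freqs)
            fit = fit_ploidy(freqs)
            correct[ploidy] += fit.best_ploidy == ploidy
    total = 3 * n_per_ploidy
    return {
        "n_individuals": total,
        "correct_per_ploidy": correct,
        "accuracy_pct": 100.0 * sum(correct.values()) / total,
    }


# --------------------------------------------------------------------------- #
# coalescent validity of the summary statistics
# --------------------------------------------------------------------------- #


def tajimas_d_neutral(
    n_loci: int = 1000,
    seed: int = 0,
    n_haplotypes: int = 20,
    theta: float = 5.0,
    locus_length: int = 300,
) -> dict:
    """Mean Tajima's D over neutral constant-size coalescent loci."""
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_loci):
        aln, _ = simulate_coalescent_alignment(
            n_haplotypes, theta, locus_length, seed=rng
        )
        d = diversity_stats(aln, "sp0", prefiltered=True).tajimas_d
        if np.isfinite(d):
            values.append(d)
    return {
        "n_loci": len(values),
        "mean_d": float(np.mean(values)),
        "sd_d": float(np.std(values)),
    }


def watterson_check(
    n_replicates: int = 2000,
    seed: int = 0,
    n_haplotypes: int = 10,
    theta: float = 2.0,
    locus_length: int = 400,
) -> dict:
    """Mean segregating sites against the closed-form theta * a1."""
    rng = np.random.default_rng(seed)
    a1 = sum(1.0 / i for i in range(1, n_haplotypes))
    S = []
    for _ in range(n_replicates):
        aln, _ = simulate_coalescent_alignment(
            n_haplotypes, theta, locus_length, seed=rng
        )
        cols = aln.matrix
        S.append(int((~(cols == cols[0]).all(axis=0)).sum()))
    return {
        "mean_s": float(np.mean(S)),
        "expected_s": theta * a1,
        "se": float(np.std(S) / np.sqrt(len(S))),
    }


# --------------------------------------------------------------------------- #
# tree-space cluster recovery
# --------------------------------------------------------------------------- #


def make_two_bases(
    n_leaves: int, rng: np.random.Generator, min_rf: int | None = None
) -> TreeSet:
    """Two well-separated random base topologies on one namespace."""
    if min_rf is None:
        min_rf = 2 * (n_leaves - 3) - 2
    labels = [f"s{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    bases = dendropy.TreeList(taxon_namespace=tns)
    from .treespace import rf_distance

    while len(bases) < 2:
        t = random_topology(labels, rng)
        t = dendropy.Tree.get(
            data=t.as_string(schema="newick"), schema="newick",
            taxon_namespace=tns,
        )
        if not bases or rf_distance(bases[0], t) >= min_rf:
            bases.append(t)
    return TreeSet(trees=bases)


def pam_gap_recovery(
    n_runs: int = 100,
    seed: int = 0,
    n_trees: int = 200,
    n_leaves: int = 8,
    nni_prob: float = 0.2,
    k_max: int = 10,
    B: int = 50,
) -> dict:
    """How often PAM + gap statistic selects k = 2 on two-topology mixtures."""
    rng = np.random.default_rng(seed)
    k_stars = []
    for _ in range(n_runs):
        bases = make_two_bases(n_leaves, rng)
        ts = simulate_gene_trees(bases, [0.5, 0.5], nni_prob, n_trees, seed=rng)
        D = rf_matrix(ts)
        emb = pam_gap(D, k_max=k_max, B=B, seed=rng)
        k_stars.append(emb.k_star)
    k_stars = np.array(k_stars)
    return {
        "n_runs": n_runs,
        "k2_pct": float(100.0 * (k_stars == 2).mean()),
        "median_k": float(np.median(k_stars)),
    }


# --------------------------------------------------------------------------- #
# within-locus consistency contrast
# --------------------------------------------------------------------------- #


def _duplicate_rows(aln: LocusAlignment, copies: int) -> LocusAlignment:
    rows = np.repeat(aln.matrix, copies, axis=0)
    inds = [
        f"{sp}_{k}" for sp in aln.species_labels for k in range(copies)
    ]
    sps = [sp for sp in aln.species_labels for _ in range(copies)]
    return LocusAlignment(
        aln.locus_id, inds, [0] * len(inds), sps, [2] * len(inds), rows
    )


def consistency_contrast(
    n_loci: int = 50,
    seed: int = 0,
    n_species: int = 6,
    seq_len: int = 400,
    n_replicates: int = 6,
) -> dict:
    """Concordant vs discordant loci under the resampling consistency test.

    Concordant loci: individuals within a species are identical (two species
    topologies alternate across loci). Discordant loci: the two individuals
    of each species descend from different planted topologies.
    """
    rng = np.random.default_rng(seed)
    bases = make_two_bases(n_species, rng, min_rf=4)
    topos = []
    for t in bases.trees:
        for e in t.preorder_edge_iter():
            e.length = 0.15
        topos.append(t)

    concordant = []
    for i in range(n_loci):
        t = topos[i % 2]
        aln = simulate_jc_alignment(t, seq_len, seed=rng)
        aln.locus_id = f"C{i}"
        concordant.append(_duplicate_rows(aln, 2))
    rep_c = within_locus_consistency(
        concordant, n_replicates=n_replicates, seed=rng
    )

    discordant = []
    species = sorted(l.taxon.label for l in topos[0].leaf_node_iter())
    for i in range(n_loci):
        a1 = simulate_jc_alignment(topos[0], seq_len, seed=rng)
        a2 = simulate_jc_alignment(topos[1], seq_len, seed=rng)
        rows, inds, sps = [], [], []
        for sp in species:
            for k, src in enumerate((a1, a2)):
                rows.append(src.matrix[src.species_labels.index(sp)])
                inds.append(f"{sp}_{k}")
                sps.append(sp)
        discordant.append(
            LocusAlignment(f"D{i}", inds, [0] * len(inds), sps,
                           [2] * len(inds), np.array(rows))
        )
    rep_d = within_locus_consistency(
        discordant, n_replicates=n_replicates, seed=rng
    )
    within_d = np.array(list(rep_d.within_locus_rf.values()))
    return {
        "concordant_report": rep_c,
        "discordant_report": rep_d,
        "concordant_max_within": float(
            max(rep_c.within_locus_rf.values())
        ),
        "discordant_positive_loci": int((within_d > 0).sum()),
        "n_loci": n_loci,
    }


# --------------------------------------------------------------------------- #
# niche statistics
# --------------------------------------------------------------------------- #


def pearson_permutation_calibration(
    n_datasets: int = 50,
    n_perms_per_dataset: int = 20,
    n_species: int = 6,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I rate of the correlation p-value under label permutation.

    Small independent null datasets are drawn and the Tajima's D labels are
    randomly permuted before each correlation; the rejection rate at
    ``alpha`` estimates the calibration of the t-based p-value at n = 6.
    """
    from .niche import AreaChange

    rng = np.random.default_rng(seed)
    rejections = 0
    total = 0
    for _ in range(n_datasets):
        x = rng.normal(size=n_species)
        y = rng.normal(size=n_species)
        changes = [
            AreaChange(f"sp{i}", 1.0, 1.0, float(v)) for i, v in enumerate(x)
        ]
        for _ in range(n_perms_per_dataset):
            perm = rng.permutation(n_species)
            d = {f"sp{i}": float(y[perm[i]]) for i in range(n_species)}
            res = correlate_demography(changes, d)
            rejections += res.p_value < alpha
            total += 1
    return {"n_tests": total, "rejection_rate": rejections / total}


def raster_change_check(seed: int = 0) -> dict:
    """Constructed-raster truth for areas and the relative-change statistic."""
    cur, past = simulate_raster_pair(20, 20, 100, 50, seed=seed)
    a_cur = suitable_area(cur)
    a_past = suitable_area(past)
    change = relative_area_change(a_cur, a_past)
    return {
        "area_current": a_cur,
        "area_past": a_past,
        "rel_change": change.rel_change,
    }
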