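"""Generators: genotype/read-count laws, coalescent expectations, trees, rasters."""

import dendropy
import numpy as np
import pytest

from ploidpop import (
    SimConfig,
    rf_distance,
    simulate_coalescent_alignment,
    simulate_gene_trees,
    simulate_genotypes,
    simulate_inheritance_cohort,
    simulate_jc_alignment,
    simulate_raster_pair,
    simulate_read_counts,
)
from ploidpop.containers import read_esri_ascii, write_esri_ascii
from ploidpop.simdata import (
    ConfigurationError,
    LocusLengthError,
    random_nni,
    random_topology,
)


class TestGenotypes:
    def test_fixed_differences_force_dosage_two(self, rng):
        cfg = SimConfig(ploidy=4, inheritance_mode="disomic",
                        fixed_diff_prob=1.0, n_sites=100)
        gt = simulate_genotypes(cfg, rng=rng)
        assert (gt.dosages == 2).all()

    def test_degenerate_prior_yields_invariant_sites(self, rng):
        cfg = SimConfig(ploidy=4, inheritance_mode="tetrasomic", n_sites=50)
        gt = simulate_genotypes(cfg, rng=rng, freqs=np.zeros(50))
        assert (gt.dosages == 0).all()
        assert (gt.site_truth == "invariant").all()

    def test_disomic_excess_of_intermediate_dosages(self, rng):
        """Fixed subgenome differences concentrate dosage at 2 of 4."""
        n = 100_000
        q = np.random.default_rng(0).beta(0.2, 0.2, size=n)
        dis = simulate_genotypes(
            SimConfig(ploidy=4, inheritance_mode="disomic",
                      fixed_diff_prob=0.5, n_sites=n),
            rng=rng, freqs=q, freqs2=q,
        )
        tet = simulate_genotypes(
            SimConfig(ploidy=4, inheritance_mode="tetrasomic", n_sites=n),
            rng=rng, freqs=q,
        )
        frac_dis = (dis.dosages == 2).mean()
        frac_tet = (tet.dosages == 2).mean()
        assert frac_dis > frac_tet

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ploidy": 2, "inheritance_mode": "disomic"},
            {"error_rate": 0.5},
            {"mean_depth": 0.0},
            {"ploidy": 5},
            {"fixed_diff_prob": 1.5},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42, ploidy=4, inheritance_mode="tetrasomic",
                        n_sites=500)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)


class TestReadCounts:
    def test_homozygous_reference_gives_zero_alt_reads(self, rng):
        cfg = SimConfig(ploidy=4, inheritance_mode="tetrasomic",
                        error_rate=0.0, n_sites=200)
        gt = simulate_genotypes(cfg, rng=rng, freqs=np.zeros(200))
        counts = simulate_read_counts(gt, cfg, rng=rng)
        assert (counts.count_b == 0).all()
        assert (counts.depth >= 1).all()

    def test_balanced_dosage_mean_frequency(self, rng):
        """dosage 2/4 without error: alt fraction centered on 0.5."""
        from ploidpop.simdata import GenotypeVector

        n = 10_000
        cfg = SimConfig(ploidy=4, inheritance_mode="tetrasomic",
                        error_rate=0.0, mean_depth=100, n_sites=n)
        gt = GenotypeVector(np.full(n, 2), np.full(n, "biallelic"), 4)
        counts = simulate_read_counts(gt, cfg, rng=rng)
        frac = counts.count_b / counts.depth
        se = frac.std() / np.sqrt(n)
        assert abs(frac.mean() - 0.5) < 3 * se + 1e-12

    def test_error_rate_shifts_mean_frequency(self, rng):
        """Full-dosage sites read at 1 - epsilon on average."""
        from ploidpop.simdata import GenotypeVector

        n = 10_000
        cfg = SimConfig(ploidy=4, inheritance_mode="tetrasomic",
                        error_rate=0.01, mean_depth=50, n_sites=n)
        gt = GenotypeVector(np.full(n, 4), np.full(n, "biallelic"), 4)
        counts = simulate_read_counts(gt, cfg, rng=rng)
        frac = counts.count_b / counts.depth
        se = frac.std() / np.sqrt(n)
        assert abs(frac.mean() - 0.99) < 3 * se + 1e-12

    def test_cohort_layout(self, rng):
        cfg = SimConfig(ploidy=4, inheritance_mode="disomic",
                        fixed_diff_prob=0.05, n_sites=300)
        cohort = simulate_inheritance_cohort(cfg, 3, 2, 2, rng=rng)
        assert len(cohort.diploids) == 6
        assert {c.species_label for c in cohort.diploids} == {"X", "Y"}
        # all individuals share site coordinates
        for c in cohort.diploids + cohort.tetrasomic + cohort.disomic:
            assert np.array_equal(c.site_index, np.arange(300))


class TestCoalescent:
    def test_no_mutation_rate_means_no_segregating_sites(self):
        aln, tree = simulate_coalescent_alignment(6, 0.0, 100, seed=3)
        assert len({s for s in aln.sequences()}) == 1

    def test_watterson_expectation(self, rng):
        """Mean segregating sites matches theta * a1 (closed form)."""
        theta, n, reps = 2.0, 10, 600
        a1 = sum(1.0 / i for i in range(1, n))
        S = []
        for _ in range(reps):
            aln, _ = simulate_coalescent_alignment(n, theta, 400, seed=rng)
            cols = aln.matrix
            S.append(int((~(cols == cols[0]).all(axis=0)).sum()))
        se = np.std(S) / np.sqrt(reps)
        assert abs(np.mean(S) - theta * a1) < 3 * se

    def test_pairwise_diversity_expectation(self, rng):
        """n=2: expected pairwise differences per locus equal theta."""
        reps, theta = 800, 1.0
        diffs = []
        for _ in range(reps):
            aln, _ = simulate_coalescent_alignment(2, theta, 200, seed=rng)
            diffs.append((aln.matrix[0] != aln.matrix[1]).sum())
        se = np.std(diffs) / np.sqrt(reps)
        assert abs(np.mean(diffs) - theta) < 3 * se

    def test_locus_too_short_raises(self):
        with pytest.raises(LocusLengthError):
            # theta enormous relative to locus length
            simulate_coalescent_alignment(10, 500.0, 5, seed=0)

    def test_matches_msprime_oracle(self, rng):
        """Independent coalescent implementation agrees on mean S."""
        msprime = pytest.importorskip("msprime")
        theta, n, reps = 2.0, 10, 400
        mine = []
        for _ in range(reps):
            aln, _ = simulate_coalescent_alignment(n, theta, 400, seed=rng)
            cols = aln.matrix
            mine.append(int((~(cols == cols[0]).all(axis=0)).sum()))
        other = []
        for i in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=1.0,
                sequence_length=1, random_seed=i + 1, discrete_genome=False,
            )
            ts = msprime.sim_mutations(
                ts, rate=theta / 2, random_seed=i + 1, discrete_genome=False
            )
            other.append(ts.num_sites)
        se = np.sqrt(np.var(mine) / reps + np.var(other) / reps)
        assert abs(np.mean(mine) - np.mean(other)) < 4 * se

    def test_genealogy_is_returned_with_all_tips(self):
        aln, tree = simulate_coalescent_alignment(5, 1.0, 100, seed=9)
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(
            aln.individual_ids
        )


class TestJukesCantor:
    def test_zero_branch_lengths_give_identical_sequences(self):
        t = dendropy.Tree.get(data="((a:0,b:0):0,(c:0,d:0):0);", schema="newick")
        aln = simulate_jc_alignment(t, 200, seed=1)
        assert len(set(aln.sequences())) == 1

    def test_divergence_increases_with_branch_length(self):
        short = dendropy.Tree.get(data="(a:0.01,b:0.01);", schema="newick")
        long = dendropy.Tree.get(data="(a:0.5,b:0.5);", schema="newick")
        d = []
        for t in (short, long):
            aln = simulate_jc_alignment(t, 2000, seed=5)
            d.append((aln.matrix[0] != aln.matrix[1]).mean())
        assert d[0] < d[1]


class TestGeneTrees:
    def test_no_perturbation_single_base_gives_identical_trees(self, rng):
        labels = [f"s{i}" for i in range(6)]
        base = random_topology(labels, rng)
        tns = base.taxon_namespace
        from ploidpop.containers import TreeSet

        bases = TreeSet(trees=dendropy.TreeList([base], taxon_namespace=tns))
        ts = simulate_gene_trees(bases, [1.0], 0.0, 20, seed=1)
        assert all(rf_distance(ts.trees[0], t) == 0 for t in ts.trees)

    def test_two_distant_bases_give_two_block_distance_matrix(
        self, eight_leaf_bases
    ):
        from ploidpop.treespace import rf_matrix

        ts = simulate_gene_trees(eight_leaf_bases, [0.5, 0.5], 0.0, 40, seed=2)
        D = rf_matrix(ts)
        same = ts.truth[:, None] == ts.truth[None, :]
        assert (D[same] == 0).all()
        assert (D[~same] > 0).all()

    def test_mismatched_leaf_sets_rejected(self, rng):
        from ploidpop.containers import TreeSet

        t1 = random_topology(["a", "b", "c", "d"], rng)
        t2 = random_topology(["a", "b", "c", "e"], rng)
        tns = dendropy.TaxonNamespace(["a", "b", "c", "d", "e"])
        trees = dendropy.TreeList(taxon_namespace=tns)
        for t in (t1, t2):
            trees.append(
                dendropy.Tree.get(data=t.as_string(schema="newick"),
                                  schema="newick", taxon_namespace=tns)
            )
        with pytest.raises(ValueError, match="leaf set"):
            simulate_gene_trees(TreeSet(trees=trees), [0.5, 0.5], 0.0, 5, seed=0)

    def test_nni_moves_rf_exactly_two(self, rng):
        for _ in range(10):
            t = random_topology([f"s{i}" for i in range(8)], rng)
            assert rf_distance(t, random_nni(t, rng)) == 2


class TestRasters:
    def test_exact_suitable_cell_counts(self):
        cur, past = simulate_raster_pair(20, 20, 100, 50, seed=0)
        assert (cur.data >= 0.8).sum() == 100
        assert (past.data >= 0.8).sum() == 50

    def test_bit_identical_under_fixed_seed(self):
        a1, b1 = simulate_raster_pair(10, 10, 30, 10, seed=7)
        a2, b2 = simulate_raster_pair(10, 10, 30, 10, seed=7)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(b1.data, b2.data)

    def test_esri_ascii_round_trip(self, tmp_path):
        cur, _ = simulate_raster_pair(8, 12, 20, 5, seed=1)
        path = tmp_path / "cur.asc"
        write_esri_ascii(cur, str(path))
        back = read_esri_ascii(str(path))
        assert np.allclose(back.data, cur.data)
        assert back.cellsize == cur.cellsize

    def test_count_exceeding_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_raster_pair(3, 3, 10, 1, seed=0)
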