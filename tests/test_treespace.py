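"""RF distances, MDS, PAM + gap, NJ building, consistency test, gCF."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ploidpop import (
    LocusAlignment,
    build_tree,
    gene_concordance,
    mds_embed,
    pam,
    pam_gap,
    rf_distance,
    rf_matrix,
    simulate_gene_trees,
    simulate_jc_alignment,
    within_locus_consistency,
)
from ploidpop.containers import TreeSet
from ploidpop.simdata import random_nni, random_topology
from ploidpop.treespace import tree_splits

from conftest import make_base_pair


def brute_force_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Independent oracle: enumerate edges with networkx connectivity."""
    nx = pytest.importorskip("networkx")

    def splits(tree):
        g = nx.Graph()
        leaves = set()
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                g.add_edge(id(node.parent_node), id(node))
            if node.is_leaf():
                g.nodes[id(node)]["label"] = node.taxon.label
                leaves.add(node.taxon.label)
        out = set()
        ref = min(leaves)
        for u, v in list(g.edges()):
            h = g.copy()
            h.remove_edge(u, v)
            for comp in nx.connected_components(h):
                labs = frozenset(
                    g.nodes[n]["label"] for n in comp if "label" in g.nodes[n]
                )
                if 2 <= len(labs) <= len(leaves) - 2:
                    side = labs if ref not in labs else leaves - labs
                    if 2 <= len(side) <= len(leaves) - 2:
                        out.add(frozenset(side))
        return out

    return len(splits(t1) ^ splits(t2))


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, rng):
        t = random_topology(list("abcdefgh"), rng)
        assert rf_distance(t, t) == 0

    def test_four_leaf_alternatives_distance_two(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((a,c),(b,d));", schema="newick")
        assert rf_distance(t1, t2) == 2

    def test_matches_brute_force_oracle(self, rng):
        trees = [random_topology(list("abcdefgh"), rng) for _ in range(12)]
        for t1, t2 in itertools.combinations(trees, 2):
            assert rf_distance(t1, t2) == brute_force_rf(t1, t2)

    def test_matches_dendropy_oracle(self, rng):
        labels = [f"s{i}" for i in range(8)]
        tns = dendropy.TaxonNamespace(labels)
        trees = []
        for _ in range(10):
            t = random_topology(labels, rng)
            t = dendropy.Tree.get(
                data=t.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns,
            )
            t.encode_bipartitions()
            trees.append(t)
        from dendropy.calculate import treecompare

        for t1, t2 in itertools.combinations(trees, 2):
            assert rf_distance(t1, t2) == treecompare.symmetric_difference(
                t1, t2
            )

    def test_metric_properties(self, rng):
        trees = [random_topology(list("abcdefg"), rng) for _ in range(6)]
        for a, b, c in itertools.combinations(trees, 3):
            dab, dbc, dac = (
                rf_distance(a, b), rf_distance(b, c), rf_distance(a, c),
            )
            assert dab == rf_distance(b, a)
            assert dac <= dab + dbc

    def test_mismatched_leaves_named_in_error(self, rng):
        t1 = random_topology(list("abcd"), rng)
        t2 = random_topology(list("abce"), rng)
        with pytest.raises(ValueError, match="'d', 'e'"):
            rf_distance(t1, t2)

    def test_normalized_variant_bounded(self, rng):
        t1 = random_topology(list("abcdefgh"), rng)
        t2 = random_topology(list("abcdefgh"), rng)
        assert 0 <= rf_distance(t1, t2, normalized=True) <= 1


class TestMDS:
    def test_collinear_points_recovered_in_one_dimension(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        coords = mds_embed(D, dims=1)
        got = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        assert np.allclose(got, D, atol=1e-8)

    def test_round_trip_of_planar_point_set(self, rng):
        pts = rng.normal(size=(15, 2))
        D = cdist(pts, pts)
        coords = mds_embed(D, dims=2)
        assert np.allclose(cdist(coords, coords), D, atol=1e-8)

    def test_two_block_rf_matrix_separates(self, rng, eight_leaf_bases):
        ts = simulate_gene_trees(eight_leaf_bases, [0.5, 0.5], 0.2, 60, seed=4)
        D = rf_matrix(ts)
        coords = mds_embed(D, dims=2)
        a, b = coords[ts.truth == 0], coords[ts.truth == 1]
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        spread = max(a.std(axis=0).max(), b.std(axis=0).max())
        assert between > 2 * spread

    def test_excess_dimensions_reduced_with_warning(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        D = np.abs(x[:, None] - x[None, :])
        with pytest.warns(UserWarning, match="reduced"):
            coords = mds_embed(D, dims=3)
        assert coords.shape[1] < 3


class TestPAM:
    def test_two_blobs_perfect_assignment(self, rng):
        pts = np.vstack([
            rng.normal(0, 0.3, size=(25, 2)),
            rng.normal(5, 0.3, size=(25, 2)),
        ])
        D = cdist(pts, pts)
        medoids, idx, cost = pam(D, 2)
        assert len(set(idx[:25])) == 1 and len(set(idx[25:])) == 1
        assert idx[0] != idx[-1]

    def test_cost_not_worse_than_random_medoids(self, rng):
        pts = rng.normal(size=(40, 2))
        D = cdist(pts, pts)
        _, _, cost = pam(D, 3)
        for _ in range(20):
            med = rng.choice(40, 3, replace=False)
            assert cost <= D[:, med].min(axis=1).sum() + 1e-9

    def test_gap_selects_two_for_two_blobs(self, rng):
        pts = np.vstack([
            rng.normal(0, 0.5, size=(40, 2)),
            rng.normal(8, 0.5, size=(40, 2)),
        ])
        emb = pam_gap(cdist(pts, pts), k_max=8, B=30, seed=5)
        assert emb.k_star == 2

    def test_gap_single_blob_selects_one(self, rng):
        hits = 0
        for s in range(5):
            pts = np.random.default_rng(s).normal(size=(50, 2))
            emb = pam_gap(cdist(pts, pts), k_max=6, B=30, seed=s)
            hits += emb.k_star == 1
        assert hits >= 4

    def test_degenerate_identical_input_gives_one(self):
        D = np.zeros((20, 20))
        assert pam_gap(D, k_max=5, B=10, seed=0).k_star == 1


class TestBuildTree:
    def test_additive_distances_recover_topology(self):
        t = dendropy.Tree.get(
            data="((a:0.1,b:0.1):0.08,(c:0.1,d:0.1):0.08);", schema="newick"
        )
        aln = simulate_jc_alignment(t, 3000, seed=2)
        built = build_tree(aln)
        ref = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        assert rf_distance(built, ref) == 0

    def test_identical_sequences_give_star(self):
        aln = simulate_jc_alignment(
            dendropy.Tree.get(data="((a:0,b:0):0,(c:0,d:0):0);",
                              schema="newick"),
            300, seed=0,
        )
        star = build_tree(aln)
        _, splits = tree_splits(star)
        assert splits == frozenset()

    def test_saturated_distance_capped_with_warning(self):
        m = np.array([
            np.frombuffer(b"ACGT" * 25, dtype="S1"),
            np.frombuffer(b"CAGT" * 25, dtype="S1"),
            np.frombuffer(b"GTAC" * 25, dtype="S1"),  # 100% mismatch vs row 0
        ])
        aln = LocusAlignment("L", ["a", "b", "c"], [0] * 3,
                             ["a", "b", "c"], [1] * 3, m)
        with pytest.warns(UserWarning, match="saturated"):
            build_tree(aln)

    def test_recovery_on_fixed_six_leaf_tree(self, rng):
        base = dendropy.Tree.get(
            data="((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05,(e:0.1,f:0.1):0.05);",
            schema="newick",
        )
        ref = dendropy.Tree.get(data=base.as_string(schema="newick"),
                                schema="newick")
        hits = 0
        for _ in range(20):
            aln = simulate_jc_alignment(base, 500, seed=rng)
            hits += rf_distance(build_tree(aln), ref) == 0
        assert hits >= 19


def _species_locus(topology, locus_id, n_per_species=2, seq_len=400, seed=0):
    """Locus alignment where individuals within a species are identical."""
    rng = np.random.default_rng(seed)
    species = sorted(l.taxon.label for l in topology.leaf_node_iter())
    aln = simulate_jc_alignment(topology, seq_len, seed=rng)
    rows, inds, sps = [], [], []
    for sp in species:
        for k in range(n_per_species):
            rows.append(aln.matrix[aln.species_labels.index(sp)])
            inds.append(f"{sp}_{k}")
            sps.append(sp)
    return LocusAlignment(locus_id, inds, [0] * len(inds), sps,
                          [2] * len(inds), np.array(rows))


class TestConsistency:
    def _topologies(self, rng, n_species=6):
        labels = [f"sp{i}" for i in range(n_species)]
        ts = make_base_pair(labels, rng, min_rf=4)
        out = []
        for t in ts.trees:
            for e in t.preorder_edge_iter():
                e.length = 0.15
            out.append(t)
        return out

    def test_no_intraspecific_variation_gives_zero_within(self, rng):
        t1, t2 = self._topologies(rng)
        loci = [
            _species_locus(t1, "L1", seed=1),
            _species_locus(t1, "L2", seed=2),
            _species_locus(t2, "L3", seed=3),
            _species_locus(t2, "L4", seed=4),
        ]
        rep = within_locus_consistency(loci, n_replicates=4, seed=0)
        assert all(v == 0.0 for v in rep.within_locus_rf.values())
        assert rep.between_locus_rf > 0
        assert rep.verdict == "rapid_speciation_like"

    def test_planted_discordance_raises_within_score(self, rng):
        t1, t2 = self._topologies(rng)
        loci = []
        for i in range(4):
            rloc = np.random.default_rng(50 + i)
            a1 = simulate_jc_alignment(t1, 400, seed=rloc)
            a2 = simulate_jc_alignment(t2, 400, seed=rloc)
            rows, inds, sps = [], [], []
            species = sorted(l.taxon.label for l in t1.leaf_node_iter())
            for sp in species:
                for k, src in enumerate((a1, a2)):
                    rows.append(src.matrix[src.species_labels.index(sp)])
                    inds.append(f"{sp}_{k}")
                    sps.append(sp)
            loci.append(
                LocusAlignment(f"L{i}", inds, [0] * len(inds), sps,
                               [2] * len(inds), np.array(rows))
            )
        rep = within_locus_consistency(loci, n_replicates=6, seed=1)
        assert rep.median_within > 0
        assert rep.verdict == "ils_or_geneflow_like"

    def test_locus_missing_a_species_is_skipped(self, rng):
        t1, t2 = self._topologies(rng)
        full = _species_locus(t1, "full", seed=1)
        partial = _species_locus(t1, "partial", seed=2)
        keep = [i for i, s in enumerate(partial.species_labels) if s != "sp0"]
        partial = partial.take_rows(keep)
        rep = within_locus_consistency([full, partial], n_replicates=3, seed=0)
        assert rep.skipped_loci == ["partial"]
        assert rep.n_loci_used == 1


class TestConcordance:
    def test_fully_concordant_set_is_100(self, rng):
        sp = random_topology([f"s{i}" for i in range(8)], rng)
        genes = TreeSet(trees=dendropy.TreeList(
            [dendropy.Tree.get(data=sp.as_string(schema="newick"),
                               schema="newick") for _ in range(30)]
        ))
        table = gene_concordance(sp, genes)
        assert len(table.branches) == 5  # internal branches of 8-leaf tree
        assert all(b.gcf == 100.0 for b in table.branches)
        assert all(b.n_decisive == 30 for b in table.branches)

    def test_half_nni_mixture_gives_fifty_on_affected_branch(self, rng):
        sp = random_topology([f"s{i}" for i in range(8)], rng)
        alt = random_nni(sp, rng)
        trees = dendropy.TreeList()
        for src in (sp, alt):
            for _ in range(10):
                trees.append(
                    dendropy.Tree.get(data=src.as_string(schema="newick"),
                                      schema="newick")
                )
        table = gene_concordance(sp, TreeSet(trees=trees))
        gcfs = sorted(b.gcf for b in table.branches)
        assert gcfs[0] == 50.0
        assert all(g == 100.0 for g in gcfs[1:])

    def test_matches_direct_bipartition_counting(self, rng):
        """Oracle: count supporting trees per branch with dendropy encodings."""
        labels = [f"s{i}" for i in range(7)]
        sp = random_topology(labels, rng)
        genes = [random_topology(labels, rng) for _ in range(60)]
        table = gene_concordance(
            sp, TreeSet(trees=dendropy.TreeList(genes))
        )
        gene_splits = [tree_splits(g)[1] for g in genes]
        for b in table.branches:
            leaves = frozenset(labels)
            ref = min(leaves)
            X = b.bipartition
            side = X if ref not in X else leaves - X
            count = sum(side in s for s in gene_splits)
            assert b.n_decisive == 60  # full leaf overlap: all decisive
            assert b.n_concordant == count

    def test_unknown_gene_leaf_rejected(self, rng):
        sp = random_topology(list("abcd"), rng)
        bad = random_topology(list("abcz"), rng)
        with pytest.raises(ValueError, match="z"):
            gene_concordance(sp, TreeSet(trees=dendropy.TreeList([bad])))
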