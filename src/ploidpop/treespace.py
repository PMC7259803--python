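"""Gene-tree conflict analysis in Robinson-Foulds tree space.

The question this module answers: is gene-tree/species-tree conflict spread
uniformly through tree space (as expected under incomplete lineage sorting
or gene flow) or concentrated in a few clusters of alternative topologies
(as expected after rapid speciation)? The toolkit: unnormalized RF distances
between all gene trees, a classical multidimensional-scaling embedding of
the distance matrix, partitioning-around-medoids clustering with the gap
statistic selecting the cluster count, per-branch gene concordance factors,
and a within-locus consistency test that rebuilds each locus tree from
random one-individual-per-species subsamples.

Trees are handled as unrooted topologies; splits are leaf-label sets, so
trees from different sources compare correctly as long as labels match.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.spatial.distance import cdist

from .containers import LocusAlignment, TreeSet

# --------------------------------------------------------------------------- #
# Robinson-Foulds
# --------------------------------------------------------------------------- #


def tree_splits(tree: dendropy.Tree) -> tuple[frozenset, frozenset]:
    """(leaf set, set of non-trivial splits) of an unrooted topology.

    Each split is the canonical side -- the one not containing the
    lexicographically smallest leaf label -- as a frozenset of labels.
    """
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    n = len(leaves)
    splits = set()
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            group = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
            below[id(node)] = group
            if 2 <= len(group) <= n - 2:
                side = leaves - group if ref in group else group
                if 2 <= len(side) <= n - 2:
                    splits.add(side)
    return leaves, frozenset(splits)


def rf_distance(
    t1: dendropy.Tree, t2: dendropy.Tree, normalized: bool = False
) -> float:
    """Unnormalized RF: non-trivial splits present in exactly one tree."""
    l1, s1 = tree_splits(t1)
    l2, s2 = tree_splits(t2)
    if l1 != l2:
        diff = sorted(l1 ^ l2)
        raise ValueError(f"leaf sets differ; symmetric difference: {diff}")
    rf = len(s1 ^ s2)
    if normalized:
        denom = len(s1) + len(s2)
        return rf / denom if denom else 0.0
    return float(rf)


def rf_matrix(ts: TreeSet) -> np.ndarray:
    """Pairwise unnormalized RF matrix over a tree set."""
    parsed = [tree_splits(t) for t in ts.trees]
    leaf_sets = {p[0] for p in parsed}
    if len(leaf_sets) > 1:
        raise ValueError("trees must share one leaf set")
    n = len(parsed)
    D = np.zeros((n, n))
    for i in range(n):
        si = parsed[i][1]
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = len(si ^ parsed[j][1])
    return D


# --------------------------------------------------------------------------- #
# classical MDS
# --------------------------------------------------------------------------- #


def mds_embed(D: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centers -D^2/2, takes the top ``dims`` eigenpairs and scales
    eigenvectors by sqrt(eigenvalue); axes whose eigenvalues are not
    positive are dropped (with a warning when that truncates ``dims``).
    Sign convention: the first nonzero coordinate of each axis is positive.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.size else vals > 0
    n_pos = int(pos.sum())
    if n_pos < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding reduced from {dims}",
            stacklevel=2,
        )
    use = min(dims, max(n_pos, 1))
    coords = vecs[:, :use] * np.sqrt(np.maximum(vals[:use], 0.0))
    for a in range(coords.shape[1]):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return coords


# --------------------------------------------------------------------------- #
# PAM and the gap statistic
# --------------------------------------------------------------------------- #


def pam(D: np.ndarray, k: int, max_swaps: int = 200) -> tuple[np.ndarray, np.ndarray, float]:
    """Partitioning around medoids (build + swap) on a distance matrix.

    Returns (medoid indices, assignment, total cost). Deterministic: the
    build phase is the standard greedy, and the best improving swap is taken
    each round (lowest index on ties).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k < 1 or k > n:
        raise ValueError("k out of range")
    # build
    medoids = [int(np.argmin(D.sum(axis=0)))]
    d_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d_near[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        m = int(np.argmax(gain))
        medoids.append(m)
        d_near = np.minimum(d_near, D[:, m])
    medoids = np.array(sorted(medoids))
    for _ in range(max_swaps):
        dm = D[:, medoids]
        idx = np.argmin(dm, axis=1)
        d_near = dm[np.arange(n), idx]
        if k > 1:
            dm2 = dm.copy()
            dm2[np.arange(n), idx] = np.inf
            d_second = dm2.min(axis=1)
        else:
            d_second = np.full(n, np.inf)
        base = np.minimum(D - d_near[:, None], 0.0).sum(axis=0)
        best_delta, best_pair = -1e-12, None
        for mi in range(k):
            mask = idx == mi
            if not mask.any():
                cand = base - 0.0
            else:
                sub = D[mask]
                own = (
                    np.minimum(sub, d_second[mask][:, None])
                    - d_near[mask][:, None]
                ).sum(axis=0)
                cand = base - np.minimum(
                    sub - d_near[mask][:, None], 0.0
                ).sum(axis=0) + own
            cand[medoids] = np.inf
            h = int(np.argmin(cand))
            if cand[h] < best_delta:
                best_delta, best_pair = float(cand[h]), (mi, h)
        if best_pair is None:
            break
        medoids[best_pair[0]] = best_pair[1]
        medoids = np.array(sorted(medoids))
    dm = D[:, medoids]
    idx = np.argmin(dm, axis=1)
    cost = float(dm[np.arange(n), idx].sum())
    return medoids, idx, cost


@dataclass
class TreeSpaceEmbedding:
    """RF tree-space embedding with PAM clustering and the gap curve."""

    distance_matrix: np.ndarray
    coords: np.ndarray
    cluster_assignment: np.ndarray
    k_star: int
    gap_curve: np.ndarray  # columns: k, gap, s_k
    medoids: np.ndarray


def pam_gap(
    D: np.ndarray,
    k_max: int = 10,
    B: int = 50,
    seed: int | np.random.Generator = 0,
    dims: int = 2,
) -> TreeSpaceEmbedding:
    """Choose the cluster count by the gap statistic on MDS coordinates.

    PAM runs on the Euclidean distances of the ``dims``-dimensional
    embedding; the reference distribution is uniform over the bounding box
    of the coordinates (B draws per k). k* is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1} (the first-SE-max rule); degenerate inputs
    (all points coincident) return k* = 1.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < k_max + 1:
        raise ValueError("need at least k_max + 1 items")
    if np.allclose(D, 0.0):
        return TreeSpaceEmbedding(
            D, np.zeros((n, 1)), np.zeros(n, dtype=int), 1,
            np.zeros((0, 3)), np.array([0]),
        )
    coords = mds_embed(D, dims=dims)
    Dc = cdist(coords, coords)
    lo, hi = coords.min(axis=0), coords.max(axis=0)

    ks = np.arange(1, k_max + 1)
    log_w = np.empty(len(ks))
    results = {}
    for i, k in enumerate(ks):
        medoids, idx, cost = pam(Dc, int(k))
        results[int(k)] = (medoids, idx)
        log_w[i] = np.log(max(cost, 1e-12))
    ref_log_w = np.empty((B, len(ks)))
    for b in range(B):
        ref = lo + rng.random(coords.shape) * (hi - lo)
        Dr = cdist(ref, ref)
        for i, k in enumerate(ks):
            _, _, cost = pam(Dr, int(k))
            ref_log_w[b, i] = np.log(max(cost, 1e-12))
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    k_star = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            k_star = int(ks[i])
            break
    medoids, idx = results[k_star]
    return TreeSpaceEmbedding(
        distance_matrix=D,
        coords=coords,
        cluster_assignment=idx,
        k_star=k_star,
        gap_curve=np.column_stack([ks, gap, s]),
        medoids=medoids,
    )


# --------------------------------------------------------------------------- #
# distance-based tree building (desk-scale gene trees)
# --------------------------------------------------------------------------- #


def jc_distance_matrix(
    aln: LocusAlignment,
    labels: list[str] | None = None,
    saturation_cap: float = 5.0,
) -> tuple[np.ndarray, list[str]]:
    """Jukes-Cantor distances with pairwise-deletion overlap.

    d = -3/4 ln(1 - 4p/3); pairs with p >= 0.75 are saturated and set to
    ``saturation_cap`` with a warning.
    """
    m = aln.matrix
    valid = np.isin(m, [b"A", b"C", b"G", b"T"])
    n = m.shape[0]
    if labels is None:
        labels = list(aln.individual_ids)
    D = np.zeros((n, n))
    saturated = False
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        overlap = int(both.sum())
        if overlap == 0:
            raise ValueError(
                f"rows {labels[i]!r}/{labels[j]!r} share no comparable sites"
            )
        p = float((m[i, both] != m[j, both]).sum()) / overlap
        if p >= 0.75:
            d = saturation_cap
            saturated = True
        else:
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        D[i, j] = D[j, i] = d
    if saturated:
        warnings.warn("saturated JC distance capped", stacklevel=2)
    return D, labels


def build_tree(
    aln: LocusAlignment,
    method: str = "nj_jc69",
    labels: list[str] | None = None,
    collapse_tol: float = 1e-10,
) -> dendropy.Tree:
    """Neighbor-joining tree on Jukes-Cantor distances.

    Internal edges of (numerically) zero length are collapsed, so identical
    sequences yield a star tree. Requires >= 3 sequences.
    """
    if method != "nj_jc69":
        raise ValueError(f"unknown method {method!r}")
    if aln.n_rows < 3:
        raise ValueError("tree building requires >= 3 sequences")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    D, labels = jc_distance_matrix(aln, labels=labels)
    newick = str(nj(DistanceMatrix(D, ids=labels)))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    for edge in list(tree.postorder_edge_iter()):
        head = edge.head_node
        if (
            edge.tail_node is not None
            and not head.is_leaf()
            and edge.length is not None
            and edge.length < collapse_tol
        ):
            edge.collapse()
    return tree


# --------------------------------------------------------------------------- #
# within-locus consistency resampling test
# --------------------------------------------------------------------------- #


@dataclass
class ConsistencyReport:
    """Within- vs between-locus genealogy conflict summary.

    ``rapid_speciation_like``: replicate subsamples of a locus agree with
    each other (median within-locus RF at or below the threshold) while the
    per-locus consensus trees still conflict between loci.
    """

    within_locus_rf: dict[str, float]
    between_locus_rf: float
    verdict: str
    n_loci_used: int
    skipped_loci: list[str] = field(default_factory=list)
    consensus_trees: list[dendropy.Tree] = field(default_factory=list)

    @property
    def median_within(self) -> float:
        vals = list(self.within_locus_rf.values())
        return float(np.median(vals)) if vals else float("nan")


def _majority_consensus(trees: list[dendropy.Tree]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(
            dendropy.Tree.get(
                data=t.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=tns,
            )
        )
    # strictly-greater-than-half majority rule: exact ties stay out
    cons = tl.consensus(min_freq=0.5 + 1e-9)
    cons.is_rooted = False
    return cons


def within_locus_consistency(
    loci: list[LocusAlignment],
    n_replicates: int = 6,
    seed: int | np.random.Generator = 0,
    threshold: float = 0.0,
) -> ConsistencyReport:
    """Resample one individual per species per replicate and rebuild trees.

    Per locus the score is the mean pairwise RF among the replicate trees;
    between loci it is the mean pairwise RF among the per-locus majority-rule
    consensus trees. Loci where any species is missing are skipped.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    all_species = sorted({s for aln in loci for s in aln.species_labels})
    within: dict[str, float] = {}
    consensus: list[dendropy.Tree] = []
    skipped: list[str] = []
    for aln in loci:
        by_species: dict[str, list[int]] = {}
        for row, (ind, sp) in enumerate(
            zip(aln.individual_ids, aln.species_labels)
        ):
            by_species.setdefault(sp, []).append(row)
        if set(by_species) != set(all_species):
            skipped.append(aln.locus_id)
            continue
        rep_trees = []
        for _ in range(n_replicates):
            rows = []
            for sp in all_species:
                cand = by_species[sp]
                rows.append(cand[rng.integers(len(cand))])
            sub = aln.take_rows(rows)
            rep_trees.append(build_tree(sub, labels=list(all_species)))
        scores = [
            rf_distance(a, b)
            for a, b in itertools.combinations(rep_trees, 2)
        ]
        within[aln.locus_id] = float(np.mean(scores)) if scores else 0.0
        consensus.append(_majority_consensus(rep_trees))
    between_scores = [
        rf_distance(a, b) for a, b in itertools.combinations(consensus, 2)
    ]
    between = float(np.mean(between_scores)) if between_scores else 0.0
    med_within = float(np.median(list(within.values()))) if within else float("nan")
    verdict = (
        "rapid_speciation_like"
        if within and med_within <= threshold and between > threshold
        else "ils_or_geneflow_like"
    )
    return ConsistencyReport(
        within_locus_rf=within,
        between_locus_rf=between,
        verdict=verdict,
        n_loci_used=len(within),
        skipped_loci=skipped,
        consensus_trees=consensus,
    )


# --------------------------------------------------------------------------- #
# gene concordance factors
# --------------------------------------------------------------------------- #


@dataclass
class BranchConcordance:
    """gCF for one internal species-tree branch."""

    bipartition: frozenset
    gcf: float  # percent, nan when no decisive tree
    n_decisive: int
    n_concordant: int


@dataclass
class ConcordanceTable:
    branches: list[BranchConcordance]

    def as_dict(self) -> dict[frozenset, float]:
        return {b.bipartition: b.gcf for b in self.branches}


def _branch_groups(tree: dendropy.Tree):
    """For each internal edge: (split side, list of the four+ neighbor groups)."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        X = below[id(node)]
        Y = leaves - X
        if len(X) < 2 or len(Y) < 2:
            continue
        x_groups = [below[id(c)] for c in node.child_nodes()]
        tail = node.parent_node
        y_groups = [
            below[id(c)] for c in tail.child_nodes() if c is not node
        ]
        above = leaves - below[id(tail)]
        if above:
            y_groups.append(above)
        if len(y_groups) < 2:
            # tail is the root with two children: open up the sibling
            sib = [c for c in tail.child_nodes() if c is not node][0]
            if sib.is_leaf():
                continue  # |Y| < 2 handled above; defensive
            y_groups = [below[id(c)] for c in sib.child_nodes()]
        out.append((X, x_groups + y_groups))
    return out


def gene_concordance(
    species_tree: dendropy.Tree, gene_trees: TreeSet
) -> ConcordanceTable:
    """Per-branch gene concordance factors.

    For each internal species-tree branch, gCF is the percentage of decisive
    gene trees (those with at least one leaf in every neighbor group of the
    branch) whose induced topology contains the branch's bipartition.
    """
    sp_leaves = frozenset(
        l.taxon.label for l in species_tree.leaf_node_iter()
    )
    gene_info = []
    for t in gene_trees.trees:
        leaves, splits = tree_splits(t)
        if not leaves <= sp_leaves:
            raise ValueError(
                f"gene-tree leaves not in species tree: {sorted(leaves - sp_leaves)}"
            )
        gene_info.append((leaves, splits))
    seen = set()
    branches = []
    for X, groups in _branch_groups(species_tree):
        canon_full = min(X, sp_leaves - X, key=lambda s: (len(s), sorted(s)))
        if canon_full in seen:
            continue
        seen.add(canon_full)
        n_dec = n_con = 0
        for leaves, splits in gene_info:
            if not all(leaves & g for g in groups):
                continue
            n_dec += 1
            xl = X & leaves
            ref = min(leaves)
            side = (leaves - xl) if ref in xl else xl
            if side in splits:
                n_con += 1
        gcf = 100.0 * n_con / n_dec if n_dec else float("nan")
        branches.append(
            BranchConcordance(
                bipartition=canon_full,
                gcf=gcf,
                n_decisive=n_dec,
                n_concordant=n_con,
            )
        )
    return ConcordanceTable(branches=branches)
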