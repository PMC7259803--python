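"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators here are first-class, tested code: read counts at biallelic
sites under diploid/triploid/tetraploid genotypes with tetrasomic (one
panmictic chromosome pool) or disomic (two fixed subgenomes) inheritance and
sequencing noise; neutral coalescent locus alignments; gene-tree sets drawn
from a mixture of base topologies; and paired suitability rasters with known
suitable-cell counts.

The key biological mechanism the genotype generator reproduces: a disomic
(allotetraploid-like) individual carries two subgenomes, and sites that are
fixed inter-subgenome differences have dosage exactly 2 of 4 -- an excess of
intermediate-frequency (AABB) sites relative to a tetrasomic tetraploid at
the same allele-frequency prior, which never concentrates mass at dosage 2
beyond the binomial expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .containers import LocusAlignment, SiteAlleleCounts, SuitabilityRaster, TreeSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")

VALID_MODES = {"tetrasomic", "disomic", "none"}


class ConfigurationError(ValueError):
    """Invalid simulation parameter combination."""


@dataclass
class SimConfig:
    """Free parameters of the read-count simulator.

    Parameters
    ----------
    seed:
        Base seed; every generator is bit-reproducible given it.
    n_sites:
        Number of candidate sites simulated per individual.
    mean_depth:
        Poisson rate (reads/site); realized depth is truncated to >= 1.
    error_rate:
        Per-read symmetric base-miscall probability, in [0, 0.5).
    ploidy:
        2, 3 or 4.
    inheritance_mode:
        ``tetrasomic`` (one pool; also used for diploids/triploids),
        ``disomic`` (two subgenomes; tetraploids only) or ``none``.
    fixed_diff_prob:
        Probability that a site is a fixed inter-subgenome difference
        (disomic mode only).
    maf_alpha:
        Shape of the symmetric Beta(a, a) allele-frequency prior; the default
        0.2 mimics a neutral-SFS-like excess of rare variants.
    """

    seed: int = 0
    n_sites: int = 5000
    mean_depth: float = 50.0
    error_rate: float = 0.005
    ploidy: int = 4
    inheritance_mode: str = "tetrasomic"
    fixed_diff_prob: float = 0.0
    maf_alpha: float = 0.2

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must lie in [0, 0.5)")
        if self.ploidy not in (2, 3, 4):
            raise ConfigurationError("ploidy must be 2, 3 or 4")
        if self.inheritance_mode not in VALID_MODES:
            raise ConfigurationError(f"unknown inheritance mode {self.inheritance_mode!r}")
        if self.inheritance_mode == "disomic" and self.ploidy != 4:
            raise ConfigurationError("disomic inheritance requires ploidy 4")
        if not 0 <= self.fixed_diff_prob <= 1:
            raise ConfigurationError("fixed_diff_prob must lie in [0, 1]")
        if self.maf_alpha <= 0:
            raise ConfigurationError("maf_alpha must be positive")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be positive")


@dataclass
class GenotypeVector:
    """Per-site alternate-allele dosages with truth labels for recovery tests."""

    dosages: np.ndarray
    site_truth: np.ndarray  # {"invariant", "biallelic"} w.r.t. the individual
    ploidy: int

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int64)
        self.site_truth = np.asarray(self.site_truth)
        if ((self.dosages < 0) | (self.dosages > self.ploidy)).any():
            raise ValueError("dosage out of [0, ploidy] bounds")
        if len(self.dosages) != len(self.site_truth):
            raise ValueError("truth labels must match dosage length")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def population_frequencies(
    n_sites: int, maf_alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-site population alternate-allele frequencies from Beta(a, a)."""
    return rng.beta(maf_alpha, maf_alpha, size=n_sites)


# --------------------------------------------------------------------------- #
# genotypes and read counts
# --------------------------------------------------------------------------- #


def simulate_genotypes(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    freqs: np.ndarray | None = None,
    freqs2: np.ndarray | None = None,
) -> GenotypeVector:
    """Simulate per-site alternate-allele dosages for one individual.

    Diploids and tetrasomic polyploids draw ``dosage ~ Binomial(ploidy, q)``
    from one panmictic pool; a disomic tetraploid draws
    ``Binomial(2, q1) + Binomial(2, q2)`` from two subgenomes, and with
    probability ``fixed_diff_prob`` a site is a fixed inter-subgenome
    difference (q1=0, q2=1), forcing dosage exactly 2.

    ``freqs``/``freqs2`` override the prior draw with explicit population
    frequencies (used to give individuals of a cohort shared coordinates).
    """
    rng = _rng(cfg.seed if rng is None else rng)
    if freqs is None:
        freqs = population_frequencies(cfg.n_sites, cfg.maf_alpha, rng)
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    if cfg.inheritance_mode == "disomic":
        q2 = freqs if freqs2 is None else np.asarray(freqs2, dtype=float)
        dosage = rng.binomial(2, freqs) + rng.binomial(2, q2)
        fixed = rng.random(n) < cfg.fixed_diff_prob
        dosage[fixed] = 2
    else:
        dosage = rng.binomial(cfg.ploidy, freqs)
    truth = np.where(
        (dosage > 0) & (dosage < cfg.ploidy), "biallelic", "invariant"
    )
    return GenotypeVector(dosages=dosage, site_truth=truth, ploidy=cfg.ploidy)


def simulate_read_counts(
    gt: GenotypeVector,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    individual_id: str = "ind0",
    species_label: str = "sp0",
    locus_id: str = "locus0",
) -> SiteAlleleCounts:
    """Sequence a genotype vector: Poisson depth (>=1), binomial allele reads.

    The per-read probability of observing the alternate allele is
    ``f = (k/p)(1 - eps) + (1 - k/p) eps`` for dosage ``k`` and ploidy ``p``
    under the symmetric biallelic miscall model.
    """
    if gt.ploidy != cfg.ploidy:
        raise ConfigurationError("genotype ploidy does not match config")
    rng = _rng(cfg.seed + 1 if rng is None else rng)
    n = len(gt.dosages)
    # truncated Poisson via inverse CDF on U(e^-lam, 1)
    depth = _truncated_poisson(cfg.mean_depth, n, rng)
    frac = gt.dosages / gt.ploidy
    f = frac * (1 - cfg.error_rate) + (1 - frac) * cfg.error_rate
    alt = rng.binomial(depth, f)
    return SiteAlleleCounts(
        individual_id=individual_id,
        species_label=species_label,
        locus_ids=np.full(n, locus_id),
        site_index=np.arange(n),
        count_a=depth - alt,
        count_b=alt,
        count_other=np.zeros(n, dtype=np.int64),
    )


def _truncated_poisson(lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, vectorized by resampling zeros."""
    depth = rng.poisson(lam, size=n)
    zero = depth == 0
    while zero.any():
        depth[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = depth == 0
    return depth


def simulate_biallelic_individual(
    ploidy: int,
    n_biallelic: int,
    rng: np.random.Generator | int = 0,
    mean_depth: float = 50.0,
    error_rate: float = 0.005,
    maf_alpha: float = 0.2,
    individual_id: str = "ind0",
    species_label: str = "sp0",
) -> SiteAlleleCounts:
    """Read counts for exactly ``n_biallelic`` individual-heterozygous sites.

    Dosages are drawn from the prior conditioned on heterozygosity
    (0 < dosage < ploidy), the site class whose read-frequency signature the
    ploidy fit consumes.
    """
    rng = _rng(rng)
    cfg = SimConfig(
        seed=0,
        n_sites=n_biallelic,
        mean_depth=mean_depth,
        error_rate=error_rate,
        ploidy=ploidy,
        inheritance_mode="none" if ploidy != 4 else "tetrasomic",
        maf_alpha=maf_alpha,
    )
    dosages = np.empty(0, dtype=np.int64)
    while len(dosages) < n_biallelic:
        q = population_frequencies(4 * n_biallelic, maf_alpha, rng)
        d = rng.binomial(ploidy, q)
        d = d[(d > 0) & (d < ploidy)]
        dosages = np.concatenate([dosages, d])
    gt = GenotypeVector(
        dosages=dosages[:n_biallelic],
        site_truth=np.full(n_biallelic, "biallelic"),
        ploidy=ploidy,
    )
    return simulate_read_counts(
        gt, cfg, rng=rng, individual_id=individual_id,
        species_label=species_label,
    )


# --------------------------------------------------------------------------- #
# cohorts on shared site coordinates (inheritance-mode experiments)
# --------------------------------------------------------------------------- #


@dataclass
class Cohort:
    """Simulated individuals of a two-species system on shared coordinates."""

    diploids: list[SiteAlleleCounts]
    tetrasomic: list[SiteAlleleCounts]
    disomic: list[SiteAlleleCounts]
    freq_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    freq_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    fixed_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


def species_pair_frequencies(
    n_sites: int,
    maf_alpha: float,
    fixed_diff_prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population frequencies for a sister-species pair.

    Both species share the ancestral frequency at ordinary sites; with
    probability ``fixed_diff_prob`` a site is a fixed difference between the
    species (q_x = 0, q_y = 1).
    """
    q = population_frequencies(n_sites, maf_alpha, rng)
    fixed = rng.random(n_sites) < fixed_diff_prob
    qx, qy = q.copy(), q.copy()
    qx[fixed] = 0.0
    qy[fixed] = 1.0
    return qx, qy, fixed


def simulate_inheritance_cohort(
    cfg: SimConfig,
    n_diploids_per_species: int = 8,
    n_tetrasomic: int = 8,
    n_disomic: int = 8,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Simulate diploids of two sister species plus observed tetraploids.

    A tetraploid genome holds two chromosome-pair sets, and its sequencing
    is modelled as the pooled sequencing of those two sets (each a
    diploid-like draw at ``mean_depth``), so an observed tetraploid has the
    same read-count law as the corresponding in-silico combination of two
    diploids: a tetrasomic tetraploid pools two sets drawn from the species
    X frequency pool (dosage ``Binomial(2, q_x) + Binomial(2, q_x)``, i.e.
    ``Binomial(4, q_x)``); a disomic tetraploid pools one subgenome from
    each species, so fixed inter-species differences surface as dosage-2
    (AABB) sites -- the excess-of-intermediate-frequencies mechanism the
    pairwise diploid combinations model downstream.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    qx, qy, fixed = species_pair_frequencies(
        cfg.n_sites, cfg.maf_alpha, cfg.fixed_diff_prob, rng
    )
    dip_cfg = SimConfig(
        seed=cfg.seed,
        n_sites=cfg.n_sites,
        mean_depth=cfg.mean_depth,
        error_rate=cfg.error_rate,
        maf_alpha=cfg.maf_alpha,
        ploidy=2,
        inheritance_mode="none",
    )

    def diploid_draw(q: np.ndarray, name: str, species: str) -> SiteAlleleCounts:
        gt = simulate_genotypes(dip_cfg, rng=rng, freqs=q)
        return simulate_read_counts(
            gt, dip_cfg, rng=rng, individual_id=name, species_label=species
        )

    def pooled_tetraploid(
        q1: np.ndarray, q2: np.ndarray, name: str, species: str
    ) -> SiteAlleleCounts:
        half_a = diploid_draw(q1, name, species)
        half_b = diploid_draw(q2, name, species)
        return SiteAlleleCounts(
            individual_id=name,
            species_label=species,
            locus_ids=half_a.locus_ids,
            site_index=half_a.site_index,
            count_a=half_a.count_a + half_b.count_a,
            count_b=half_a.count_b + half_b.count_b,
            count_other=half_a.count_other + half_b.count_other,
        )

    diploids = []
    for species, q in (("X", qx), ("Y", qy)):
        for i in range(n_diploids_per_species):
            diploids.append(diploid_draw(q, f"{species}{i}", species))
    tetrasomic = [
        pooled_tetraploid(qx, qx, f"T{i}", "tet_tetrasomic")
        for i in range(n_tetrasomic)
    ]
    disomic = [
        pooled_tetraploid(qx, qy, f"D{i}", "tet_disomic")
        for i in range(n_disomic)
    ]
    return Cohort(diploids, tetrasomic, disomic, qx, qy, fixed)


# --------------------------------------------------------------------------- #
# neutral coalescent alignments
# --------------------------------------------------------------------------- #


class LocusLengthError(ValueError):
    """More segregating sites realized than the locus can hold."""


def _coalescent_genealogy(
    n: int, growth: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hudson's algorithm: returns (parent, node_time, branch_length).

    Times are in coalescent units; with exponential growth rate ``g`` the
    coalescence rate at (backward) time t is C(j,2)·e^{g t}.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    lineages = list(range(n))
    t = 0.0
    nxt = n
    while len(lineages) > 1:
        j = len(lineages)
        rate = j * (j - 1) / 2.0
        e = rng.exponential()
        if growth == 0.0:
            t += e / rate
        else:
            t = math.log(math.exp(growth * t) + growth * e / rate) / growth
        i1, i2 = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[i1], lineages[i2]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        for x in sorted((i1, i2), reverse=True):
            lineages.pop(x)
        lineages.append(nxt)
        nxt += 1
    brlen = np.zeros(n_nodes)
    has_parent = parent >= 0
    brlen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent, node_time, brlen


def _genealogy_to_tree(
    parent: np.ndarray, brlen: np.ndarray, labels: list[str]
) -> dendropy.Tree:
    n = len(labels)
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = {}
    for i in range(len(parent)):
        node = dendropy.Node()
        node.edge.length = float(brlen[i])
        if i < n:
            node.taxon = tns.get_taxon(labels[i])
        nodes[i] = node
    root = None
    for i, p in enumerate(parent):
        if p < 0:
            root = nodes[i]
        else:
            nodes[p].add_child(nodes[i])
    tree.seed_node = root
    return tree


def _descendant_leaves(parent: np.ndarray, n_leaves: int) -> list[np.ndarray]:
    """Boolean leaf membership below each node."""
    n_nodes = len(parent)
    below = [np.zeros(n_leaves, dtype=bool) for _ in range(n_nodes)]
    for i in range(n_leaves):
        below[i][i] = True
        p = parent[i]
        while p >= 0:
            below[p][i] = True
            p = parent[p]
    return below


def simulate_coalescent_alignment(
    n_haplotypes: int,
    theta: float,
    locus_length: int,
    growth: float = 0.0,
    seed: int | np.random.Generator = 0,
    locus_id: str = "locus0",
    species_label: str = "sp0",
    individual_prefix: str = "ind",
) -> tuple[LocusAlignment, dendropy.Tree]:
    """Neutral coalescent locus under the infinite-sites model.

    Mutation count is Poisson(theta * T_total / 2) with T_total the total
    branch length in coalescent units, each mutation placed uniformly on the
    genealogy and mapped to a distinct alignment column; remaining columns
    are monomorphic. Raises :class:`LocusLengthError` when the realized
    number of segregating sites exceeds ``locus_length``.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = _rng(seed)
    parent, _, brlen = _coalescent_genealogy(n_haplotypes, growth, rng)
    total = float(brlen.sum())
    n_mut = rng.poisson(theta * total / 2.0) if theta > 0 else 0
    if n_mut > locus_length:
        raise LocusLengthError(
            f"{n_mut} segregating sites exceed locus length {locus_length}"
        )
    anc_idx = rng.integers(0, 4, size=locus_length)
    matrix = np.tile(_BASES[anc_idx], (n_haplotypes, 1))
    if n_mut:
        positions = rng.choice(locus_length, size=n_mut, replace=False)
        branch_p = brlen / total
        branches = rng.choice(len(brlen), size=n_mut, p=branch_p)
        below = _descendant_leaves(parent, n_haplotypes)
        for pos, br in zip(positions, branches):
            derived = _BASES[(anc_idx[pos] + rng.integers(1, 4)) % 4]
            matrix[below[br], pos] = derived
    labels = [f"{individual_prefix}{i}" for i in range(n_haplotypes)]
    aln = LocusAlignment(
        locus_id=locus_id,
        individual_ids=labels,
        haplotype_index=[0] * n_haplotypes,
        species_labels=[species_label] * n_haplotypes,
        ploidies=[1] * n_haplotypes,
        matrix=matrix,
    )
    return aln, _genealogy_to_tree(parent, brlen, labels)


def simulate_jc_alignment(
    tree: dendropy.Tree,
    seq_length: int,
    seed: int | np.random.Generator = 0,
    rate_scale: float = 1.0,
    species_from_labels: bool = True,
    ploidy: int = 1,
) -> LocusAlignment:
    """Finite-sites Jukes-Cantor simulation along a tree with branch lengths.

    Provides NJ-tree fixtures where the infinite-sites generator is
    unsuitable. Tip labels become both individual and species labels.
    """
    rng = _rng(seed)
    root = tree.seed_node
    seqs: dict[int, np.ndarray] = {id(root): rng.integers(0, 4, size=seq_length)}
    tips: list[tuple[str, np.ndarray]] = []
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            d = (node.edge.length or 0.0) * rate_scale
            p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            parent_seq = seqs[id(node.parent_node)]
            seq = parent_seq.copy()
            hit = rng.random(seq_length) < p_change
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
            seqs[id(node)] = seq
        if node.is_leaf():
            tips.append((node.taxon.label, seqs[id(node)]))
    matrix = np.array([_BASES[s] for _, s in tips])
    labels = [lab for lab, _ in tips]
    return LocusAlignment(
        locus_id="locus0",
        individual_ids=labels,
        haplotype_index=[0] * len(labels),
        species_labels=labels if species_from_labels else ["sp0"] * len(labels),
        ploidies=[ploidy] * len(labels),
        matrix=matrix,
    )


# --------------------------------------------------------------------------- #
# gene-tree sets
# --------------------------------------------------------------------------- #


def random_topology(
    labels: list[str], rng: np.random.Generator | int = 0
) -> dendropy.Tree:
    """Uniform random binary topology by sequential random joins."""
    rng = _rng(rng)
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        node.edge.length = 1.0
        nodes.append(node)
    while len(nodes) > 1:
        i1, i2 = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i1], nodes[i2]
        joined = dendropy.Node()
        joined.edge.length = 1.0
        joined.add_child(a)
        joined.add_child(b)
        for x in sorted((int(i1), int(i2)), reverse=True):
            nodes.pop(x)
        nodes.append(joined)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = False
    return tree


def random_nni(
    tree: dendropy.Tree, rng: np.random.Generator | int = 0
) -> dendropy.Tree:
    """Return a copy of ``tree`` perturbed by one random nearest-neighbour
    interchange across a random internal edge (unrooted move)."""
    rng = _rng(rng)
    out = tree.clone(depth=1)
    if len(out.seed_node.child_nodes()) == 2:
        # a bifurcating seed is an artifact of rooted storage; collapse it so
        # every candidate edge is a genuine internal edge of the unrooted tree
        out.deroot()
    candidates = []
    for edge in out.preorder_edge_iter():
        head, tail = edge.head_node, edge.tail_node
        if tail is None or head.is_leaf():
            continue
        tail_others = [c for c in tail.child_nodes() if c is not head]
        if not tail_others:
            continue
        candidates.append((head, tail, tail_others))
    if not candidates:
        return out
    head, tail, tail_others = candidates[rng.integers(len(candidates))]
    child = head.child_nodes()[rng.integers(len(head.child_nodes()))]
    swap = tail_others[rng.integers(len(tail_others))]
    head.remove_child(child)
    tail.remove_child(swap)
    head.add_child(swap)
    tail.add_child(child)
    return out


def simulate_gene_trees(
    base_topologies: TreeSet,
    weights: np.ndarray,
    nni_prob: float,
    n_trees: int,
    seed: int | np.random.Generator = 0,
) -> TreeSet:
    """Draw trees from a topology mixture, each perturbed by one random NNI
    with probability ``nni_prob``; generator labels retained in ``truth``."""
    rng = _rng(seed)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(base_topologies):
        raise ValueError("one weight per base topology required")
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("weights must sum to 1")
    leaf_sets = [
        frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
        for tree in base_topologies.trees
    ]
    if len(set(leaf_sets)) != 1:
        raise ValueError("base topologies must share one leaf set")
    tns = base_topologies.taxon_namespace
    trees = dendropy.TreeList(taxon_namespace=tns)
    truth = rng.choice(len(weights), size=n_trees, p=weights)
    for k in truth:
        base = base_topologies.trees[int(k)]
        if rng.random() < nni_prob:
            trees.append(random_nni(base, rng))
        else:
            trees.append(base.clone(depth=1))
    return TreeSet(trees=trees, truth=truth)


# --------------------------------------------------------------------------- #
# suitability rasters
# --------------------------------------------------------------------------- #


def simulate_raster_pair(
    nrow: int,
    ncol: int,
    current_suitable_cells: int,
    past_suitable_cells: int,
    seed: int | np.random.Generator = 0,
    xllcorner: float = 115.0,
    yllcorner: float = -35.0,
    cellsize: float = 0.05,
) -> tuple[SuitabilityRaster, SuitabilityRaster]:
    """Paired current/past rasters with exact suitable-cell counts.

    Suitable cells get probability drawn from (0.8, 1]; the remainder from
    [0, 0.8), so a 0.8-inclusive threshold recovers the counts exactly.
    """
    rng = _rng(seed)
    rasters = []
    for k in (current_suitable_cells, past_suitable_cells):
        ncell = nrow * ncol
        if k > ncell:
            raise ValueError("suitable cell count exceeds grid size")
        grid = rng.random(ncell) * 0.8
        idx = rng.choice(ncell, size=k, replace=False)
        grid[idx] = 0.8 + 0.2 * (1.0 - rng.random(k))
        rasters.append(
            SuitabilityRaster(
                data=grid.reshape(nrow, ncol),
                xllcorner=xllcorner,
                yllcorner=yllcorner,
                cellsize=cellsize,
            )
        )
    return rasters[0], rasters[1]
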