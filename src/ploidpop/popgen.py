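"""Locus-wise population-genetic summary statistics on haplotype alignments.

Statistics are haplotype-based: a diploid contributes up to two rows and a
tetraploid up to four, so all estimators operate on the phased rows of a
:class:`~ploidpop.containers.LocusAlignment` directly.

Site filtering mirrors the upstream convention: only invariant and biallelic
sites are analysed, sites with more than two nucleotide alleles are dropped,
sites containing any gap or N are dropped before allele counting
(complete-deletion policy; pairwise deletion available as a switch), and a
locus is retained only when strictly more than ``min_sites`` (default 100)
sites survive.

Estimators: nucleotide diversity pi (mean pairwise difference per kept
site), Watterson's theta S/(a1 L), Tajima's D with the standard constants,
between-species dxy, and the Hudson-type Fst = 1 - Hw/Hb.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import LocusAlignment

_ACGT = [b"A", b"C", b"G", b"T"]


# --------------------------------------------------------------------------- #
# site filtering
# --------------------------------------------------------------------------- #


@dataclass
class SiteFilterResult:
    """Bookkeeping of the per-site filters for one locus."""

    locus_id: str
    kept_sites: np.ndarray
    n_invariant: int
    n_biallelic: int
    n_dropped_multiallelic: int
    n_dropped_gap: int
    min_sites: int

    @property
    def n_kept(self) -> int:
        return len(self.kept_sites)

    @property
    def passes(self) -> bool:
        # "more than min_sites" is strict
        return self.n_kept > self.min_sites


def filter_locus(
    aln: LocusAlignment, min_sites: int = 100, gap_policy: str = "complete"
) -> SiteFilterResult:
    """Classify each column as invariant / biallelic / multiallelic / gappy.

    With the default complete-deletion policy a column containing any gap or
    N is dropped outright; with ``pairwise`` the column is kept (pair
    overlaps handle the gaps downstream) unless it has no unambiguous base
    at all.
    """
    if aln.n_rows == 0 or aln.length == 0:
        raise ValueError("empty alignment")
    m = aln.matrix
    present = np.stack([(m == b).any(axis=0) for b in _ACGT])
    n_alleles = present.sum(axis=0)
    gappy = ~np.isin(m, _ACGT).all(axis=0)
    if gap_policy == "complete":
        drop_gap = gappy
    elif gap_policy == "pairwise":
        drop_gap = n_alleles == 0
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    multi = (n_alleles > 2) & ~drop_gap
    invariant = (n_alleles == 1) & ~drop_gap
    biallelic = (n_alleles == 2) & ~drop_gap
    kept = np.flatnonzero(invariant | biallelic)
    return SiteFilterResult(
        locus_id=aln.locus_id,
        kept_sites=kept,
        n_invariant=int(invariant.sum()),
        n_biallelic=int(biallelic.sum()),
        n_dropped_multiallelic=int(multi.sum()),
        n_dropped_gap=int(drop_gap.sum()),
        min_sites=min_sites,
    )


def filtered_alignment(
    aln: LocusAlignment, result: SiteFilterResult | None = None, **kwargs
) -> LocusAlignment:
    """Alignment restricted to the kept columns."""
    if result is None:
        result = filter_locus(aln, **kwargs)
    return LocusAlignment(
        locus_id=aln.locus_id,
        individual_ids=aln.individual_ids,
        haplotype_index=aln.haplotype_index,
        species_labels=aln.species_labels,
        ploidies=aln.ploidies,
        matrix=aln.matrix[:, result.kept_sites],
    )


# --------------------------------------------------------------------------- #
# per-locus statistics
# --------------------------------------------------------------------------- #


@dataclass
class LocusStats:
    """Summary statistics for one locus and one species (or species pair)."""

    locus_id: str
    species: str
    n_haplotypes: int
    n_sites: int
    S: int
    pi: float
    theta_w: float
    tajimas_d: float  # nan when S == 0
    fst: float = float("nan")
    dxy: float = float("nan")


def _column_base_counts(m: np.ndarray) -> np.ndarray:
    """(4, L) counts of A,C,G,T per column."""
    return np.stack([(m == b).sum(axis=0) for b in _ACGT])


def _pairwise_diff_total(m: np.ndarray) -> tuple[float, int]:
    """Sum over columns of pairwise-different haplotype pairs, plus S."""
    counts = _column_base_counts(m)
    n = counts.sum(axis=0)  # per-column sample size (gap-free after filter)
    pairs_diff = (n * n - (counts * counts).sum(axis=0)) / 2.0
    seg = ((counts > 0).sum(axis=0) >= 2).sum()
    return float(pairs_diff.sum()), int(seg)


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from segregating sites and total mean pairwise difference.

    Uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2 in the sample
    size n; returns nan when S = 0 (the statistic is undefined).
    """
    if S == 0 or n < 2:
        return float("nan")
    a1 = _a1(n)
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / a1) / np.sqrt(var)


def diversity_stats(
    aln: LocusAlignment,
    species: str,
    min_sites: int = 100,
    prefiltered: bool = False,
) -> LocusStats:
    """Within-species pi, Watterson's theta and Tajima's D for one locus.

    The site filter runs on the full alignment (all species) unless
    ``prefiltered``; statistics then use the species' haplotype rows only.
    """
    work = aln if prefiltered else filtered_alignment(aln, min_sites=min_sites)
    rows = np.flatnonzero(work.rows_for_species(species))
    if len(rows) < 2:
        raise ValueError(f"species {species!r} has < 2 haplotypes at {aln.locus_id}")
    m = work.matrix[rows]
    L = m.shape[1]
    n = len(rows)
    diff_total, S = _pairwise_diff_total(m)
    n_pairs = n * (n - 1) / 2.0
    pi_total = diff_total / n_pairs
    pi = pi_total / L if L else 0.0
    theta_w = S / (_a1(n) * L) if L else 0.0
    return LocusStats(
        locus_id=aln.locus_id,
        species=species,
        n_haplotypes=n,
        n_sites=L,
        S=S,
        pi=pi,
        theta_w=theta_w,
        tajimas_d=tajimas_d(S, n, pi_total),
    )


def pairwise_fst(
    aln: LocusAlignment,
    species_a: str,
    species_b: str,
    min_sites: int = 100,
    prefiltered: bool = False,
) -> LocusStats:
    """Hudson-type Fst = 1 - Hw/Hb and dxy for one locus and species pair.

    Hw averages the two within-species mean pairwise diversities; Hb is the
    mean between-species pairwise difference. Fst is undefined (nan) when
    Hb = 0.
    """
    work = aln if prefiltered else filtered_alignment(aln, min_sites=min_sites)
    ra = np.flatnonzero(work.rows_for_species(species_a))
    rb = np.flatnonzero(work.rows_for_species(species_b))
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError("both species need >= 2 haplotypes")
    ma, mb = work.matrix[ra], work.matrix[rb]
    L = ma.shape[1]
    na, nb = len(ra), len(rb)
    diff_a, _ = _pairwise_diff_total(ma)
    diff_b, _ = _pairwise_diff_total(mb)
    hw_a = diff_a / (na * (na - 1) / 2.0)
    hw_b = diff_b / (nb * (nb - 1) / 2.0)
    ca = _column_base_counts(ma)
    cb = _column_base_counts(mb)
    between = float((na * nb - (ca * cb).sum(axis=0)).sum())
    hb = between / (na * nb)
    hw = 0.5 * (hw_a + hw_b)
    fst = 1.0 - hw / hb if hb > 0 else float("nan")
    diff_all, S_all = _pairwise_diff_total(np.vstack([ma, mb]))
    n = na + nb
    pi_total = diff_all / (n * (n - 1) / 2.0)
    return LocusStats(
        locus_id=aln.locus_id,
        species=f"{species_a}|{species_b}",
        n_haplotypes=n,
        n_sites=L,
        S=S_all,
        pi=pi_total / L if L else 0.0,
        theta_w=S_all / (_a1(n) * L) if L else 0.0,
        tajimas_d=tajimas_d(S_all, n, pi_total),
        fst=fst,
        dxy=hb / L if L else float("nan"),
    )


# --------------------------------------------------------------------------- #
# across-locus aggregation and clustering
# --------------------------------------------------------------------------- #


@dataclass
class SpeciesMatrix:
    """Symmetric species-by-species summary matrix."""

    labels: list[str]
    matrix: np.ndarray
    kind: str = "median_fst"
    linkage: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")


def aggregate_fst(
    loci: list[LocusAlignment],
    species: list[str],
    min_sites: int = 100,
) -> SpeciesMatrix:
    """Median across loci of per-locus pairwise Hudson Fst (S10-style matrix).

    Loci failing the site filter, lacking haplotypes, or with undefined Fst
    are excluded from the medians.
    """
    k = len(species)
    mat = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        vals = []
        for aln in loci:
            result = filter_locus(aln, min_sites=min_sites)
            if not result.passes:
                continue
            try:
                st = pairwise_fst(
                    filtered_alignment(aln, result), species[i], species[j],
                    prefiltered=True,
                )
            except ValueError:
                continue
            if np.isfinite(st.fst):
                vals.append(st.fst)
        mat[i, j] = mat[j, i] = float(np.median(vals)) if vals else np.nan
    return SpeciesMatrix(labels=list(species), matrix=mat, kind="median_fst")


def diversity_matrix(
    loci: list[LocusAlignment],
    species: list[str],
    min_sites: int = 100,
) -> SpeciesMatrix:
    """Mean nucleotide diversity within (diagonal) and dxy between species."""
    k = len(species)
    acc = [[[] for _ in range(k)] for _ in range(k)]
    for aln in loci:
        result = filter_locus(aln, min_sites=min_sites)
        if not result.passes:
            continue
        work = filtered_alignment(aln, result)
        for i in range(k):
            try:
                st = diversity_stats(work, species[i], prefiltered=True)
                acc[i][i].append(st.pi)
            except ValueError:
                pass
        for i, j in itertools.combinations(range(k), 2):
            try:
                st = pairwise_fst(work, species[i], species[j], prefiltered=True)
            except ValueError:
                continue
            if np.isfinite(st.dxy):
                acc[i][j].append(st.dxy)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        if acc[i][i]:
            mat[i, i] = float(np.mean(acc[i][i]))
    for i, j in itertools.combinations(range(k), 2):
        if acc[i][j]:
            mat[i, j] = mat[j, i] = float(np.mean(acc[i][j]))
    return SpeciesMatrix(labels=list(species), matrix=mat, kind="mean_diversity")


def cluster_species(matrix: SpeciesMatrix, method: str = "average") -> SpeciesMatrix:
    """Agglomerative (UPGMA by default) clustering of the species matrix.

    The matrix is treated as a distance matrix (diagonal zeroed). Returns the
    input with the scipy linkage attached; ties resolve deterministically by
    scipy's lowest-index convention.
    """
    d = matrix.matrix.copy()
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    z = hierarchy.linkage(squareform(d, checks=True), method=method)
    out = SpeciesMatrix(matrix.labels, matrix.matrix, matrix.kind)
    out.linkage = z
    return out


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a newick dendrogram string."""
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.get_left()), walk(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl / 2:.6g},{right}:{dr / 2:.6g})"

    return walk(tree) + ";"


def stats_table(
    loci: list[LocusAlignment], species: list[str], min_sites: int = 100
) -> pd.DataFrame:
    """Per-locus, per-species statistics table over all passing loci."""
    rows = []
    for aln in loci:
        result = filter_locus(aln, min_sites=min_sites)
        if not result.passes:
            continue
        work = filtered_alignment(aln, result)
        for sp in species:
            try:
                st = diversity_stats(work, sp, prefiltered=True)
            except ValueError:
                continue
            rows.append(vars(st))
    return pd.DataFrame(rows)
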