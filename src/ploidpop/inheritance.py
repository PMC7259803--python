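"""Inheritance-mode inference for tetraploids via in-silico tetraploid models.

An allotetraploid with disomic inheritance carries two subgenomes that never
recombine their homoeologous chromosomes, so fixed inter-subgenome
differences surface as balanced AABB sites: an excess of intermediate
(40-60%) over rare (<30%) allele frequencies. An autotetraploid with
tetrasomic inheritance has one panmictic chromosome pool and no such excess.

Expectations for both origins are built from observed diploids: summing the
per-site allele counts of two conspecific diploids models an autotetraploid,
summing counts of two heterospecific diploids models an allotetraploid.
Each observed tetraploid is then placed by comparing its intermediate/rare
frequency ratio against the two model groups with Wilcoxon rank-sum tests,
Benjamini-Hochberg adjusted within the declared comparison family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BaseFrequencySet, SiteAlleleCounts
from .sitefreq import denoise_frequencies, extract_biallelic_frequencies

INTERMEDIATE_BAND = (0.40, 0.60)
RARE_MAX = 0.30


# --------------------------------------------------------------------------- #
# in-silico tetraploids
# --------------------------------------------------------------------------- #


@dataclass
class CombinedTetraploid:
    """Two diploids merged into one virtual tetraploid by count summation."""

    source_ids: tuple[str, str]
    mode: str  # within_species | between_species
    counts: SiteAlleleCounts
    n_conflicts: int = 0  # sites dropped for allele-identity disagreement


def combine_diploids(a: SiteAlleleCounts, b: SiteAlleleCounts) -> CombinedTetraploid:
    """Sum per-site allele counts of two diploids over shared coordinates.

    Sites absent from either source are dropped; when both sources carry
    allele identities, sites whose allele pairs disagree are dropped and
    tallied. The operation is symmetric in its arguments.
    """
    same_axis = len(a) == len(b) and np.array_equal(
        a.site_index, b.site_index
    ) and np.array_equal(a.locus_ids, b.locus_ids)
    if same_axis:
        ia = ib = np.arange(len(a))
        locus, site = a.locus_ids, a.site_index
    else:
        fa = pd.DataFrame({"locus": a.locus_ids, "site": a.site_index,
                           "ia": np.arange(len(a))})
        fb = pd.DataFrame({"locus": b.locus_ids, "site": b.site_index,
                           "ib": np.arange(len(b))})
        merged = fa.merge(fb, on=["locus", "site"], how="inner", sort=True)
        ia = merged["ia"].to_numpy()
        ib = merged["ib"].to_numpy()
        locus, site = merged["locus"].to_numpy(), merged["site"].to_numpy()

    ca, cb = a.count_a[ia], a.count_b[ia]
    da, db = b.count_a[ib], b.count_b[ib]
    n_conflicts = 0
    if a.allele_a is not None and b.allele_a is not None:
        a1, a2 = a.allele_a[ia], a.allele_b[ia]
        b1, b2 = b.allele_a[ib], b.allele_b[ib]
        straight = (a1 == b1) & (a2 == b2)
        swapped = (a1 == b2) & (a2 == b1) & ~straight
        conflict = ~(straight | swapped)
        n_conflicts = int(conflict.sum())
        da = np.where(swapped, b.count_b[ib], da)
        db = np.where(swapped, b.count_a[ib], db)
        keep = ~conflict
        ca, cb, da, db = ca[keep], cb[keep], da[keep], db[keep]
        locus, site = locus[keep], site[keep]
        other = a.count_other[ia][keep] + b.count_other[ib][keep]
        alle_a, alle_b = a.allele_a[ia][keep], a.allele_b[ia][keep]
    else:
        other = a.count_other[ia] + b.count_other[ib]
        alle_a = alle_b = None

    mode = (
        "within_species"
        if a.species_label == b.species_label
        else "between_species"
    )
    combined = SiteAlleleCounts(
        individual_id=f"{a.individual_id}+{b.individual_id}",
        species_label=(
            a.species_label
            if mode == "within_species"
            else f"{a.species_label}+{b.species_label}"
        ),
        locus_ids=locus,
        site_index=site,
        count_a=ca + da,
        count_b=cb + db,
        count_other=other,
        allele_a=alle_a,
        allele_b=alle_b,
    )
    return CombinedTetraploid(
        source_ids=(a.individual_id, b.individual_id),
        mode=mode,
        counts=combined,
        n_conflicts=n_conflicts,
    )


def build_expectation_sets(
    diploids: list[SiteAlleleCounts],
    species_pair: tuple[str, str] | None = None,
) -> tuple[list[CombinedTetraploid], list[CombinedTetraploid]]:
    """All within-species (auto model) and between-species (allo model) pairs.

    ``species_pair`` optionally restricts the allo set to combinations of two
    named species. Species with fewer than two diploids contribute no auto
    pairs.
    """
    by_species: dict[str, list[SiteAlleleCounts]] = {}
    for d in diploids:
        by_species.setdefault(d.species_label, []).append(d)
    if len(by_species) < 2:
        raise ValueError("expectation sets require diploids of >= 2 species")
    auto = [
        combine_diploids(a, b)
        for group in by_species.values()
        for a, b in itertools.combinations(group, 2)
    ]
    allo = []
    for spA, spB in itertools.combinations(sorted(by_species), 2):
        if species_pair is not None and {spA, spB} != set(species_pair):
            continue
        for a in by_species[spA]:
            for b in by_species[spB]:
                allo.append(combine_diploids(a, b))
    return auto, allo


# --------------------------------------------------------------------------- #
# ratio statistic
# --------------------------------------------------------------------------- #


@dataclass
class RatioStat:
    """Intermediate/rare allele-frequency ratio for one individual.

    Bands live on the unfolded representation: intermediate is the closed
    interval [0.40, 0.60] (both mirrored entries of a balanced site count),
    rare is the open interval (0, 0.30) -- the low side only, mirrors of
    rare entries fall near 1 and are not counted.
    """

    individual_id: str
    n_intermediate: int
    n_rare: int
    ratio: float  # nan when undefined
    group: str = ""

    @property
    def defined(self) -> bool:
        return self.n_rare > 0


def intermediate_rare_ratio(
    freqs: BaseFrequencySet,
    int_band: tuple[float, float] = INTERMEDIATE_BAND,
    rare_max: float = RARE_MAX,
    group: str = "",
) -> RatioStat:
    """Count band memberships and form the ratio; flagged when no rare entries."""
    f = freqs.freqs[freqs.signal_posterior >= 0.5]
    n_int = int(((f >= int_band[0]) & (f <= int_band[1])).sum())
    n_rare = int(((f > 0) & (f < rare_max)).sum())
    ratio = n_int / n_rare if n_rare else float("nan")
    return RatioStat(
        individual_id=freqs.individual_id,
        n_intermediate=n_int,
        n_rare=n_rare,
        ratio=ratio,
        group=group,
    )


def ratios_for_counts(
    counts_list,
    group: str = "",
    denoise: bool = False,
    extract_kwargs: dict | None = None,
) -> list[RatioStat]:
    """Extract frequencies (optionally denoised) and compute ratios per individual."""
    kw = extract_kwargs or {}
    out = []
    for c in counts_list:
        counts = c.counts if isinstance(c, CombinedTetraploid) else c
        freqs = extract_biallelic_frequencies(counts, **kw)
        if denoise and len(freqs) >= 100:
            freqs = denoise_frequencies(freqs)
        out.append(intermediate_rare_ratio(freqs, group=group))
    return out


# --------------------------------------------------------------------------- #
# group comparisons
# --------------------------------------------------------------------------- #


@dataclass
class GroupTest:
    """One Wilcoxon rank-sum comparison between two ratio groups."""

    name: str
    statistic: float
    p_raw: float
    p_adj: float | None
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    n_undefined: int = 0


def compare_groups(
    a: list[RatioStat], b: list[RatioStat], name: str = ""
) -> GroupTest:
    """Two-sided Wilcoxon rank-sum on the defined ratio values.

    Exact enumeration applies when both groups have <= 10 values and no ties
    occur; otherwise the normal approximation with tie and continuity
    correction is used (scipy's ``auto`` policy implements exactly this).
    Undefined ratios (no rare entries) are excluded and tallied.
    """
    xa = np.array([r.ratio for r in a if r.defined])
    xb = np.array([r.ratio for r in b if r.defined])
    n_undef = (len(a) - len(xa)) + (len(b) - len(xb))
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("a group has no defined ratios")
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need >= 3 defined ratios per group")
    res = stats.mannwhitneyu(
        xa, xb, alternative="two-sided", use_continuity=True, method="auto"
    )
    return GroupTest(
        name=name,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adj=None,
        n_a=len(xa),
        n_b=len(xb),
        median_a=float(np.median(xa)),
        median_b=float(np.median(xb)),
        n_undefined=n_undef,
    )


def adjust_family(tests: list[GroupTest]) -> list[GroupTest]:
    """Benjamini-Hochberg adjustment across the declared comparison family."""
    if not tests:
        return tests
    p = [t.p_raw for t in tests]
    adj = multipletests(p, method="fdr_bh")[1]
    for t, q in zip(tests, adj):
        t.p_adj = float(q)
    return tests


# --------------------------------------------------------------------------- #
# classification
# --------------------------------------------------------------------------- #


@dataclass
class InheritanceCall:
    """Inheritance-mode label for one tetraploid species."""

    species: str
    label: str  # tetrasomic | disomic | mixed
    p_vs_auto: float
    p_vs_allo: float
    n_individuals: dict[str, int] = field(default_factory=dict)
    tests: list[GroupTest] = field(default_factory=list)


def classify_inheritance(
    observed: list[RatioStat],
    auto_model: list[RatioStat],
    allo_model: list[RatioStat],
    alpha: float = 0.05,
    species: str = "",
) -> InheritanceCall:
    """Decision rule on the adjusted Wilcoxon p-values.

    tetrasomic: observed significantly below the allo model and not
    distinguishable from the auto model; disomic: the mirror (observed
    significantly above the auto model, not distinguishable from the allo
    model); mixed otherwise (both significant, or neither). The BH family is
    {observed-vs-auto, observed-vs-allo, auto-vs-allo}.
    """
    t_auto = compare_groups(observed, auto_model, name="observed_vs_auto")
    t_allo = compare_groups(observed, allo_model, name="observed_vs_allo")
    t_models = compare_groups(auto_model, allo_model, name="auto_vs_allo")
    adjust_family([t_auto, t_allo, t_models])

    sig_auto = t_auto.p_adj < alpha
    sig_allo = t_allo.p_adj < alpha
    obs_below_allo = t_allo.median_a < t_allo.median_b
    obs_above_auto = t_auto.median_a > t_auto.median_b

    if sig_allo and obs_below_allo and not sig_auto:
        label = "tetrasomic"
    elif sig_auto and obs_above_auto and not sig_allo:
        label = "disomic"
    else:
        label = "mixed"
    return InheritanceCall(
        species=species,
        label=label,
        p_vs_auto=t_auto.p_adj,
        p_vs_allo=t_allo.p_adj,
        n_individuals={
            "observed": len(observed),
            "model_auto": len(auto_model),
            "model_allo": len(allo_model),
        },
        tests=[t_auto, t_allo, t_models],
    )


def plot_frequency_histograms(groups: dict[str, np.ndarray], path: str) -> None:
    """Overlayed allele-frequency histograms per group (0-1 axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 1, 51)
    for name, values in groups.items():
        ax.hist(values, bins=bins, histtype="step", density=True, label=name)
    ax.set_xlabel("allele frequency at biallelic sites")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
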