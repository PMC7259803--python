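"""Biallelic base-frequency extraction, denoising, and GMM ploidy assignment.

The ploidy model follows the nQuire idea: at biallelic sites, read-level
alternate-allele frequencies of a ploidy-p individual concentrate around the
dosage fractions k/p. A free three-component Gaussian mixture is compared
with fixed-mean mixtures ({1/2} for diploids, {1/3, 2/3} for triploids,
{1/4, 1/2, 3/4} for tetraploids); the fixed model whose log-likelihood falls
least short of the free model wins. A uniform-noise component absorbs
frequencies produced by mapping artefacts before the ploidy fit (the
"denoised" input).

All mixtures are fit by EM with a shared Gaussian variance. Duplicate
frequency values are collapsed to weighted unique values first, which leaves
the likelihood identical but makes EM cost scale with the number of distinct
read-count ratios rather than the number of sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import BaseFrequencySet, SiteAlleleCounts

_SQRT2PI = math.sqrt(2.0 * math.pi)

FIXED_MEANS = {
    2: np.array([0.5]),
    3: np.array([1.0 / 3.0, 2.0 / 3.0]),
    4: np.array([0.25, 0.5, 0.75]),
}


class InsufficientSitesError(ValueError):
    """Too few usable frequency entries for a ploidy fit."""


# --------------------------------------------------------------------------- #
# extraction
# --------------------------------------------------------------------------- #


def extract_biallelic_frequencies(
    counts: SiteAlleleCounts,
    min_depth: int = 10,
    min_minor_count: int = 3,
    max_other_frac: float = 0.05,
) -> BaseFrequencySet:
    """Site filters and mirrored frequency extraction.

    A site is kept when total depth >= ``min_depth``, both alleles carry at
    least ``min_minor_count`` reads (which excludes invariant sites), and
    third-allele reads make up at most ``max_other_frac`` of the depth.
    Frequencies are computed on the two-allele depth and recorded unfolded
    (both ``f`` and ``1 - f``).
    """
    depth = counts.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        other_frac = np.where(depth > 0, counts.count_other / depth, 0.0)
    keep = (
        (depth >= min_depth)
        & (counts.count_a >= min_minor_count)
        & (counts.count_b >= min_minor_count)
        & (other_frac <= max_other_frac)
    )
    biallelic_depth = counts.count_a[keep] + counts.count_b[keep]
    f = counts.count_b[keep] / biallelic_depth
    out = BaseFrequencySet.from_site_frequencies(
        counts.individual_id, f, biallelic_depth
    )
    if len(out) == 0:
        out.warning = "no sites passed the biallelic filters"
    return out


# --------------------------------------------------------------------------- #
# EM core
# --------------------------------------------------------------------------- #


@dataclass
class MixtureFit:
    """A fitted mixture of (optionally) a Uniform(0,1) plus Gaussians."""

    weights: np.ndarray  # uniform weight first when has_uniform
    means: np.ndarray
    sigma: float
    log_likelihood: float
    has_uniform: bool
    n_iter: int
    converged: bool
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _component_densities(
    x: np.ndarray, means: np.ndarray, sigma: float, has_uniform: bool
) -> np.ndarray:
    """(n, K[+1]) matrix of component densities at x."""
    z = (x[:, None] - means[None, :]) / sigma
    gauss = np.exp(-0.5 * z * z) / (sigma * _SQRT2PI)
    if has_uniform:
        return np.column_stack([np.ones_like(x), gauss])
    return gauss


def _em_mixture(
    x: np.ndarray,
    counts: np.ndarray,
    means: np.ndarray,
    free_means: bool,
    has_uniform: bool,
    weights: np.ndarray | None = None,
    sigma: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-6,
    var_floor: float = 1e-4,
) -> MixtureFit:
    """Weighted EM; monotone log-likelihood is enforced as an internal check."""
    means = np.array(means, dtype=float)
    n_comp = len(means) + (1 if has_uniform else 0)
    w = (
        np.full(n_comp, 1.0 / n_comp)
        if weights is None
        else np.array(weights, dtype=float)
    )
    total = counts.sum()
    ll_prev = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = _component_densities(x, means, sigma, has_uniform)
        mix = dens * w[None, :]
        row = mix.sum(axis=1)
        row = np.maximum(row, 1e-300)
        ll = float((counts * np.log(row)).sum())
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise RuntimeError("EM log-likelihood decreased")
        trace.append(ll)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        resp = mix / row[:, None]
        wr = resp * counts[:, None]
        comp_mass = wr.sum(axis=0)
        w = comp_mass / total
        g0 = 1 if has_uniform else 0
        gauss_resp = wr[:, g0:]
        gauss_mass = np.maximum(comp_mass[g0:], 1e-12)
        if free_means:
            means = (gauss_resp * x[:, None]).sum(axis=0) / gauss_mass
        sq = (x[:, None] - means[None, :]) ** 2
        var = (gauss_resp * sq).sum() / max(gauss_mass.sum(), 1e-12)
        sigma = math.sqrt(max(var, var_floor))
    return MixtureFit(
        weights=w,
        means=means,
        sigma=sigma,
        log_likelihood=trace[-1] if trace else -np.inf,
        has_uniform=has_uniform,
        n_iter=it,
        converged=converged,
        ll_trace=np.asarray(trace),
    )


def _unique_weighted(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, counts = np.unique(np.round(x, 10), return_counts=True)
    return vals, counts.astype(float)


def _kmeanspp_means(
    x: np.ndarray, counts: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++-style seeding of Gaussian means on weighted values."""
    p = counts / counts.sum()
    means = [x[rng.choice(len(x), p=p)]]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
        probs = d2 * counts
        s = probs.sum()
        if s <= 0:
            means.append(x[rng.choice(len(x), p=p)])
        else:
            means.append(x[rng.choice(len(x), p=probs / s)])
    return np.sort(np.array(means))


def _posterior_signal(
    x: np.ndarray, fit: MixtureFit
) -> np.ndarray:
    dens = _component_densities(x, fit.means, fit.sigma, fit.has_uniform)
    mix = dens * fit.weights[None, :]
    total = np.maximum(mix.sum(axis=1), 1e-300)
    if fit.has_uniform:
        return 1.0 - mix[:, 0] / total
    return np.ones_like(x)


# --------------------------------------------------------------------------- #
# denoising
# --------------------------------------------------------------------------- #


def denoise_frequencies(
    freqs: BaseFrequencySet,
    max_iter: int = 500,
    tol: float = 1e-6,
    posterior_threshold: float = 0.5,
    seed: int = 0,
) -> BaseFrequencySet:
    """Fit Uniform(0,1) noise + three free Gaussians; keep signal entries.

    The posterior probability of non-noise membership is averaged over each
    mirrored (f, 1-f) pair so that the retained set stays symmetric; entries
    with posterior >= ``posterior_threshold`` constitute the denoised set.
    """
    if len(freqs) < 100:
        raise InsufficientSitesError(
            "denoising requires at least 100 frequency entries"
        )
    x, counts = _unique_weighted(freqs.freqs)
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    inits = [np.array([0.25, 0.5, 0.75])] + [
        _kmeanspp_means(x, counts, 3, rng) for _ in range(4)
    ]
    for means0 in inits:
        fit = _em_mixture(
            x, counts, means0, free_means=True, has_uniform=True,
            max_iter=max_iter, tol=tol,
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    post = _posterior_signal(freqs.freqs, best)
    m = len(freqs) // 2
    pair_post = 0.5 * (post[:m] + post[m:])
    post = np.concatenate([pair_post, pair_post])
    out = BaseFrequencySet(
        individual_id=freqs.individual_id,
        freqs=freqs.freqs,
        depths=freqs.depths,
        signal_posterior=post,
    )
    keep = post >= posterior_threshold
    # drop/keep whole mirrored pairs so symmetry is preserved exactly
    out = out.subset(keep)
    if not best.converged:
        out.warning = "denoising EM did not converge; best-so-far fit used"
    if len(out) == 0:
        out.warning = "denoising removed every entry"
    out.noise_weight = float(best.weights[0])  # type: ignore[attr-defined]
    out.denoise_fit = best  # type: ignore[attr-defined]
    return out


# --------------------------------------------------------------------------- #
# ploidy fit
# --------------------------------------------------------------------------- #


@dataclass
class PloidyFit:
    """Free-vs-fixed mixture likelihood comparison for one individual."""

    individual_id: str
    ll_free: float
    ll_fixed: dict[int, float]
    delta: dict[int, float]
    best_ploidy: int
    n_sites_used: int
    free_fit: MixtureFit | None = None
    fixed_fits: dict[int, MixtureFit] = field(default_factory=dict)


def fit_ploidy(
    freqs: BaseFrequencySet,
    min_sites: int = 200,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> PloidyFit:
    """Assign ploidy by the free-vs-fixed Gaussian-mixture likelihood gap.

    For each candidate ploidy the mixture means are clamped to the dosage
    fractions while weights and the shared variance stay free; the free
    model has three unconstrained means. ``delta[p] = ll_free - ll_fixed[p]``
    is non-negative up to EM tolerance (each fixed model is nested in the
    free one); the assigned ploidy minimizes delta, ties broken toward the
    lower ploidy.
    """
    usable = freqs.signal_posterior >= 0.5
    entries = freqs.freqs[usable]
    if len(entries) < min_sites:
        raise InsufficientSitesError(
            f"{len(entries)} usable entries < required {min_sites}"
        )
    x, counts = _unique_weighted(entries)
    rng = np.random.default_rng(seed)

    fixed_fits: dict[int, MixtureFit] = {}
    for p, means in FIXED_MEANS.items():
        fixed_fits[p] = _em_mixture(
            x, counts, means, free_means=False, has_uniform=False,
            max_iter=max_iter, tol=tol,
        )

    # free model: k-means++ restarts plus warm starts at each fixed optimum,
    # which guarantees ll_free >= ll_fixed[p] up to EM tolerance
    best: MixtureFit | None = None
    starts: list[tuple[np.ndarray, np.ndarray | None, float]] = [
        (np.array([0.25, 0.5, 0.75]), None, 0.05)
    ]
    for p, ffit in fixed_fits.items():
        means = np.full(3, 0.5) if p == 2 else (
            np.array([ffit.means[0], 0.5, ffit.means[1]]) if p == 3 else ffit.means
        )
        w = _expand_weights(ffit, p)
        starts.append((means, w, ffit.sigma))
    for _ in range(max(0, n_restarts - len(starts))):
        starts.append((_kmeanspp_means(x, counts, 3, rng), None, 0.05))
    for means0, w0, s0 in starts:
        fit = _em_mixture(
            x, counts, means0, free_means=True, has_uniform=False,
            weights=w0, sigma=s0, max_iter=max_iter, tol=tol,
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit

    ll_fixed = {p: f.log_likelihood for p, f in fixed_fits.items()}
    ll_free = max(best.log_likelihood, max(ll_fixed.values()))
    delta = {p: ll_free - ll for p, ll in ll_fixed.items()}
    # The diploid fixed model is nested in the tetraploid one (weights are
    # free), so a naive argmin of delta is ill-posed: delta[4] <= delta[2]
    # for any diploid at the optimum. Break the near-ties toward the more
    # parsimonious model with a BIC parameter-count penalty ((p-1) component
    # weights plus the shared variance per model).
    n_entries = len(entries)
    bic = {p: 2.0 * delta[p] + (p - 1) * math.log(n_entries) for p in delta}
    best_p = min(sorted(bic), key=lambda p: (bic[p], p))
    return PloidyFit(
        individual_id=freqs.individual_id,
        ll_free=ll_free,
        ll_fixed=ll_fixed,
        delta=delta,
        best_ploidy=best_p,
        n_sites_used=len(entries) // 2,
        free_fit=best,
        fixed_fits=fixed_fits,
    )


def _expand_weights(fit: MixtureFit, p: int) -> np.ndarray:
    """Map a fixed model's weights onto the 3-component free model."""
    if p == 2:
        return np.array([1 / 3, 1 / 3, 1 / 3])
    if p == 3:
        w = fit.weights
        return np.array([w[0], 1e-6, w[1]]) / (w.sum() + 1e-6)
    return fit.weights.copy()


# --------------------------------------------------------------------------- #
# sample QC
# --------------------------------------------------------------------------- #


@dataclass
class SampleQCReport:
    """Missing-data and ploidy-concordance filters for one individual."""

    individual_id: str
    informative_fraction: float
    expected_ploidy: int
    estimated_ploidy: int | None
    status: str  # pass | fail_missing_data | fail_ploidy_mismatch


def qc_sample(
    informative_fraction: float,
    expected_ploidy: int,
    fit: PloidyFit | None,
    threshold: float = 0.2,
    individual_id: str = "",
) -> SampleQCReport:
    """Apply the two sample filters in order.

    The missing-data filter fails when the informative (non-gap) fraction is
    below ``threshold`` (>= threshold passes: the bound is inclusive); the
    ploidy filter fails when the estimated ploidy does not match the
    expectation for the species.
    """
    estimated = fit.best_ploidy if fit is not None else None
    if informative_fraction < threshold:
        status = "fail_missing_data"
    elif estimated is not None and estimated != expected_ploidy:
        status = "fail_ploidy_mismatch"
    else:
        status = "pass"
    return SampleQCReport(
        individual_id=individual_id or (fit.individual_id if fit else ""),
        informative_fraction=informative_fraction,
        expected_ploidy=expected_ploidy,
        estimated_ploidy=estimated,
        status=status,
    )


def informative_fraction(loci, individual_id: str) -> float:
    """Non-gap fraction of an individual's concatenated alignment rows.

    Loci where the individual is absent contribute all-gap rows of the locus
    length; gaps are ``-`` and ``N``.
    """
    total = 0
    informative = 0
    for aln in loci:
        rows = [i for i, ind in enumerate(aln.individual_ids) if ind == individual_id]
        if rows:
            sub = aln.matrix[rows]
            total += sub.size
            informative += int(((sub != b"-") & (sub != b"N")).sum())
        else:
            total += aln.length
    if total == 0:
        raise ValueError("no alignment columns found")
    return informative / total
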