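"""Post-SDM analytics: suitable-area change and its demographic correlate.

Consumes presence-probability rasters (cloglog-scale, 0-1) for a current and
a past (last-glacial-maximum) climate slice, extracts suitable area with an
inclusive 0.8 probability threshold, forms the relative change
(current - past) / current, and correlates it with per-species median
Tajima's D. Also provides the greedy pruning of highly correlated
bioclimatic variables (|r| > 0.85) used upstream of distribution modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SuitabilityRaster

DEFAULT_THRESHOLD = 0.8
DEFAULT_R_MAX = 0.85


# --------------------------------------------------------------------------- #
# correlated-variable pruning
# --------------------------------------------------------------------------- #


def prune_correlated_variables(
    table: pd.DataFrame, r_max: float = DEFAULT_R_MAX
) -> list[str]:
    """Greedy removal of highly correlated variables.

    Constant (zero-variance) columns are dropped first with a warning. Then,
    while any pair exceeds ``r_max`` in |Pearson r|, the member of the worst
    pair with the higher mean absolute correlation to the remaining
    variables is dropped; ties break toward keeping the earlier column.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 variables over >= 3 locations")
    kept = list(table.columns)
    constant = [c for c in kept if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant variables: {constant}", stacklevel=2)
        kept = [c for c in kept if c not in constant]
    while len(kept) > 1:
        corr = table[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_max:
            break
        mean_i = corr[i].sum() / (len(kept) - 1)
        mean_j = corr[j].sum() / (len(kept) - 1)
        # drop the more promiscuous member; on exact ties the later column goes
        drop = kept[j] if mean_j >= mean_i else kept[i]
        kept.remove(drop)
    return kept


# --------------------------------------------------------------------------- #
# suitable area and change
# --------------------------------------------------------------------------- #


def suitable_area(
    raster: SuitabilityRaster,
    threshold: float = DEFAULT_THRESHOLD,
    cell_areas: np.ndarray | None = None,
) -> float:
    """Suitable area at an inclusive probability threshold.

    Counts non-nodata cells with probability >= ``threshold``; with
    ``cell_areas`` supplied (same shape) the count becomes an area sum.
    """
    valid = ~raster.nodata_mask
    if not valid.any():
        raise ValueError("raster has no valid cells")
    suitable = valid & (raster.data >= threshold)
    if cell_areas is None:
        return float(suitable.sum())
    cell_areas = np.asarray(cell_areas, dtype=float)
    if cell_areas.shape != raster.shape:
        raise ValueError("cell-area grid shape mismatch")
    return float(cell_areas[suitable].sum())


def latitude_cell_areas(raster: SuitabilityRaster) -> np.ndarray:
    """Approximate km^2 per cell on a geographic grid (cos-latitude weighting)."""
    nrow, ncol = raster.shape
    km_per_deg = 111.32
    lat_top = raster.yllcorner + nrow * raster.cellsize
    lats = lat_top - (np.arange(nrow) + 0.5) * raster.cellsize
    h = raster.cellsize * km_per_deg
    w = raster.cellsize * km_per_deg * np.cos(np.radians(lats))
    return np.repeat((h * w)[:, None], ncol, axis=1)


@dataclass
class AreaChange:
    """Relative suitable-area change for one species.

    ``rel_change = (current - past) / current``: positive means shrinkage
    since the past slice, negative means expansion. Undefined when the
    current area is zero.
    """

    species: str
    area_current: float
    area_past: float
    rel_change: float  # nan when undefined

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rel_change)


def relative_area_change(
    current: float, past: float, species: str = ""
) -> AreaChange:
    rel = (current - past) / current if current > 0 else float("nan")
    return AreaChange(
        species=species,
        area_current=float(current),
        area_past=float(past),
        rel_change=rel,
    )


def area_change_from_rasters(
    current: SuitabilityRaster,
    past: SuitabilityRaster,
    threshold: float = DEFAULT_THRESHOLD,
    species: str = "",
    weighted: bool = False,
) -> AreaChange:
    """Threshold both rasters and form the relative change statistic."""
    cw = latitude_cell_areas(current) if weighted else None
    pw = latitude_cell_areas(past) if weighted else None
    return relative_area_change(
        suitable_area(current, threshold, cw),
        suitable_area(past, threshold, pw),
        species=species,
    )


# --------------------------------------------------------------------------- #
# correlation with demography
# --------------------------------------------------------------------------- #


@dataclass
class DemographyCorrelation:
    """Pearson correlation between area change and median Tajima's D."""

    n: int
    pearson_r: float
    r_squared: float
    p_value: float
    group: str = ""


def correlate_demography(
    changes: list[AreaChange],
    tajimas_d: dict[str, float],
    group_filter: list[str] | None = None,
    group_label: str = "",
) -> DemographyCorrelation:
    """Pearson r of (relative area change, median Tajima's D) across species.

    The two-sided p-value comes from t = r sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom. Species lacking either value, or outside
    ``group_filter``, are excluded; zero variance in either vector makes the
    correlation undefined.
    """
    pairs = []
    for ch in changes:
        if group_filter is not None and ch.species not in group_filter:
            continue
        if not ch.defined or ch.species not in tajimas_d:
            continue
        pairs.append((ch.rel_change, tajimas_d[ch.species]))
    if len(pairs) < 3:
        raise ValueError("need >= 3 species with defined values")
    x, y = map(np.array, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return DemographyCorrelation(
        n=len(pairs),
        pearson_r=float(r),
        r_squared=float(r * r),
        p_value=float(p),
        group=group_label,
    )
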