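"""Binarization, richness stacking, natural-breaks hotspots, density maps.

Per-species logistic maps are binarized (top natural-breaks class, or a
fixed threshold), overlaid into an integer richness surface, and the
richness surface is reclassified with 3-class natural breaks into
non-suitable / low-suitability / high-suitability; high-suitability cells
are the "suitable habitat" of each group. The Fisher-Jenks optimal
partition is implemented here (exact weighted dynamic program over distinct
values, with optional binning for very large continuous rasters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterLayer

__all__ = [
    "GroupSuitability",
    "jenks_breaks",
    "jenks_classify",
    "binarize_species",
    "stack_richness",
    "classify_hotspots",
    "neighborhood_density",
    "unique_group_cells",
    "build_group_suitability",
]


def jenks_breaks(values, k: int, max_bins: int | None = None) -> np.ndarray:
    """Fisher-Jenks optimal 1-D classification into ``k`` classes.

    Returns the ``k - 1`` break values (upper bounds of the lower classes),
    minimizing total within-class sum of squared deviations. Exact over the
    distinct input values; if ``max_bins`` is given and there are more
    distinct values, values are first binned to that many quantile levels.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to classify")
    uniq, counts = np.unique(v, return_counts=True)
    if uniq.size < k:
        raise ValueError(f"need at least {k} distinct values, have {uniq.size}")
    if max_bins is not None and uniq.size > max_bins:
        qs = np.quantile(v, np.linspace(0, 1, max_bins + 1))
        mids = 0.5 * (qs[:-1] + qs[1:])
        idx = np.clip(np.searchsorted(qs, v, side="right") - 1, 0, max_bins - 1)
        uniq2, counts = np.unique(idx, return_counts=True)
        uniq = mids[uniq2]
    if k == 1:
        return np.array([])

    u = uniq.size
    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * uniq)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * uniq**2)])

    def seg_cost(i, j):
        # SSD of segment covering unique values i..j inclusive (vectorized in i)
        W = cw[j + 1] - cw[i]
        S = cwx[j + 1] - cwx[i]
        S2 = cwx2[j + 1] - cwx2[i]
        return S2 - S * S / W

    # dp[c, j]: min cost of splitting values[0..j] into c+1 classes
    dp = np.empty((k, u))
    back = np.zeros((k, u), dtype=int)
    idx_all = np.arange(u)
    dp[0] = seg_cost(np.zeros(u, dtype=int), idx_all)
    for c in range(1, k):
        for j in range(c, u):
            i = np.arange(c, j + 1)  # first index of the last class
            cand = dp[c - 1, i - 1] + seg_cost(i, j)
            best = int(np.argmin(cand))
            dp[c, j] = cand[best]
            back[c, j] = i[best]
    # recover class boundaries
    breaks = []
    j = u - 1
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        breaks.append(uniq[i - 1])  # upper bound of the class below
        j = i - 1
    return np.array(breaks[::-1])


def jenks_classify(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Class codes 0..k-1; a value equal to a break joins the lower class."""
    out = np.searchsorted(np.asarray(breaks, float), values, side="left").astype(float)
    out[~np.isfinite(values)] = np.nan
    return out


def binarize_species(
    logistic_map: RasterLayer,
    method: str = "jenks3_top",
    threshold: float | None = None,
    sample_cap: int = 100_000,
    seed: int = 0,
) -> RasterLayer:
    """Binary habitat map from a logistic suitability map.

    ``jenks3_top``: 3-class natural breaks on finite values, top class -> 1
    (breaks computed on a seeded uniform sample of at most ``sample_cap``
    cells for very large maps). ``fixed_threshold``: value >= threshold -> 1.
    Nodata cells stay nodata in the output.
    """
    vals = logistic_map.values
    finite = np.isfinite(vals)
    if method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold requires a threshold")
        binary = (vals >= threshold).astype(float)
    elif method == "jenks3_top":
        fv = vals[finite]
        if np.unique(fv).size < 3:
            raise ValueError("jenks3_top needs at least 3 distinct suitability values")
        if fv.size > sample_cap:
            rng = np.random.default_rng(seed)
            fv = fv[rng.choice(fv.size, sample_cap, replace=False)]
        breaks = jenks_breaks(fv, 3, max_bins=1024)
        binary = (vals > breaks[-1]).astype(float)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    binary[~finite] = np.nan
    return RasterLayer(logistic_map.grid, f"{logistic_map.name}_bin", binary, "categorical")


def stack_richness(binary_maps: list[RasterLayer]) -> RasterLayer:
    """Cellwise count of species for which the cell is suitable."""
    if not binary_maps:
        raise ValueError("no binary maps to stack")
    grid = binary_maps[0].grid
    total = np.zeros(grid.shape)
    any_finite = np.zeros(grid.shape, dtype=bool)
    for m in binary_maps:
        if not m.grid.same_geometry(grid):
            raise ValueError(f"map {m.name!r} is on a different grid")
        fin = np.isfinite(m.values)
        total[fin] += m.values[fin]
        any_finite |= fin
    total[~any_finite] = np.nan
    return RasterLayer(grid, "richness", total)


def classify_hotspots(richness: RasterLayer, sample_cap: int = 100_000, seed: int = 0) -> RasterLayer:
    """3-class natural breaks on richness: 0 non-suitable, 1 low, 2 high."""
    vals = richness.values
    finite = np.isfinite(vals)
    distinct = np.unique(vals[finite])
    if distinct.size >= 3:
        fv = vals[finite]
        if fv.size > sample_cap:
            rng = np.random.default_rng(seed)
            fv = fv[rng.choice(fv.size, sample_cap, replace=False)]
        breaks = jenks_breaks(fv, 3, max_bins=1024)
        out = jenks_classify(vals, breaks)
    elif distinct.size == 2:
        warnings.warn("richness has only 2 distinct values; degenerate 2-class hotspots")
        out = np.where(vals > distinct[0], 2.0, 0.0)
        out[~finite] = np.nan
    else:
        warnings.warn("richness is constant; all cells coded non-suitable")
        out = np.zeros_like(vals)
        out[~finite] = np.nan
    return RasterLayer(richness.grid, "hotspot3", out, "categorical")


def _odd_window_cells(window_edge: float, cellsize: float) -> int:
    ratio = window_edge / cellsize
    n = int(2 * round((ratio - 1) / 2) + 1)
    return max(1, n)


def neighborhood_density(binary: RasterLayer, window_edge: float = 1000.0) -> RasterLayer:
    """Mean of a binary raster over a square moving window (shrinking at
    edges to in-bounds, finite cells)."""
    if window_edge < binary.grid.cellsize:
        raise ValueError("window_edge must be at least one cell")
    n = _odd_window_cells(window_edge, binary.grid.cellsize)
    vals = np.where(np.isfinite(binary.values), binary.values, 0.0)
    fin = np.isfinite(binary.values).astype(float)
    sums = ndimage.uniform_filter(vals, size=n, mode="constant", cval=0.0) * n * n
    counts = ndimage.uniform_filter(fin, size=n, mode="constant", cval=0.0) * n * n
    counts = np.round(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = sums / counts
    dens[counts == 0] = np.nan
    return RasterLayer(binary.grid, f"{binary.name}_density", dens)


def unique_group_cells(
    suitable_masks: dict[str, RasterLayer],
) -> tuple[RasterLayer, dict[int, str]]:
    """Label cells suitable for exactly one group with that group's code.

    Codes are 1-based in the masks' insertion order; multi-group and
    no-group cells are 0.
    """
    names = list(suitable_masks)
    grid = suitable_masks[names[0]].grid
    count = np.zeros(grid.shape)
    label = np.zeros(grid.shape)
    for code, name in enumerate(names, start=1):
        m = suitable_masks[name]
        if not m.grid.same_geometry(grid):
            raise ValueError(f"mask {name!r} is on a different grid")
        on = np.isfinite(m.values) & (m.values > 0)
        count += on
        label[on] = code
    label[count != 1] = 0.0
    return RasterLayer(grid, "unique_group", label, "categorical"), dict(
        enumerate(names, start=1)
    )


@dataclass
class GroupSuitability:
    """All stacked products for one ecological group."""

    group: str
    species_binary: dict[str, RasterLayer]
    richness: RasterLayer
    hotspot3: RasterLayer
    suitable_mask: RasterLayer
    density: RasterLayer


def build_group_suitability(
    group: str,
    species_maps: dict[str, RasterLayer],
    binarize_method: str = "jenks3_top",
    thresholds: dict[str, float] | None = None,
    density_window: float = 1000.0,
    seed: int = 0,
) -> GroupSuitability:
    """Binarize each species map, stack, classify, and derive the group's
    suitable-habitat mask and density surface."""
    binaries = {}
    for sp, mp in species_maps.items():
        if binarize_method == "fixed_threshold":
            thr = (thresholds or {}).get(sp)
            binaries[sp] = binarize_species(mp, "fixed_threshold", thr)
        else:
            binaries[sp] = binarize_species(mp, binarize_method, seed=seed)
    richness = stack_richness(list(binaries.values()))
    hotspot3 = classify_hotspots(richness, seed=seed)
    suit = (hotspot3.values == 2).astype(float)
    suit[~np.isfinite(hotspot3.values)] = np.nan
    suitable = RasterLayer(richness.grid, f"{group}_suitable", suit, "categorical")
    density = neighborhood_density(suitable, density_window)
    return GroupSuitability(group, binaries, richness, hotspot3, suitable, density)
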