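"""Moving-window Shannon landscape metrics and disturbance exposure.

SHDI per window is ``-sum p_i ln p_i`` over the class shares among finite
cells; SHEI divides by ``ln m`` where ``m`` is the number of classes present
in the window (default) or in the whole map (the FRAGSTATS convention) —
both bases are offered, single-class windows score 0 on both indices.
Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterLayer
from .stacking import _odd_window_cells

__all__ = ["WindowMetrics", "shannon_window", "exposure_summary"]

_QUANTS = (0.1, 0.25, 0.5, 0.75, 0.9)


@dataclass
class WindowMetrics:
    shdi: RasterLayer
    shei: RasterLayer
    window_edge: float
    window_cells: int
    shei_basis: str


def shannon_window(
    landcover: RasterLayer,
    window_edge: float = 900.0,
    shei_basis: str = "window",
) -> WindowMetrics:
    """Windowed Shannon diversity and evenness of a categorical raster.

    Edge windows shrink to the in-bounds cells; all-nodata windows are
    missing in both outputs.
    """
    if landcover.kind != "categorical":
        raise ValueError("shannon_window expects a categorical layer")
    if shei_basis not in ("window", "map"):
        raise ValueError("shei_basis must be 'window' or 'map'")
    n = _odd_window_cells(window_edge, landcover.grid.cellsize)
    vals = landcover.values
    finite = np.isfinite(vals)
    classes = np.unique(vals[finite])
    shape = vals.shape

    total = ndimage.uniform_filter(finite.astype(float), size=n, mode="constant", cval=0.0)
    total = np.round(total * n * n)
    shdi = np.zeros(shape)
    present = np.zeros(shape)
    for cls in classes:
        ind = (vals == cls).astype(float)
        cnt = np.round(ndimage.uniform_filter(ind, size=n, mode="constant", cval=0.0) * n * n)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = cnt / total
            term = np.where(p > 0, -p * np.log(p), 0.0)
        shdi += np.where(total > 0, term, 0.0)
        present += (cnt > 0).astype(float)

    if shei_basis == "window":
        denom = np.log(np.maximum(present, 1.0))
    else:
        denom = np.full(shape, np.log(max(classes.size, 1)))
    shei = np.where(denom > 0, shdi / np.where(denom > 0, denom, 1.0), 0.0)
    empty = total == 0
    shdi[empty] = np.nan
    shei[empty] = np.nan
    grid = landcover.grid
    return WindowMetrics(
        RasterLayer(grid, "shdi", shdi),
        RasterLayer(grid, "shei", shei),
        window_edge,
        n,
        shei_basis,
    )


def exposure_summary(
    disturbance: RasterLayer,
    suitable_masks: dict[str, RasterLayer],
) -> pd.DataFrame:
    """Quantile summary of a disturbance raster over each group's suitable
    cells (tidy table: one row per group)."""
    rows = []
    for group, mask in suitable_masks.items():
        if not mask.grid.same_geometry(disturbance.grid):
            raise ValueError(f"mask {group!r} is on a different grid")
        sel = np.isfinite(mask.values) & (mask.values > 0) & np.isfinite(disturbance.values)
        vals = disturbance.values[sel]
        row = dict(group=group, indicator=disturbance.name, n=int(vals.size),
                   is_empty=vals.size == 0)
        for q in _QUANTS:
            row[f"q{int(q * 100):02d}"] = float(np.quantile(vals, q)) if vals.size else np.nan
        row["median"] = row["q50"]
        rows.append(row)
    return pd.DataFrame(rows)
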