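"""Terrain derivatives and per-group terrain/vegetation profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterLayer

__all__ = ["slope_aspect", "terrain_profiles"]

# Horn 3x3 kernels (x eastward with columns, y northward against rows)
_KX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / 8.0
_KY = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]]) / 8.0


def slope_aspect(dem: RasterLayer) -> tuple[RasterLayer, RasterLayer]:
    """Slope and aspect from a DEM by Horn's 3x3 finite differences.

    Slope is in degrees. Aspect is the compass bearing (0 = north, clockwise)
    of the upslope gradient; flat cells (zero gradient) have undefined aspect
    and are reported as nodata. Edge cells use edge-replicated padding.
    """
    if dem.grid.nrows < 3 or dem.grid.ncols < 3:
        raise ValueError("DEM must be at least 3x3 for slope/aspect")
    z = dem.values
    cs = dem.grid.cellsize
    dzdx = ndimage.convolve(z, _KX[::-1, ::-1], mode="nearest") / cs
    dzdy = ndimage.convolve(z, _KY[::-1, ::-1], mode="nearest") / cs
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0
    aspect[grad == 0] = np.nan
    bad = ~np.isfinite(z)
    slope[bad] = np.nan
    aspect[bad] = np.nan
    return (
        RasterLayer(dem.grid, "slo", slope),
        RasterLayer(dem.grid, "asp", aspect),
    )


def terrain_profiles(
    suitable_masks: dict[str, RasterLayer],
    layers: dict[str, RasterLayer] | list[RasterLayer],
) -> pd.DataFrame:
    """Boxplot-style summary of terrain/vegetation layers over suitable cells.

    For each (group, variable): median, q1, q3 (linear-interpolation
    quantiles), and whiskers at 1.5 x IQR capped at the data range. Groups
    with an empty mask get a row flagged ``empty``.
    """
    if not isinstance(layers, dict):
        layers = {lyr.name: lyr for lyr in layers}
    rows = []
    for group, mask in suitable_masks.items():
        sel = np.isfinite(mask.values) & (mask.values > 0)
        for var, lyr in layers.items():
            vals = lyr.values[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                rows.append(
                    dict(group=group, variable=var, n=0, median=np.nan, q1=np.nan,
                         q3=np.nan, whisker_low=np.nan, whisker_high=np.nan, is_empty=True)
                )
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = max(vals.min(), q1 - 1.5 * iqr)
            hi = min(vals.max(), q3 + 1.5 * iqr)
            rows.append(
                dict(group=group, variable=var, n=int(vals.size), median=med, q1=q1,
                     q3=q3, whisker_low=lo, whisker_high=hi, is_empty=False)
            )
    return pd.DataFrame(rows)
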