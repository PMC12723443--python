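"""Protected-area gap analysis within biogeographic regions.

For each region the suitable-habitat area, reserve area and their overlap
are tallied (cell counts times cell area), along with two coverage
percentages: ``coverage_pct_reserve`` = 100 * overlap / reserve (the ratio
the reference regional tables print) and ``coverage_pct_suitable`` =
100 * overlap / suitable (the share of habitat that is protected). A zero
denominator yields a missing ratio, never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import RasterLayer

__all__ = ["regional_overlay", "coverage_ratio", "AREA_UNIT_KM2E4"]

AREA_UNIT_KM2E4 = 1e10  # m^2 per 10^4 km^2, the reporting unit


def coverage_ratio(overlap_area: float, denominator_area: float) -> float:
    """100 * overlap / denominator; NaN when the denominator is zero."""
    if overlap_area < 0 or denominator_area < 0:
        raise ValueError("areas must be nonnegative")
    if denominator_area == 0:
        return float("nan")
    return 100.0 * overlap_area / denominator_area


def regional_overlay(
    suitable_mask: RasterLayer,
    reserve_mask: RasterLayer,
    regions: RasterLayer,
    area_unit: float = AREA_UNIT_KM2E4,
) -> pd.DataFrame:
    """Per-region suitable / reserve / overlap areas and coverage ratios.

    Areas are reported in multiples of ``area_unit`` (default 10^4 km^2)
    with raw cell counts alongside.
    """
    grid = suitable_mask.grid
    for lyr, nm in ((reserve_mask, "reserves"), (regions, "regions")):
        if not lyr.grid.same_geometry(grid):
            raise ValueError(f"{nm} raster is on a different grid")
    suit = np.isfinite(suitable_mask.values) & (suitable_mask.values > 0)
    res = np.isfinite(reserve_mask.values) & (reserve_mask.values > 0)
    reg = regions.values
    labels = np.unique(reg[np.isfinite(reg)]).astype(int)
    cell_area = grid.cell_area
    rows = []
    for lab in labels:
        in_reg = reg == lab
        s = int(np.count_nonzero(suit & in_reg))
        r = int(np.count_nonzero(res & in_reg))
        o = int(np.count_nonzero(suit & res & in_reg))
        s_a, r_a, o_a = (c * cell_area / area_unit for c in (s, r, o))
        rows.append(
            dict(
                region=lab,
                suitable_cells=s,
                reserve_cells=r,
                overlap_cells=o,
                suitable_area=s_a,
                reserve_area=r_a,
                overlap_area=o_a,
                coverage_pct_reserve=coverage_ratio(o_a, r_a),
                coverage_pct_suitable=coverage_ratio(o_a, s_a),
            )
        )
    return pd.DataFrame(rows)
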