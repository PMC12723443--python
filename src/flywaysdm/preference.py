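"""Use-availability land-use preference (the Relative Preference index).

For group *i* and land-cover class *l*::

    RF[i, l] = (U[i, l] / S[i, l]) * 1e4

where ``U`` is the area of distinct suitable cells occupied by at least one
of the group's occurrence records within class *l*, and ``S`` is the area of
predicted suitable habitat within the same class. The 1e4 scaling only aids
readability; classes with no suitable habitat get a missing (NaN) RF, never
zero. Occupancy counts distinct cells, so duplicated records cannot inflate
the index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import OccurrenceSet, RasterLayer

__all__ = ["rf_index", "RF_SCALE", "DEFAULT_LANDCOVER_CLASSES"]

RF_SCALE = 1e4

# the six land-cover classes summarized in preference reports
DEFAULT_LANDCOVER_CLASSES = {
    1: "cropland",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "barren",
    6: "impervious",
}


def rf_index(
    occ: OccurrenceSet,
    suitable_mask: RasterLayer,
    landcover: RasterLayer,
    group: str,
    class_names: dict[int, str] | None = None,
    restrict_to_suitable: bool = True,
) -> pd.DataFrame:
    """RF rows for one group over every land-cover class.

    ``restrict_to_suitable`` (default, matching the use-availability design
    evaluated inside predicted suitable areas) counts only occupied cells
    that are also suitable; disabling it counts any occupied cell in the
    class.
    """
    if landcover.kind != "categorical":
        raise ValueError("landcover must be a categorical layer")
    grid = suitable_mask.grid
    if not landcover.grid.same_geometry(grid):
        raise ValueError("landcover and suitable mask are on different grids")
    names = class_names or DEFAULT_LANDCOVER_CLASSES
    occ_g = occ.for_group(group) if "group" in occ.df and group in set(occ.df["group"]) else occ
    rows, cols = occ_g.unique_cells(grid)
    occupied = np.zeros(grid.shape, dtype=bool)
    occupied[rows, cols] = True
    suitable = np.isfinite(suitable_mask.values) & (suitable_mask.values > 0)
    if restrict_to_suitable:
        occupied &= suitable
    lc = landcover.values
    cell_area = grid.cell_area
    classes = np.unique(lc[np.isfinite(lc)]).astype(int)
    out = []
    for cls in classes:
        in_class = lc == cls
        S_cells = int(np.count_nonzero(suitable & in_class))
        U_cells = int(np.count_nonzero(occupied & in_class))
        S = S_cells * cell_area
        U = U_cells * cell_area
        rf = (U / S) * RF_SCALE if S > 0 else np.nan
        out.append(
            dict(
                group=group,
                lc_class=int(cls),
                lc_name=names.get(int(cls), str(cls)),
                U_area=U,
                S_area=S,
                U_cells=U_cells,
                S_cells=S_cells,
                RF=rf,
                note="" if S > 0 else "no suitable habitat in class",
            )
        )
    return pd.DataFrame(out)
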