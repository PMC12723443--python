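"""Planar grids, raster layers/stacks, and raster + occurrence I/O.

Conventions shared by every module in the package:

* one planar coordinate reference system (inputs must be pre-projected;
  no reprojection is performed);
* row 0 / column 0 is the **northwest** cell, rows run north to south;
* cells are half-open ``[x, x + cellsize)`` in both axes;
* nodata is carried as ``NaN`` in memory and serialized as the grid's
  sentinel value.

Raster formats: ESRI ASCII grid (``.asc``) and GeoTIFF (via tifffile with
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags). Occurrences travel as
``species,group,x,y`` CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "RasterLayer",
    "RasterStack",
    "OccurrenceSet",
    "RasterParseError",
    "read_raster",
    "write_raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "resample_nearest",
    "dedup_grid",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "rasterize_geojson",
]


class RasterParseError(ValueError):
    """Raised when a raster file violates its format contract."""


@dataclass(frozen=True)
class Grid:
    """Geometry of a north-up, row-major raster.

    ``x_origin``/``y_origin`` locate the **lower-left** corner of the grid
    (matching the ESRI ASCII ``xllcorner``/``yllcorner`` convention), while
    arrays are stored with row 0 in the north.
    """

    nrows: int
    ncols: int
    cellsize: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area(self) -> float:
        return self.cellsize * self.cellsize

    @property
    def x_max(self) -> float:
        return self.x_origin + self.ncols * self.cellsize

    @property
    def y_max(self) -> float:
        return self.y_origin + self.nrows * self.cellsize

    def cell_of(self, x, y):
        """Map map-coordinates to (row, col); out-of-bounds yields -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor((y - self.y_origin) / self.cellsize).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_origin + (col + 0.5) * self.cellsize
        y = self.y_origin + (self.nrows - row - 0.5) * self.cellsize
        return x, y

    def same_geometry(self, other: "Grid", rtol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and math.isclose(self.cellsize, other.cellsize, rel_tol=rtol)
            and math.isclose(self.x_origin, other.x_origin, rel_tol=rtol, abs_tol=1e-6)
            and math.isclose(self.y_origin, other.y_origin, rel_tol=rtol, abs_tol=1e-6)
        )


@dataclass
class RasterLayer:
    """A named single-band raster; nodata is NaN in ``values``."""

    grid: Grid
    name: str
    values: np.ndarray
    kind: str = "continuous"  # or "categorical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, name or self.name, self.values.copy(), self.kind)


class RasterStack:
    """An ordered collection of aligned layers."""

    def __init__(self, layers: Iterable[RasterLayer]):
        layers = list(layers)
        if not layers:
            raise ValueError("empty raster stack")
        grid = layers[0].grid
        self._layers: dict[str, RasterLayer] = {}
        for lyr in layers:
            if not lyr.grid.same_geometry(grid):
                raise ValueError(f"layer {lyr.name!r} is not aligned with the stack grid")
            if lyr.name in self._layers:
                raise ValueError(f"duplicate layer name {lyr.name!r}")
            self._layers[lyr.name] = lyr
        self.grid = grid

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers.values())

    def __len__(self) -> int:
        return len(self._layers)

    def __getitem__(self, name: str) -> RasterLayer:
        try:
            return self._layers[name]
        except KeyError:
            raise KeyError(f"no layer named {name!r} in stack (have {self.names})") from None

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def add(self, layer: RasterLayer) -> None:
        if not layer.grid.same_geometry(self.grid):
            raise ValueError(f"layer {layer.name!r} is not aligned with the stack grid")
        if layer.name in self._layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        self._layers[layer.name] = layer

    def values_at_cells(self, rows, cols, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_cells, n_layers) matrix of layer values at the given cells."""
        names = list(names) if names is not None else self.names
        out = np.empty((len(np.atleast_1d(rows)), len(names)))
        for j, n in enumerate(names):
            out[:, j] = self[n].values[rows, cols]
        return out

    def finite_mask(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = names or self.names
        mask = np.ones(self.grid.shape, dtype=bool)
        for n in names:
            mask &= self[n].finite_mask
        return mask


# ---------------------------------------------------------------------------
# occurrences


@dataclass
class OccurrenceSet:
    """Presence-only records (``species, group, x, y``), optionally snapped."""

    df: pd.DataFrame
    grid: Grid | None = None

    REQUIRED = ("species", "group", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.df["species"]))

    def for_species(self, species: str) -> "OccurrenceSet":
        return OccurrenceSet(self.df[self.df["species"] == species].copy(), self.grid)

    def for_group(self, group: str) -> "OccurrenceSet":
        return OccurrenceSet(self.df[self.df["group"] == group].copy(), self.grid)

    def cells(self, grid: Grid | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Rows and cols on ``grid`` for every record; out-of-bounds dropped."""
        g = grid or self.grid
        if g is None:
            raise ValueError("no grid attached to occurrence set")
        row, col = g.cell_of(self.df["x"].to_numpy(), self.df["y"].to_numpy())
        ok = row >= 0
        return row[ok], col[ok]

    def unique_cells(self, grid: Grid | None = None) -> tuple[np.ndarray, np.ndarray]:
        row, col = self.cells(grid)
        g = grid or self.grid
        flat = np.unique(row * g.ncols + col)
        return flat // g.ncols, flat % g.ncols


def dedup_grid(occ: OccurrenceSet, dedup_cellsize: float = 1000.0) -> OccurrenceSet:
    """Retain one record per species per ``dedup_cellsize`` grid cell.

    The retained record is the first in input order; records with non-finite
    coordinates are dropped (their count is available via the length delta).
    """
    if not dedup_cellsize > 0:
        raise ValueError("dedup_cellsize must be positive")
    df = occ.df
    finite = np.isfinite(df["x"].to_numpy()) & np.isfinite(df["y"].to_numpy())
    df = df[finite]
    cx = np.floor(df["x"].to_numpy() / dedup_cellsize).astype(np.int64)
    cy = np.floor(df["y"].to_numpy() / dedup_cellsize).astype(np.int64)
    key = pd.DataFrame({"species": df["species"].to_numpy(), "cx": cx, "cy": cy})
    keep = ~key.duplicated()
    return OccurrenceSet(df[keep.to_numpy()].copy(), occ.grid)


def read_occurrences_csv(path: str | Path, grid: Grid | None = None) -> OccurrenceSet:
    df = pd.read_csv(path)
    return OccurrenceSet(df, grid)


def write_occurrences_csv(occ: OccurrenceSet, path: str | Path) -> None:
    occ.df.to_csv(path, index=False, columns=list(OccurrenceSet.REQUIRED))


# ---------------------------------------------------------------------------
# ESRI ASCII grid

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path, name: str | None = None, kind: str = "continuous") -> RasterLayer:
    """Read an ESRI ASCII grid; raises :class:`RasterParseError` on malformed files."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lineno = 0
        line = ""
        # header: key/value pairs until the first line that is all numeric
        for line in fh:
            lineno += 1
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _ASC_HEADER_KEYS:
                if key in header:
                    raise RasterParseError(f"{path}:{lineno}: duplicate header key {key!r}")
                if len(parts) != 2:
                    raise RasterParseError(f"{path}:{lineno}: malformed header line {line!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError:
                    raise RasterParseError(
                        f"{path}:{lineno}: non-numeric header value {parts[1]!r}"
                    ) from None
            else:
                break
        required = [k for k in _ASC_HEADER_KEYS if k != "nodata_value"]
        missing = [k for k in required if k not in header]
        if missing:
            raise RasterParseError(f"{path}: missing header keys {missing}")
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        nodata = header.get("nodata_value", -9999.0)

        def parse_row(text: str, lno: int) -> np.ndarray:
            try:
                vals = np.array([float(v) for v in text.split()])
            except ValueError:
                raise RasterParseError(f"{path}:{lno}: non-numeric data cell") from None
            if vals.size != ncols:
                raise RasterParseError(
                    f"{path}:{lno}: expected {ncols} values per row, found {vals.size}"
                )
            return vals

        if line.split() and line.split()[0].lower() not in _ASC_HEADER_KEYS:
            rows.append(parse_row(line, lineno))
        for line in fh:
            lineno += 1
            if line.strip():
                rows.append(parse_row(line, lineno))
    if len(rows) != nrows:
        raise RasterParseError(f"{path}: header declares {nrows} rows, file has {len(rows)}")
    values = np.vstack(rows)
    values[values == nodata] = np.nan
    grid = Grid(nrows, ncols, header["cellsize"], header["xllcorner"], header["yllcorner"], nodata)
    return RasterLayer(grid, name or path.stem, values, kind)


def write_ascii_grid(layer: RasterLayer, path: str | Path, fmt: str = "%.6g") -> None:
    g = layer.grid
    vals = np.where(np.isfinite(layer.values), layer.values, g.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.x_origin:.6f}\n")
        fh.write(f"yllcorner {g.y_origin:.6f}\n")
        fh.write(f"cellsize {g.cellsize:.6f}\n")
        fh.write(f"NODATA_value {g.nodata:g}\n")
        for r in range(g.nrows):
            fh.write(" ".join(fmt % v for v in vals[r]) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF (single planar CRS; georeferencing via baseline GeoTIFF tags)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(layer: RasterLayer, path: str | Path) -> None:
    import tifffile

    g = layer.grid
    vals = np.where(np.isfinite(layer.values), layer.values, g.nodata).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cellsize, g.cellsize, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_origin, g.y_max, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{g.nodata:g}"),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path: str | Path, name: str | None = None, kind: str = "continuous") -> RasterLayer:
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterParseError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        x_origin = tie[3]
        y_top = tie[4]
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise RasterParseError(f"{path}: non-square pixels are not supported")
    nrows, ncols = vals.shape
    vals[vals == nodata] = np.nan
    grid = Grid(nrows, ncols, sx, x_origin, y_top - nrows * sx, nodata)
    return RasterLayer(grid, name or path.stem, vals, kind)


def read_raster(path: str | Path, format: str | None = None, **kw) -> RasterLayer:
    fmt = format or _infer_format(path)
    if fmt == "asc":
        return read_ascii_grid(path, **kw)
    if fmt == "geotiff":
        return read_geotiff(path, **kw)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_raster(layer: RasterLayer, path: str | Path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "asc":
        write_ascii_grid(layer, path)
    elif fmt == "geotiff":
        write_geotiff(layer, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".asc":
        return "asc"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    raise ValueError(f"cannot infer raster format from {path}")


# ---------------------------------------------------------------------------
# nearest-neighbour resampling

def resample_nearest(layer: RasterLayer, target: Grid) -> RasterLayer:
    """Resample onto ``target``: each target cell takes the value of the source
    cell containing the target cell's center. Nodata propagates; target cells
    whose centers fall outside the source extent become nodata."""
    src = layer.grid
    if (
        target.x_origin >= src.x_max
        or target.x_max <= src.x_origin
        or target.y_origin >= src.y_max
        or target.y_max <= src.y_origin
    ):
        raise ValueError("target grid does not overlap the source raster")
    rows = np.arange(target.nrows)
    cols = np.arange(target.ncols)
    cx, _ = target.cell_center(np.zeros_like(cols), cols)
    _, cy = target.cell_center(rows, np.zeros_like(rows))
    src_col = np.floor((cx - src.x_origin) / src.cellsize).astype(int)
    src_row = src.nrows - 1 - np.floor((cy - src.y_origin) / src.cellsize).astype(int)
    out = np.full(target.shape, np.nan)
    ok_r = (src_row >= 0) & (src_row < src.nrows)
    ok_c = (src_col >= 0) & (src_col < src.ncols)
    rr, cc = np.meshgrid(src_row[ok_r], src_col[ok_c], indexing="ij")
    out[np.ix_(ok_r, ok_c)] = layer.values[rr, cc]
    tgt = replace(target, nodata=src.nodata)
    return RasterLayer(tgt, layer.name, out, layer.kind)


# ---------------------------------------------------------------------------
# GeoJSON polygons → raster mask / labels

def rasterize_geojson(path_or_obj, grid: Grid, value_property: str | None = None) -> RasterLayer:
    """Rasterize GeoJSON polygons by cell-center containment.

    Without ``value_property`` the result is a 0/1 mask; with it, each cell
    takes the property value of the first feature containing its center.
    """
    from shapely.geometry import shape, Point
    from shapely.strtree import STRtree

    if isinstance(path_or_obj, (str, Path)):
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    else:
        obj = path_or_obj
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    geoms, vals = [], []
    for i, f in enumerate(feats):
        geoms.append(shape(f["geometry"]))
        vals.append(float(f.get("properties", {}).get(value_property, i + 1)) if value_property else 1.0)
    rows, cols = np.meshgrid(np.arange(grid.nrows), np.arange(grid.ncols), indexing="ij")
    xs, ys = grid.cell_center(rows.ravel(), cols.ravel())
    pts = [Point(x, y) for x, y in zip(xs, ys)]
    tree = STRtree(geoms)
    out = np.zeros(grid.shape).ravel()
    for gi, pi in zip(*[arr for arr in _query_pairs(tree, pts, geoms)]):
        if out[pi] == 0:
            out[pi] = vals[gi]
    return RasterLayer(grid, "geojson", out.reshape(grid.shape), "categorical")


def _query_pairs(tree, pts, geoms):
    import shapely

    idx = tree.query(pts, predicate="within")
    # shapely 2.x returns (input_idx, tree_idx)
    return idx[1], idx[0]
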