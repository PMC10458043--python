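"""Raster data model: grid specification, layers, stacks, GeoTIFF I/O,
resampling, terrain derivatives and summary statistics.

All grids live in a single projected CRS with square cells in meters.
Cell (0, 0) is the top-left cell; a point (x, y) maps to cell
``(floor((origin_y - y)/cell_size), floor((x - origin_x)/cell_size))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "GridLayer",
    "RasterStack",
    "read_geotiff",
    "write_geotiff",
    "resample",
    "derive_slope_aspect",
    "summarize",
]

# GeoTIFF tag codes used for georeferencing
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

Kind = Literal["continuous", "categorical"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (square cells, projected meters)."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_tag: str

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")
        if not self.crs_tag:
            raise ValueError("crs_tag must be a non-empty string")

    # -- coordinate helpers -------------------------------------------------

    def cell_of(self, x: np.ndarray | float, y: np.ndarray | float):
        """Map point coordinates to (row, col) indices (may be out of range)."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, float)) / self.cell_size)
        return row.astype(np.int64), col.astype(np.int64)

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col):
        """Center coordinates of cell (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_centers(self):
        """Meshgrid of all cell-center coordinates, shape (n_rows, n_cols)."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)

    def aligned_with(self, other: "GridSpec") -> bool:
        return self == other


@dataclass
class GridLayer:
    """A named raster layer on a :class:`GridSpec`."""

    spec: GridSpec
    name: str
    kind: Kind
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")

    @property
    def valid_mask(self) -> np.ndarray:
        vals = self.values
        mask = vals != self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            mask &= np.isfinite(vals)
        return mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, **kwargs) -> "GridLayer":
        out = replace(self, values=values)
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out

    def sample(self, x, y):
        """Values at point coordinates; nodata outside the grid."""
        row, col = self.spec.cell_of(x, y)
        inside = (
            (row >= 0) & (row < self.spec.n_rows)
            & (col >= 0) & (col < self.spec.n_cols)
        )
        out = np.full(np.shape(row), self.nodata, dtype=float)
        out[inside] = self.values[row[inside], col[inside]]
        return out


@dataclass
class RasterStack:
    """An ordered collection of aligned, uniquely named layers."""

    layers: list[GridLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        if self.layers:
            spec = self.layers[0].spec
            for l in self.layers[1:]:
                if not l.spec.aligned_with(spec):
                    raise ValueError(f"layer {l.name!r} is not aligned with the stack")

    @property
    def spec(self) -> GridSpec:
        if not self.layers:
            raise ValueError("empty stack has no spec")
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> GridLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def add(self, layer: GridLayer) -> None:
        if layer.name in self.names:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        if self.layers and not layer.spec.aligned_with(self.spec):
            raise ValueError(f"layer {layer.name!r} is not aligned with the stack")
        self.layers.append(layer)

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def joint_valid_mask(self) -> np.ndarray:
        """Cells valid in every layer of the stack."""
        mask = np.ones((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for l in self.layers:
            mask &= l.valid_mask
        return mask


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile-backed; pixel scale / tiepoint / GDAL nodata tags)
# ---------------------------------------------------------------------------

def write_geotiff(layer: GridLayer, path) -> None:
    """Write a layer as a single-band GeoTIFF.

    Georeferencing is stored in the standard ModelPixelScale / ModelTiepoint
    tags, the nodata sentinel in the GDAL nodata tag, and layer metadata
    (name, kind, CRS tag) as JSON in the image description.
    """
    spec = layer.spec
    values = layer.values
    if layer.kind == "categorical":
        data = np.ascontiguousarray(values, dtype=np.int32)
    else:
        data = np.ascontiguousarray(values, dtype=np.float32)
    desc = json.dumps(
        {"name": layer.name, "kind": layer.kind, "crs_tag": spec.crs_tag}
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(layer.nodata))),
    ]
    tifffile.imwrite(path, data, description=desc, extratags=extratags)


def read_geotiff(path, name: str | None = None) -> GridLayer:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF with square pixels and the standard georeferencing tags)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy})")
        tie = tags[_TAG_TIEPOINT].value
        origin_x = tie[3] - tie[0] * sx
        origin_y = tie[4] + tie[1] * sy
        values = page.asarray()
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        meta: dict = {}
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        crs_tag = meta.get("crs_tag")
        if not crs_tag:
            raise ValueError(f"{path}: no CRS recorded in the file")
        kind = meta.get("kind", "continuous")
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band 2-D raster")
    spec = GridSpec(
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=float(sx),
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        crs_tag=crs_tag,
    )
    if kind == "categorical" and nodata == int(nodata):
        nodata = int(nodata)
    return GridLayer(
        spec=spec,
        name=name or meta.get("name", "layer"),
        kind=kind,
        values=values,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_RESAMPLE_METHODS = ("nearest", "bilinear", "block_mean", "block_mode")


def resample(layer: GridLayer, target: GridSpec, method: str) -> GridLayer:
    """Resample a layer onto a target grid.

    ``nearest`` samples the source cell under each target cell center;
    ``bilinear`` interpolates between the four surrounding source cell
    centers; ``block_mean``/``block_mode`` aggregate all source cells whose
    centers fall inside a target cell.  Nodata is never interpolated: any
    bilinear/block window touching nodata yields nodata.
    """
    if method not in _RESAMPLE_METHODS:
        raise ValueError(f"unknown resampling method {method!r}")
    if layer.kind == "categorical" and method in ("bilinear", "block_mean"):
        raise ValueError(f"{method} resampling is invalid for categorical layers")
    if layer.kind == "continuous" and method == "block_mode":
        raise ValueError("block_mode resampling is invalid for continuous layers")
    if layer.spec.crs_tag != target.crs_tag:
        raise ValueError(
            f"CRS mismatch: {layer.spec.crs_tag!r} vs {target.crs_tag!r}"
        )

    if method == "nearest":
        out = _resample_nearest(layer, target)
    elif method == "bilinear":
        out = _resample_bilinear(layer, target)
    else:
        out = _resample_block(layer, target, mode=(method == "block_mode"))
    return GridLayer(
        spec=target, name=layer.name, kind=layer.kind, values=out,
        nodata=layer.nodata,
    )


def _resample_nearest(layer: GridLayer, target: GridSpec) -> np.ndarray:
    xc, yc = target.cell_centers()
    src = layer.spec
    row, col = src.cell_of(xc, yc)
    inside = (row >= 0) & (row < src.n_rows) & (col >= 0) & (col < src.n_cols)
    out = np.full(xc.shape, layer.nodata, dtype=layer.values.dtype)
    out[inside] = layer.values[row[inside], col[inside]]
    return out


def _resample_bilinear(layer: GridLayer, target: GridSpec) -> np.ndarray:
    src = layer.spec
    xc, yc = target.cell_centers()
    # fractional position in source cell-center coordinates
    fc = (xc - src.origin_x) / src.cell_size - 0.5
    fr = (src.origin_y - yc) / src.cell_size - 0.5
    r0 = np.floor(fr).astype(np.int64)
    c0 = np.floor(fc).astype(np.int64)
    wr = fr - r0
    wc = fc - c0
    out = np.full(xc.shape, layer.nodata, dtype=np.float64)
    inside = (r0 >= 0) & (r0 + 1 < src.n_rows) & (c0 >= 0) & (c0 + 1 < src.n_cols)
    valid = layer.valid_mask
    vals = np.where(valid, layer.values.astype(np.float64), np.nan)
    r0i, c0i = r0[inside], c0[inside]
    v00 = vals[r0i, c0i]
    v01 = vals[r0i, c0i + 1]
    v10 = vals[r0i + 1, c0i]
    v11 = vals[r0i + 1, c0i + 1]
    wri, wci = wr[inside], wc[inside]
    interp = (
        v00 * (1 - wri) * (1 - wci)
        + v01 * (1 - wri) * wci
        + v10 * wri * (1 - wci)
        + v11 * wri * wci
    )
    res = np.where(np.isnan(interp), layer.nodata, interp)
    out[inside] = res
    return out


def _resample_block(layer: GridLayer, target: GridSpec, mode: bool) -> np.ndarray:
    src = layer.spec
    xs, ys = src.cell_centers()
    trow, tcol = target.cell_of(xs, ys)
    inside = (
        (trow >= 0) & (trow < target.n_rows)
        & (tcol >= 0) & (tcol < target.n_cols)
    )
    out = np.full((target.n_rows, target.n_cols), layer.nodata,
                  dtype=layer.values.dtype)
    flat_idx = trow[inside] * target.n_cols + tcol[inside]
    src_vals = layer.values[inside]
    src_valid = layer.valid_mask[inside]
    order = np.argsort(flat_idx, kind="stable")
    flat_idx = flat_idx[order]
    src_vals = src_vals[order]
    src_valid = src_valid[order]
    bounds = np.flatnonzero(np.diff(flat_idx)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(flat_idx)]])
    for s, e in zip(starts, ends):
        if not src_valid[s:e].all():
            continue  # nodata in window -> nodata
        window = src_vals[s:e]
        idx = flat_idx[s]
        r, c = divmod(int(idx), target.n_cols)
        if mode:
            codes, counts = np.unique(window, return_counts=True)
            out[r, c] = codes[np.argmax(counts)]
        else:
            out[r, c] = window.mean()
    return out


# ---------------------------------------------------------------------------
# Terrain derivatives
# ---------------------------------------------------------------------------

def derive_slope_aspect(dem: GridLayer) -> tuple[GridLayer, GridLayer]:
    """Slope (percent) and aspect (degrees clockwise from north, downslope
    direction) from a DEM using Horn's 3x3 finite-difference stencil.

    Border cells, cells with nodata in their 3x3 window, and the aspect of
    flat cells are set to nodata.
    """
    if dem.kind != "continuous":
        raise ValueError("DEM must be a continuous layer")
    if dem.spec.n_rows < 3 or dem.spec.n_cols < 3:
        raise ValueError("DEM must be at least 3x3")
    z = dem.values.astype(np.float64)
    cell = dem.spec.cell_size
    valid = dem.valid_mask

    nodata = float(dem.nodata)
    slope = np.full(z.shape, nodata)
    aspect = np.full(z.shape, nodata)

    # 3x3 window: a b c / d e f / g h i
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]

    win_valid = np.ones(a.shape, dtype=bool)
    for rr in range(3):
        for cc in range(3):
            win_valid &= valid[rr:rr + a.shape[0], cc:cc + a.shape[1]]

    # dz/dx positive eastward; dz/dy positive northward
    p = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    q = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell)

    grad = np.hypot(p, q)
    slope_pct = 100.0 * grad
    # azimuth of the downslope direction (-p, -q), clockwise from north
    az = np.degrees(np.arctan2(-p, -q)) % 360.0

    interior = np.s_[1:-1, 1:-1]
    slope_i = np.full(a.shape, nodata)
    aspect_i = np.full(a.shape, nodata)
    slope_i[win_valid] = slope_pct[win_valid]
    flat = win_valid & (grad == 0)
    sloped = win_valid & (grad > 0)
    aspect_i[sloped] = az[sloped]
    aspect_i[flat] = nodata
    slope[interior] = slope_i
    aspect[interior] = aspect_i

    slope_layer = GridLayer(dem.spec, "slope", "continuous", slope, nodata)
    aspect_layer = GridLayer(dem.spec, "aspect", "continuous", aspect, nodata)
    return slope_layer, aspect_layer


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summarize(
    stack: RasterStack,
    mask: np.ndarray | None = None,
    points: Iterable[tuple[float, float]] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Min/max/mean/std per layer over valid cells (optionally restricted to
    a boolean mask), and separately over the cells containing ``points``.

    Returns a tidy frame with one row per (layer, scope).
    """
    rows = []
    spec = stack.spec
    point_rc = None
    if points is not None:
        pts = np.asarray(list(points), dtype=float)
        if pts.size:
            prow, pcol = spec.cell_of(pts[:, 0], pts[:, 1])
            inside = (
                (prow >= 0) & (prow < spec.n_rows)
                & (pcol >= 0) & (pcol < spec.n_cols)
            )
            if not inside.all():
                bad = np.flatnonzero(~inside).tolist()
                raise ValueError(f"points outside grid extent at indices {bad}")
            point_rc = (prow, pcol)
    for layer in stack:
        lmask = layer.valid_mask
        if mask is not None:
            lmask = lmask & mask
        vals = layer.values[lmask].astype(np.float64)
        if vals.size == 0:
            raise ValueError(f"layer {layer.name!r}: no valid cells to summarize")
        rows.append(_stat_row(layer.name, "area", vals, ddof))
        if point_rc is not None:
            pv = layer.values[point_rc].astype(np.float64)
            pv = pv[pv != layer.nodata]
            if pv.size == 0:
                raise ValueError(
                    f"layer {layer.name!r}: no valid cells at the given points"
                )
            rows.append(_stat_row(layer.name, "points", pv, ddof))
    return pd.DataFrame(rows)


def _stat_row(name: str, scope: str, vals: np.ndarray, ddof: int) -> dict:
    return {
        "layer": name,
        "scope": scope,
        "n": int(vals.size),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "std": float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0,
    }
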