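"""Grid data model, raster I/O, and deterministic spatial transforms.

Conventions
-----------
Cell-center registration; row 0 is the north edge.  ``origin_x``/``origin_y``
are the coordinates of the *outer* corner of the top-left cell, so the center
of cell (row, col) is at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

All distances are Euclidean in the working (projected, equal-area) CRS.
Internally nodata is represented as NaN; the ``Grid.nodata`` sentinel is only
used at the file boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "Raster",
    "RasterStack",
    "align_stack",
    "class_fractions",
    "slope_from_elevation",
    "tpi",
    "distance_to_features",
    "focal_density",
    "read_geotiff",
    "write_geotiff",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Regular grid geometry shared by aligned rasters."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_id: str = "local-metric"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and self.crs_id == other.crs_id
        )

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Cell (row, col) containing the point(s). No bounds clipping."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "crs_id": self.crs_id,
            "nodata": self.nodata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(**d)


@dataclass
class Raster:
    """A grid plus a float matrix of values (NaN = nodata)."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(self.grid, values)

    def sample(self, x, y) -> np.ndarray:
        """Value at the cell containing each point; NaN off-grid."""
        row, col = self.grid.index_of(x, y)
        out = np.full(np.shape(row), np.nan)
        ok = (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        out[ok] = self.values[row[ok], col[ok]]
        return out


@dataclass
class RasterStack:
    """Ordered, named, mutually aligned rasters."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = [r.grid for r in self.layers.values()]
        for g in grids[1:]:
            if not g.aligned_with(grids[0]):
                raise ValueError("stack layers are not aligned on one grid")

    @property
    def grid(self) -> Grid:
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def add(self, name: str, raster: Raster) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self.layers and not raster.grid.aligned_with(self.grid):
            raise ValueError(f"layer {name!r} not aligned with stack grid")
        self.layers[name] = raster

    def subset(self, names) -> "RasterStack":
        return RasterStack({n: self.layers[n] for n in names})

    def as_array(self, names=None) -> np.ndarray:
        """(n_layers, rows, cols) array in the given (or stored) order."""
        names = self.names if names is None else list(names)
        return np.stack([self.layers[n].values for n in names])


# ---------------------------------------------------------------------------
# resampling


def _resample_continuous(src: Raster, template: Grid, order: int) -> Raster:
    xs, ys = template.cell_center(
        np.arange(template.n_rows)[:, None].repeat(template.n_cols, 1),
        np.arange(template.n_cols)[None, :].repeat(template.n_rows, 0),
    )
    # fractional source indices of the template cell centers
    fcol = (xs - src.grid.origin_x) / src.grid.cell_size - 0.5
    frow = (src.grid.origin_y - ys) / src.grid.cell_size - 0.5
    inside = (
        (frow > -0.5 - 1e-9)
        & (frow < src.grid.n_rows - 0.5 + 1e-9)
        & (fcol > -0.5 - 1e-9)
        & (fcol < src.grid.n_cols - 0.5 + 1e-9)
    )
    if not inside.any():
        raise ValueError("raster has zero overlap with template grid")
    vals = np.nan_to_num(src.values)
    wvalid = src.valid.astype(float)
    coords = np.stack([frow.ravel(), fcol.ravel()])
    num = ndimage.map_coordinates(vals, coords, order=order, mode="nearest")
    den = ndimage.map_coordinates(wvalid, coords, order=order, mode="nearest")
    out = np.where(den > 1e-9, num / np.maximum(den, 1e-12), np.nan)
    out = out.reshape(template.shape)
    out[~inside] = np.nan
    # strict nodata propagation for bilinear: any nodata in support -> nodata
    if order == 1:
        out[(den.reshape(template.shape) < 1.0 - 1e-9) & inside] = np.nan
    return Raster(template, out)


def _resample_fraction(src: Raster, template: Grid) -> Raster:
    """Mean of fine 0/1 cells whose centers fall in each coarse cell."""
    rows = np.arange(src.grid.n_rows)[:, None].repeat(src.grid.n_cols, 1)
    cols = np.arange(src.grid.n_cols)[None, :].repeat(src.grid.n_rows, 0)
    xs, ys = src.grid.cell_center(rows, cols)
    trow, tcol = template.index_of(xs, ys)
    ok = (
        (trow >= 0)
        & (trow < template.n_rows)
        & (tcol >= 0)
        & (tcol < template.n_cols)
        & src.valid
    )
    if not ok.any():
        raise ValueError("raster has zero overlap with template grid")
    flat = trow[ok] * template.n_cols + tcol[ok]
    sums = np.bincount(flat, weights=src.values[ok], minlength=template.n_rows * template.n_cols)
    counts = np.bincount(flat, minlength=template.n_rows * template.n_cols)
    out = np.full(template.n_rows * template.n_cols, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return Raster(template, out.reshape(template.shape))


def align_stack(rasters: dict[str, Raster], template: Grid, methods: dict[str, str]) -> RasterStack:
    """Resample named rasters onto a template grid.

    ``methods`` maps each layer name to one of ``bilinear`` (continuous),
    ``nearest`` (categorical) or ``fraction`` (proportion of fine 0/1 cells
    within each coarse cell).
    """
    out = RasterStack()
    for name, src in rasters.items():
        if name not in methods:
            raise ValueError(f"no resampling method given for layer {name!r}")
        method = methods[name]
        if method == "bilinear":
            res = _resample_continuous(src, template, order=1)
        elif method == "nearest":
            res = _resample_continuous(src, template, order=0)
        elif method == "fraction":
            res = _resample_fraction(src, template)
        else:
            raise ValueError(f"unknown resampling method {method!r}")
        out.add(name, Raster(template, res.values))
    return out


def class_fractions(cover: Raster, classes, template: Grid | None = None) -> RasterStack:
    """Per-class fraction layers from a categorical cover raster.

    With no template the fractions are one-hot on the native grid.
    """
    template = template or cover.grid
    out = RasterStack()
    for i, cls in enumerate(classes):
        mask = np.where(cover.valid, (cover.values == i).astype(float), np.nan)
        out.add(f"frac_{cls}", _resample_fraction(Raster(cover.grid, mask), template))
    return out


# ---------------------------------------------------------------------------
# terrain


def slope_from_elevation(elev: Raster) -> Raster:
    """Slope in degrees from a 3x3 Horn finite-difference gradient.

    Edge cells use replicated-edge padding, which reduces to one-sided
    differences. Cells with nodata anywhere in their 3x3 support emit nodata.
    """
    if elev.grid.n_rows < 3 or elev.grid.n_cols < 3:
        raise ValueError("slope requires a grid of at least 3x3 cells")
    z = np.pad(elev.values, 1, mode="edge")
    cs = elev.grid.cell_size
    # Horn weights: (z[c+1] row-neighborhood) with 1-2-1 weighting
    dzdx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * cs)
    dzdy = (
        (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
    ) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    bad = ndimage.maximum_filter(np.isnan(elev.values).astype(np.uint8), size=3) > 0
    slope[bad] = np.nan
    return Raster(elev.grid, slope)


def _disk_footprint(radius: float, cell_size: float) -> np.ndarray:
    r = int(np.floor(radius / cell_size + 1e-9))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(yy, xx) * cell_size) <= radius + 1e-9


def _focal_mean(values: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """NaN-aware mean over a footprint (renormalized over valid cells)."""
    filled = np.nan_to_num(values)
    valid = (~np.isnan(values)).astype(float)
    ksum = ndimage.correlate(filled, footprint.astype(float), mode="constant", cval=0.0)
    kcnt = ndimage.correlate(valid, footprint.astype(float), mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(kcnt > 0, ksum / kcnt, np.nan)
    return out


def tpi(elev: Raster, radius: float) -> Raster:
    """Topographic position index: cell minus mean of neighbors within radius."""
    if radius < elev.grid.cell_size:
        raise ValueError("tpi radius must be at least one cell")
    fp = _disk_footprint(radius, elev.grid.cell_size)
    fp[fp.shape[0] // 2, fp.shape[1] // 2] = False  # exclude center
    nbr_mean = _focal_mean(elev.values, fp)
    out = elev.values - nbr_mean
    out[~elev.valid] = np.nan
    return Raster(elev.grid, out)


def distance_to_features(mask: Raster) -> Raster:
    """Euclidean distance (between cell centers) to the nearest 1-cell."""
    feat = np.nan_to_num(mask.values) > 0.5
    if not feat.any():
        raise ValueError("feature mask is empty")
    dist = ndimage.distance_transform_edt(~feat, sampling=mask.grid.cell_size)
    dist = np.asarray(dist, dtype=float)
    dist[~mask.valid] = np.nan
    return Raster(mask.grid, dist)


def focal_density(mask: Raster, radius: float) -> Raster:
    """Fraction of cells flagged 1 within a circular window; in [0, 1]."""
    if radius < mask.grid.cell_size:
        raise ValueError("density radius must be at least one cell")
    fp = _disk_footprint(radius, mask.grid.cell_size)
    out = _focal_mean(mask.values, fp)
    out[~mask.valid] = np.nan
    return Raster(mask.grid, out)


# ---------------------------------------------------------------------------
# I/O — single-band float32 TIFF with the grid serialized in the description
# tag (rasterio is not a dependency; tifffile covers the container format).


def write_geotiff(raster: Raster, path) -> None:
    import tifffile

    vals = raster.values.astype(np.float32)
    vals = np.where(np.isnan(vals), np.float32(raster.grid.nodata), vals)
    tifffile.imwrite(
        str(path),
        vals,
        description=json.dumps({"grid": raster.grid.to_dict()}),
    )


def read_geotiff(path, default_crs: str = "local-metric") -> Raster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        vals = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    if "grid" in meta:
        grid = Grid.from_dict(meta["grid"])
    else:
        import warnings

        warnings.warn(f"{path}: no grid metadata; assuming unit grid in {default_crs}")
        grid = Grid(vals.shape[0], vals.shape[1], 1.0, crs_id=default_crs)
    vals[vals == grid.nodata] = np.nan
    return Raster(grid, vals)


def constant_raster(grid: Grid, value: float) -> Raster:
    return Raster(grid, np.full(grid.shape, float(value)))
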