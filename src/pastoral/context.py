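"""Spatial/temporal context: grids, timelines, raster fields and mediation.

A simulation is always computed over a :class:`Context` — a planar raster
grid plus a daily timeline.  All per-cell quantities travel as
:class:`RasterField` objects.  Inputs on a different grid are mediated onto
the context grid on the fly by :func:`resample_field` (area-weighted mean
for continuous quantities, nearest neighbour for categorical codes).

Coordinate convention: row-major, origin at the top-left corner, 0-based
indices; cell (0, 0) covers ``[origin_x, origin_x + cell_size) ×
(origin_y - cell_size, origin_y]``.  A single planar reference is assumed;
no CRS reprojection is performed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd

from .units import UnitSpec, DIMENSIONLESS

__all__ = [
    "GridSpec",
    "Timeline",
    "Context",
    "RasterField",
    "ResolutionError",
    "make_default_context",
    "resample_field",
    "zonal_statistics",
]

DEFAULT_NODATA = -9999.0


class ResolutionError(ValueError):
    """Raised when two rasters cannot be brought onto a common grid."""


@dataclass(frozen=True)
class GridSpec:
    """A regular raster grid in a planar reference."""

    ncols: int
    nrows: int
    cell_size: float  # metres
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area(self) -> float:
        """Cell area in m²."""
        return self.cell_size * self.cell_size

    def x_edges(self) -> np.ndarray:
        return self.origin_x + self.cell_size * np.arange(self.ncols + 1)

    def y_edges(self) -> np.ndarray:
        """Top-to-bottom edge coordinates (decreasing)."""
        return self.origin_y - self.cell_size * np.arange(self.nrows + 1)

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.cell_size,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y,
        )


@dataclass(frozen=True)
class Timeline:
    """An inclusive daily timeline (proleptic Gregorian, leap days included)."""

    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("timeline start must not be after end")

    @property
    def step_days(self) -> int:
        return 1

    @property
    def n_steps(self) -> int:
        return (self.end - self.start).days + 1

    def date(self, t: int) -> _dt.date:
        if not 0 <= t < self.n_steps:
            raise IndexError(f"step {t} outside timeline of {self.n_steps} steps")
        return self.start + _dt.timedelta(days=t)

    def dates(self):
        for t in range(self.n_steps):
            yield self.start + _dt.timedelta(days=t)


@dataclass(frozen=True)
class Context:
    """Where and when a query is computed: grid, timeline and validity mask."""

    grid: GridSpec
    timeline: Timeline
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mask = self.mask
        if mask is None:
            mask = np.ones(self.grid.shape, dtype=bool)
            object.__setattr__(self, "mask", mask)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape must equal grid shape")
        if not mask.any():
            raise ValueError("context must contain at least one valid cell")
        object.__setattr__(self, "mask", mask)


def make_default_context(
    ncols: int = 40, nrows: int = 40, origin_x: float = 0.0, origin_y: float = 0.0
) -> Context:
    """The default context: 50 m cells, daily step, 2018-01-01 – 2050-12-31.

    The grid extent (number of cells) is user-chosen; only the resolution and
    the timeline carry defaults.
    """
    grid = GridSpec(ncols=ncols, nrows=nrows, cell_size=50.0,
                    origin_x=origin_x, origin_y=origin_y)
    timeline = Timeline(_dt.date(2018, 1, 1), _dt.date(2050, 12, 31))
    return Context(grid=grid, timeline=timeline)


@dataclass
class RasterField:
    """A gridded quantity with units and nodata.

    ``kind`` is ``"continuous"`` (float values, area-weighted aggregation) or
    ``"categorical"`` (integer codes, nearest-neighbour resampling).
    """

    concept_id: str
    grid: GridSpec
    values: np.ndarray
    units: UnitSpec = DIMENSIONLESS
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.kind == "categorical":
            if not np.issubdtype(self.values.dtype, np.integer):
                raise ValueError("categorical fields carry integer codes only")
        else:
            self.values = self.values.astype(np.float64, copy=False)

    @property
    def nodata(self) -> float:
        return self.grid.nodata

    def valid_mask(self) -> np.ndarray:
        if self.kind == "categorical":
            return self.values != int(self.grid.nodata)
        return self.values != self.grid.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]


def _axis_overlap(src_edges: np.ndarray, dst_edges: np.ndarray,
                  descending: bool = False) -> np.ndarray:
    """Overlap-length matrix W[j, i] between destination cell j and source cell i."""
    if descending:
        src_lo, src_hi = src_edges[1:], src_edges[:-1]
        dst_lo, dst_hi = dst_edges[1:], dst_edges[:-1]
    else:
        src_lo, src_hi = src_edges[:-1], src_edges[1:]
        dst_lo, dst_hi = dst_edges[:-1], dst_edges[1:]
    lo = np.maximum.outer(dst_lo, src_lo)
    hi = np.minimum.outer(dst_hi, src_hi)
    return np.clip(hi - lo, 0.0, None)


def _extents_overlap(a: GridSpec, b: GridSpec) -> bool:
    ax0, ay0, ax1, ay1 = a.extent()
    bx0, by0, bx1, by1 = b.extent()
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def resample_field(field: RasterField, target: GridSpec) -> RasterField:
    """Mediate a field onto a target grid.

    Continuous fields use the area-weighted mean of overlapping source cells;
    target cells whose valid source coverage is below 50% become nodata.
    Categorical fields take the code of the source cell containing the target
    cell centre.  Grids must overlap spatially.
    """
    if field.grid == target:
        return RasterField(field.concept_id, target, field.values.copy(),
                           field.units, field.kind)
    if not _extents_overlap(field.grid, target):
        raise ResolutionError(
            f"grids are spatially disjoint: source extent {field.grid.extent()} "
            f"vs target extent {target.extent()}"
        )

    src, vals = field.grid, field.values
    if field.kind == "categorical":
        xc = target.origin_x + target.cell_size * (np.arange(target.ncols) + 0.5)
        yc = target.origin_y - target.cell_size * (np.arange(target.nrows) + 0.5)
        ci = np.floor((xc - src.origin_x) / src.cell_size).astype(int)
        ri = np.floor((src.origin_y - yc) / src.cell_size).astype(int)
        inside_c = (ci >= 0) & (ci < src.ncols)
        inside_r = (ri >= 0) & (ri < src.nrows)
        out = np.full(target.shape, int(target.nodata), dtype=vals.dtype)
        rr, cc = np.meshgrid(ri.clip(0, src.nrows - 1), ci.clip(0, src.ncols - 1),
                             indexing="ij")
        sampled = vals[rr, cc]
        inside = np.outer(inside_r, inside_c)
        out[inside] = sampled[inside]
        return RasterField(field.concept_id, target, out, field.units, "categorical")

    wx = _axis_overlap(src.x_edges(), target.x_edges())          # (tc, sc)
    wy = _axis_overlap(src.y_edges(), target.y_edges(), True)    # (tr, sr)
    valid = field.valid_mask().astype(np.float64)
    v = np.where(valid > 0, vals, 0.0)
    num = wy @ v @ wx.T
    den = wy @ valid @ wx.T
    cell_area = target.cell_size ** 2
    coverage = den / cell_area
    out = np.full(target.shape, target.nodata, dtype=np.float64)
    ok = coverage >= 0.5
    out[ok] = num[ok] / den[ok]
    return RasterField(field.concept_id, target, out, field.units, "continuous")


def zonal_statistics(field: RasterField, zones: RasterField) -> pd.DataFrame:
    """Per-zone mean/min/max/sum of a field over a categorical zone raster.

    Returns a dataframe with columns zone_id, mean, min, max, sum; one row per
    zone code present among valid cells. Nodata cells of either raster are
    ignored.  Both rasters must share a grid.
    """
    if zones.kind != "categorical":
        raise ValueError("zones must be a categorical field")
    if zones.grid != field.grid:
        raise ResolutionError(
            f"zone grid {zones.grid} does not match field grid {field.grid}"
        )
    ok = field.valid_mask() & zones.valid_mask()
    if not ok.any():
        return pd.DataFrame(columns=["zone_id", "mean", "min", "max", "sum"])
    df = pd.DataFrame({"zone_id": zones.values[ok], "value": field.values[ok]})
    g = df.groupby("zone_id")["value"]
    out = pd.DataFrame({
        "zone_id": g.mean().index,
        "mean": g.mean().to_numpy(),
        "min": g.min().to_numpy(),
        "max": g.max().to_numpy(),
        "sum": g.sum().to_numpy(),
    }).reset_index(drop=True)
    return out
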